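"""Sliding-window dynamic functional connectivity (dFC) features.

Dynamic functional connectivity tracks how the Pearson correlation between
two regions' BOLD series varies over time: the series are band-passed, a
window of ``width`` TRs slides in steps of ``step`` TRs, and the correlation
is recomputed inside each window (a "temporal segment").  For a set of
selected regions per band the per-segment correlation matrices are
vectorised (upper triangle only — the matrices are symmetric) and
concatenated into one feature row per subject.

The vectorisation order is frozen: band blocks in the given order, segments
within a band, upper-triangle pairs row-major within a segment.  The exact
(segment, roi_a, roi_b, band) of every column is recorded in the feature
matrix's index map so feature ids are stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BandScheme, SpectralConfig, bandpass

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = [
    "SlidingWindowConfig",
    "DfcFeatureMatrix",
    "count_segments",
    "sliding_window_corr",
    "build_dfc_features",
    "mixed_window_features",
    "pairwise_discriminative_counts",
    "dfc_feature_id",
]


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Window width and step length, both in TRs."""

    width: int
    step: int = 5

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError(f"window width must be >= 2 TRs, got {self.width}")
        if self.step < 1:
            raise ValueError(f"step must be >= 1 TR, got {self.step}")


def dfc_feature_id(band: str, segment: int, roi_a: int, roi_b: int) -> str:
    """Stable id for one dFC feature column: ``<band>:seg<k>:ROI<a>-ROI<b>``."""
    return f"{band}:seg{segment}:ROI{roi_a + 1}-ROI{roi_b + 1}"


@dataclass
class DfcFeatureMatrix:
    """Subjects x (segment, ROI pair, band) sliding-window correlations."""

    values: np.ndarray
    index_map: list[tuple[int, int, int, str]]  # column -> (segment, roi_a, roi_b, band)
    config: dict[str, SlidingWindowConfig]  # band -> window config
    scheme: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x features")
        if self.values.shape[1] != len(self.index_map):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.index_map)} index entries"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return [dfc_feature_id(b, s, ra, rb) for s, ra, rb, b in self.index_map]

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        return df.to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, text: str, config: dict[str, SlidingWindowConfig], scheme: str
    ) -> "DfcFeatureMatrix":
        df = pd.read_csv(StringIO(text), sep="\t")
        index_map = []
        for col in df.columns:
            band, seg, pair = col.split(":")
            a, b = pair.split("-")
            index_map.append(
                (
                    int(seg.removeprefix("seg")),
                    int(a.removeprefix("ROI")) - 1,
                    int(b.removeprefix("ROI")) - 1,
                    band,
                )
            )
        return cls(df.to_numpy(float), index_map, config, scheme)


def count_segments(n_timepoints: int, config: SlidingWindowConfig) -> int:
    """Number of full windows: floor((N - width)/step) + 1.

    Trailing samples not covered by a full window are dropped.
    """
    if config.width > n_timepoints:
        raise ValueError(
            f"window width {config.width} exceeds series length {n_timepoints}"
        )
    return (n_timepoints - config.width) // config.step + 1


def _window_starts(n_timepoints: int, config: SlidingWindowConfig) -> np.ndarray:
    n_seg = count_segments(n_timepoints, config)
    return np.arange(n_seg) * config.step


def sliding_window_corr(
    x: np.ndarray, y: np.ndarray, config: SlidingWindowConfig
) -> np.ndarray:
    """Pearson correlation of ``x`` and ``y`` inside each sliding window.

    Windows start at 0, step, 2*step, ...; output length equals
    ``count_segments``.  A zero-variance window has no defined correlation;
    it is recorded as 0 with a warning (only degenerate inputs hit this).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    starts = _window_starts(x.size, config)
    out = np.empty(starts.size)
    w = config.width
    for i, t in enumerate(starts):
        xw = x[t : t + w]
        yw = y[t : t + w]
        sx = xw.std()
        sy = yw.std()
        if sx == 0.0 or sy == 0.0:
            logger.warning(
                "zero-variance window at start %d (width %d); correlation set to 0",
                t,
                w,
            )
            out[i] = 0.0
            continue
        out[i] = ((xw - xw.mean()) * (yw - yw.mean())).mean() / (sx * sy)
    return out


def _segment_correlations(
    roi_series: np.ndarray, config: SlidingWindowConfig
) -> np.ndarray:
    """Upper-triangle window correlations for an ROIs x time block.

    Returns segments x pairs, pairs in row-major upper-triangle order.
    """
    m, n = roi_series.shape
    starts = _window_starts(n, config)
    iu = np.triu_indices(m, k=1)
    out = np.empty((starts.size, iu[0].size))
    for i, t in enumerate(starts):
        win = roi_series[:, t : t + config.width]
        sd = win.std(axis=1)
        if np.any(sd == 0.0):
            # per-pair fallback preserves the zero-variance convention
            for j, (a, b) in enumerate(zip(*iu)):
                out[i, j] = sliding_window_corr(
                    roi_series[a, t : t + config.width],
                    roi_series[b, t : t + config.width],
                    SlidingWindowConfig(config.width, config.width),
                )[0]
            continue
        c = np.corrcoef(win)
        out[i] = c[iu]
    return out


def _normalize_configs(
    bands: Sequence[str],
    config: SlidingWindowConfig | Mapping[str, SlidingWindowConfig],
) -> dict[str, SlidingWindowConfig]:
    if isinstance(config, SlidingWindowConfig):
        return {b: config for b in bands}
    missing = [b for b in bands if b not in config]
    if missing:
        raise ValueError(f"no window config for band block(s) {missing}")
    return {b: config[b] for b in bands}


def build_dfc_features(
    cohort: "SyntheticCohort | np.ndarray",
    selected_rois_per_band: Mapping[str, Sequence[int]],
    scheme: BandScheme,
    config: SlidingWindowConfig | Mapping[str, SlidingWindowConfig],
    spectral: SpectralConfig | None = None,
) -> DfcFeatureMatrix:
    """Sliding-window correlation features among selected ROIs per band.

    For each band block the selected ROI series are band-passed and the
    window correlations of every unordered ROI pair are computed.  Under the
    Combined scheme each block is filtered with its own band; under the
    Conventional scheme the per-band ROI lists are kept as separate blocks
    but all filtered with the single Conventional band.  Columns are ordered
    band block -> segment -> upper-triangle pair, as recorded in the index map.
    """
    if spectral is None:
        spectral = SpectralConfig()
    series = getattr(cohort, "series", cohort)
    series = np.asarray(series, dtype=float)
    if series.ndim != 3:
        raise ValueError("cohort series must be subjects x ROIs x time")
    n_subjects, n_rois, n_time = series.shape
    blocks = list(selected_rois_per_band.items())
    if not blocks or any(len(rois) == 0 for _, rois in blocks):
        raise ValueError("selected ROI lists must be nonempty")
    for band_name, rois in blocks:
        bad = [r for r in rois if not (0 <= r < n_rois)]
        if bad:
            raise ValueError(f"ROI indices out of range for {band_name}: {bad}")
    # a single-ROI block has no pairs and contributes no features
    skipped = [b for b, rois in blocks if len(rois) < 2]
    if skipped:
        logger.warning("band block(s) %s have < 2 ROIs; no pair features", skipped)
    blocks = [(b, rois) for b, rois in blocks if len(rois) >= 2]
    if not blocks:
        raise ValueError("no band block has >= 2 selected ROIs; no pairs to correlate")
    configs = _normalize_configs([b for b, _ in blocks], config)

    scheme_names = set(scheme.band_names)
    index_map: list[tuple[int, int, int, str]] = []
    columns: list[np.ndarray] = []
    for band_name, rois in blocks:
        # filtering band: the block's own band if the scheme carries it,
        # otherwise the scheme's single band (Conventional case)
        if band_name in scheme_names:
            filt = scheme.band(band_name)
        elif len(scheme.bands) == 1:
            filt = scheme.bands[0]
        else:
            raise ValueError(
                f"band block {band_name!r} not in scheme {scheme.label!r}"
            )
        cfg = configs[band_name]
        n_seg = count_segments(n_time, cfg)
        rois = list(rois)
        pairs = [(rois[i], rois[j]) for i in range(len(rois)) for j in range(i + 1, len(rois))]
        block_vals = np.empty((n_subjects, n_seg * len(pairs)))
        for s in range(n_subjects):
            filtered = np.stack(
                [
                    bandpass(
                        series[s, r],
                        filt,
                        padded_length=spectral.padded_length,
                        tr_seconds=spectral.tr_seconds,
                    )
                    for r in rois
                ]
            )
            block_vals[s] = _segment_correlations(filtered, cfg).ravel()
        columns.append(block_vals)
        for seg in range(n_seg):
            for a, b in pairs:
                index_map.append((seg, a, b, band_name))
    values = np.hstack(columns)
    return DfcFeatureMatrix(
        values=values,
        index_map=index_map,
        config=configs,
        scheme=scheme.label,
    )


def mixed_window_features(
    cohort: "SyntheticCohort | np.ndarray",
    selected_rois_per_band: Mapping[str, Sequence[int]],
    scheme: BandScheme,
    config_per_band: Mapping[str, SlidingWindowConfig],
    spectral: SpectralConfig | None = None,
) -> DfcFeatureMatrix:
    """dFC features with a distinct window width per band block.

    Identical to :func:`build_dfc_features` except each band block may use
    its own window configuration, so per-band segment counts can differ;
    blocks are concatenated band-block-wise.  With equal configurations the
    output reduces to ``build_dfc_features``.
    """
    return build_dfc_features(
        cohort, selected_rois_per_band, scheme, dict(config_per_band), spectral
    )


def pairwise_discriminative_counts(
    selected_columns: Sequence[int],
    index_map: Sequence[tuple[int, int, int, str]],
) -> dict[tuple[int, int, str], int]:
    """Per-(ROI pair, band) count of temporal segments among selected features.

    Given the columns a feature-selection step retained, returns for every
    (roi_a, roi_b, band) the number of temporal segments whose window
    correlation was selected.  Counts sum to the number of selected columns.
    """
    counts: dict[tuple[int, int, str], int] = {}
    for col in selected_columns:
        _, a, b, band = index_map[col]
        key = (a, b, band)
        counts[key] = counts.get(key, 0) + 1
    return counts


def counts_to_tsv(counts: Mapping[tuple[int, int, str], int]) -> str:
    """Serialise a pair-count table (band, roi_a, roi_b, count) as TSV."""
    lines = ["band\troi_a\troi_b\tcount"]
    for (a, b, band), c in sorted(counts.items(), key=lambda kv: (kv[0][2], kv[0][0], kv[0][1])):
        lines.append(f"{band}\tROI{a + 1}\tROI{b + 1}\t{c}")
    return "\n".join(lines) + "\n"
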
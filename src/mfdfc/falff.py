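"""ALFF / fALFF amplitude measures and the per-scheme feature matrices.

ALFF (amplitude of low-frequency fluctuations) is the summed spectral
amplitude sqrt(a_k^2 + b_k^2) of a BOLD series over a frequency band,
normalised by the number of original time points.  fALFF is ALFF in the band
divided by ALFF over the full resolvable range (DC excluded) — a
scale-invariant fraction in [0, 1] measuring how much of a region's
fluctuation power lives in that band.

fALFF is computed on the unfiltered series with the band selection applied
inside the spectral sum, not on a pre-band-passed copy, so a series is never
filtered twice.  The amplitude spectrum is taken on the series' native
frequency grid by default: zero-padding redistributes a tone's amplitude
over many fine bins, and because ALFF sums amplitudes (not power) that
redistribution biases the band fraction downward, so padding is left to
callers who explicitly want the interpolated grid.  Voxel-level data are
collapsed to region-of-interest (ROI) time series by averaging before any
amplitude measure is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .bands import BandScheme, FrequencyBand, SpectralConfig, spectrum

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SyntheticCohort

__all__ = [
    "FalffMatrix",
    "alff",
    "falff",
    "roi_average",
    "build_falff_features",
    "falff_feature_id",
]


def falff_feature_id(roi_index: int, band_name: str) -> str:
    """Stable feature id for an (ROI, band) fALFF feature: ``ROI<n>@<band>``.

    ROI indices are 0-based internally; ids use the field's 1-based labels.
    """
    return f"ROI{roi_index + 1}@{band_name}"


@dataclass
class FalffMatrix:
    """Subjects x (ROI, band) fALFF feature table for one band scheme."""

    values: np.ndarray
    index_map: list[tuple[int, str]]  # column -> (roi_index, band_name)
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
        return [falff_feature_id(r, b) for r, b in self.index_map]

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        return df.to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str, scheme: str) -> "FalffMatrix":
        df = pd.read_csv(StringIO(text), sep="\t")
        index_map = []
        for col in df.columns:
            roi, band = col.split("@", 1)
            index_map.append((int(roi.removeprefix("ROI")) - 1, band))
        return cls(values=df.to_numpy(float), index_map=index_map, scheme=scheme)


def alff(
    series: np.ndarray,
    band: FrequencyBand,
    tr_seconds: float = 2.0,
    padded_length: int | None = None,
) -> float:
    """Summed in-band spectral amplitude divided by the series length.

    ``padded_length=None`` (default) uses the series' native frequency grid.
    An all-zero series has zero amplitude everywhere and returns 0.
    """
    x = np.asarray(series, dtype=float)
    if padded_length is None:
        padded_length = x.size
    dec = spectrum(x, padded_length=padded_length, tr_seconds=tr_seconds)
    in_band = (dec.frequencies >= band.f_low) & (dec.frequencies <= band.f_high)
    in_band[0] = False
    return float(dec.amplitudes[in_band].sum() / x.size)


def falff(
    series: np.ndarray,
    band: FrequencyBand,
    tr_seconds: float = 2.0,
    padded_length: int | None = None,
) -> float:
    """In-band amplitude as a fraction of full-range amplitude (DC excluded).

    ``padded_length=None`` (default) uses the series' native frequency grid.
    """
    x = np.asarray(series, dtype=float)
    if padded_length is None:
        padded_length = x.size
    dec = spectrum(x, padded_length=padded_length, tr_seconds=tr_seconds)
    total = float(dec.amplitudes[1:].sum())
    if total <= 0.0:
        raise ValueError("degenerate series: zero total spectral amplitude")
    in_band = (dec.frequencies >= band.f_low) & (dec.frequencies <= band.f_high)
    in_band[0] = False
    return float(dec.amplitudes[in_band].sum() / total)


def roi_average(
    voxel_series: np.ndarray,
    roi_labels: np.ndarray,
    expected_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse voxel time series to per-ROI means.

    Parameters
    ----------
    voxel_series
        voxels x time array.
    roi_labels
        Integer ROI label per voxel; label 0 is background and is ignored.
    expected_labels
        Labels that must each have at least one voxel; an absent label raises.

    Returns
    -------
    (roi_series, labels) with rows in ascending label order.
    """
    vs = np.asarray(voxel_series, dtype=float)
    labels = np.asarray(roi_labels)
    if vs.ndim != 2:
        raise ValueError("voxel_series must be voxels x time")
    if labels.shape[0] != vs.shape[0]:
        raise ValueError(
            f"{labels.shape[0]} labels for {vs.shape[0]} voxel rows"
        )
    present = np.unique(labels[labels > 0])
    if expected_labels is not None:
        missing = np.setdiff1d(np.asarray(expected_labels), present)
        if missing.size:
            raise ValueError(f"ROI label(s) with zero voxels: {missing.tolist()}")
        present = np.asarray(sorted(expected_labels))
    out = np.empty((present.size, vs.shape[1]))
    for i, lab in enumerate(present):
        out[i] = vs[labels == lab].mean(axis=0)
    return out, present


def build_falff_features(
    cohort: "SyntheticCohort | np.ndarray",
    scheme: BandScheme,
    config: SpectralConfig | None = None,
) -> FalffMatrix:
    """Assemble the subjects x (ROI, band) fALFF matrix for one scheme.

    Accepts either a synthetic cohort or a raw subjects x ROIs x time array.
    Feature columns are band-major in scheme order (for the Combined scheme:
    the full Slow-5 block, then the full Slow-4 block), ROI-ascending within
    each block; the ordering is recorded in ``index_map``.
    """
    if config is None:
        config = SpectralConfig()
    series = getattr(cohort, "series", cohort)
    series = np.asarray(series, dtype=float)
    if series.ndim != 3:
        raise ValueError("cohort series must be subjects x ROIs x time")
    n_subjects, n_rois, _ = series.shape
    index_map = [
        (roi, band.name) for band in scheme.bands for roi in range(n_rois)
    ]
    # one rfft per (subject, ROI) on the native grid; every band is a masked
    # sum of the same amplitudes
    n_fft = series.shape[2]
    flat = series.reshape(-1, n_fft)
    spec = np.fft.rfft(flat, n=n_fft, axis=1)
    amps = np.abs(spec)
    amps[:, 0] = 0.0  # DC excluded everywhere
    if n_fft % 2 == 0:
        amps[:, -1] *= 0.5  # Nyquist bin has no mirror; match the a,b amplitudes
    freqs = np.fft.rfftfreq(n_fft, d=config.tr_seconds)
    total = amps.sum(axis=1)
    if np.any(total <= 0.0):
        bad = int(np.argmax(total <= 0.0))
        raise ValueError(
            f"degenerate series (zero total spectral amplitude) at subject "
            f"{bad // n_rois}, ROI {bad % n_rois}"
        )
    values = np.empty((n_subjects, len(index_map)))
    col = 0
    for band in scheme.bands:
        in_band = (freqs >= band.f_low) & (freqs <= band.f_high)
        frac = (amps[:, in_band].sum(axis=1) / total).reshape(n_subjects, n_rois)
        values[:, col : col + n_rois] = frac
        col += n_rois
    return FalffMatrix(values=values, index_map=index_map, scheme=scheme.label)
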
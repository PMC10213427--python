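"""Seeded synthetic BOLD cohorts with known amplitude and connectivity effects.

The generator emits ROI-level time series (a subjects x ROIs x time array)
whose statistical structure matches what the analysis assumes: every ROI
series is a sum of band-limited oscillatory components — one per N3L band
within the resolvable range, each a mixture of random-phase sinusoids — plus
white noise.  Group effects are injected with known ground truth:

* fALFF effects multiply the in-band component amplitude for case subjects
  at designated (ROI, band) targets, shifting that band's fractional
  amplitude upward for cases;
* dFC effects build the in-band components of a designated ROI pair from a
  shared latent signal mixed with weight sqrt(rho), giving the pair an
  expected in-band correlation of rho that differs between groups.

Defaults mirror a balanced case/control resting-state cohort: 46 subjects
per group, 90 ROIs, 142 time points at TR = 2 s.  Everything is
deterministic given the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bands import DEFAULT_PADDED_LENGTH, FrequencyBand, band_table
from .dfc import dfc_feature_id
from .falff import falff_feature_id

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "effect_truth_table",
    "write_cohort",
    "read_cohort",
    "write_cohort_nifti",
]

_N_SINUSOIDS = 8  # random-frequency sinusoids per band-limited component


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort, including the effects to inject.

    ``falff_effects`` entries are (roi_index, band_name, amplitude_multiplier)
    applied to case subjects only; ``dfc_effects`` entries are
    (roi_a, roi_b, band_name, case_correlation, control_correlation).
    """

    n_per_group: int = 46
    n_rois: int = 90
    n_timepoints: int = 142
    tr_seconds: float = 2.0
    falff_effects: tuple[tuple[int, str, float], ...] = ()
    dfc_effects: tuple[tuple[int, int, str, float, float], ...] = ()
    noise_sd: float = 1.0
    subject_amplitude_sd: float = 0.25  # lognormal sigma of per-subject band amplitudes
    seed: int = 0
    shuffle_subjects: bool = False
    min_window_width: int = 30  # largest window the downstream analysis will use

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if self.n_rois < 2:
            raise ValueError(f"n_rois must be >= 2, got {self.n_rois}")
        if self.n_timepoints < 2 * self.min_window_width:
            raise ValueError(
                f"n_timepoints ({self.n_timepoints}) must be >= twice the largest "
                f"window width ({self.min_window_width})"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.subject_amplitude_sd < 0:
            raise ValueError(
                f"subject_amplitude_sd must be >= 0, got {self.subject_amplitude_sd}"
            )
        band_names = {b.name for b in self.bands()}
        for roi, band, mult in self.falff_effects:
            if not 0 <= roi < self.n_rois:
                raise ValueError(f"falff_effect roi_index {roi} out of range")
            if band not in band_names:
                raise ValueError(f"falff_effect band {band!r} not resolvable")
            if mult <= 0:
                raise ValueError(f"amplitude multiplier must be > 0, got {mult}")
        for a, b, band, rc, cc in self.dfc_effects:
            for roi in (a, b):
                if not 0 <= roi < self.n_rois:
                    raise ValueError(f"dfc_effect roi_index {roi} out of range")
            if a == b:
                raise ValueError("dfc_effect requires two distinct ROIs")
            if band not in band_names:
                raise ValueError(f"dfc_effect band {band!r} not resolvable")
            for rho in (rc, cc):
                if not -1.0 <= rho <= 1.0:
                    raise ValueError(f"correlation {rho} outside [-1, 1]")

    def bands(self) -> list[FrequencyBand]:
        return band_table(
            self.tr_seconds, self.n_timepoints, DEFAULT_PADDED_LENGTH
        )

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_per_group


@dataclass
class SyntheticCohort:
    """Generated series, group labels, and the effects actually injected."""

    series: np.ndarray  # subjects x ROIs x time
    labels: np.ndarray  # 1 = case, 0 = control
    truth: CohortSpec

    def __post_init__(self) -> None:
        spec = self.truth
        expect = (spec.n_subjects, spec.n_rois, spec.n_timepoints)
        if self.series.shape != expect:
            raise ValueError(f"series shape {self.series.shape} != spec {expect}")
        if self.labels.shape != (spec.n_subjects,):
            raise ValueError("one label per subject required")
        if int(self.labels.sum()) != spec.n_per_group:
            raise ValueError("labels must be balanced per spec")

    @property
    def tr_seconds(self) -> float:
        return self.truth.tr_seconds


def _band_component(
    rng: np.random.Generator, band: FrequencyBand, t: np.ndarray
) -> np.ndarray:
    """Unit-std sum of random-phase sinusoids at frequencies inside the band."""
    freqs = rng.uniform(band.f_low, band.f_high, size=_N_SINUSOIDS)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=_N_SINUSOIDS)
    comp = np.cos(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    sd = comp.std()
    return comp / sd if sd > 0 else comp


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a seeded synthetic cohort per the spec.

    Each ROI series sums one band-limited component per N3L band in range
    (amplitude lognormal around 1 with sigma ``subject_amplitude_sd``,
    emulating between-subject variability) plus Gaussian noise of
    ``noise_sd``.  Case subjects get
    amplitude multipliers at the fALFF-effect targets; dFC-effect pairs
    share a latent in-band component mixed with weight sqrt(rho) so their
    expected in-band correlation is the group's stated rho.  Identical
    specs (including the seed) produce bit-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    bands = spec.bands()
    t = np.arange(spec.n_timepoints) * spec.tr_seconds
    n_sub = spec.n_subjects

    labels = np.concatenate(
        [np.ones(spec.n_per_group, dtype=int), np.zeros(spec.n_per_group, dtype=int)]
    )

    amp_boost: dict[tuple[int, str], float] = {
        (roi, band): mult for roi, band, mult in spec.falff_effects
    }
    series = np.empty((n_sub, spec.n_rois, spec.n_timepoints))
    for s in range(n_sub):
        is_case = labels[s] == 1
        # one shared latent component per dfc-effect pair, per subject
        latents = {
            (a, b, band): _band_component(rng, _band_by_name(bands, band), t)
            for a, b, band, _, _ in spec.dfc_effects
        }
        for roi in range(spec.n_rois):
            sig = np.zeros(spec.n_timepoints)
            for band in bands:
                member = None
                for a, b, bname, rho_case, rho_ctrl in spec.dfc_effects:
                    if bname == band.name and roi in (a, b):
                        member = (a, b, bname, rho_case, rho_ctrl)
                        break
                if member is not None:
                    a, b, bname, rho_case, rho_ctrl = member
                    rho = rho_case if is_case else rho_ctrl
                    shared = latents[(a, b, bname)]
                    own = _band_component(rng, band, t)
                    sgn = np.sign(rho) if roi == b and rho < 0 else 1.0
                    comp = (
                        np.sqrt(abs(rho)) * sgn * shared
                        + np.sqrt(1.0 - abs(rho)) * own
                    )
                else:
                    comp = _band_component(rng, band, t)
                # between-subject variability: real cohorts differ in band
                # amplitude even without a group effect
                amp = rng.lognormal(0.0, spec.subject_amplitude_sd) if spec.subject_amplitude_sd > 0 else 1.0
                if is_case:
                    amp *= amp_boost.get((roi, band.name), 1.0)
                sig += amp * comp
            sig += rng.normal(0.0, spec.noise_sd, size=spec.n_timepoints)
            series[s, roi] = sig

    if spec.shuffle_subjects:
        perm = np.random.default_rng(spec.seed + 1).permutation(n_sub)
        series = series[perm]
        labels = labels[perm]

    return SyntheticCohort(series=series, labels=labels, truth=spec)


def _band_by_name(bands: list[FrequencyBand], name: str) -> FrequencyBand:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(name)


def effect_truth_table(cohort: SyntheticCohort) -> list[tuple[str, str]]:
    """Machine-readable ground truth: (feature_id, expected_direction) rows.

    fALFF effects map to ``ROI<n>@<band>`` ids (direction ``case>control``
    for multipliers above 1); dFC effects map to pair-level
    ``<band>:ROI<a>-ROI<b>`` ids whose direction is the sign of
    case_correlation - control_correlation.  The ids resolve in the feature
    matrices' index maps (dFC pair ids match every segment-level column for
    that pair and band).
    """
    rows: list[tuple[str, str]] = []
    for roi, band, mult in cohort.truth.falff_effects:
        direction = "case>control" if mult > 1.0 else "case<control"
        rows.append((falff_feature_id(roi, band), direction))
    for a, b, band, rho_case, rho_ctrl in cohort.truth.dfc_effects:
        lo, hi = min(a, b), max(a, b)
        direction = "case>control" if rho_case > rho_ctrl else "case<control"
        rows.append((f"{band}:ROI{lo + 1}-ROI{hi + 1}", direction))
    return rows


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write per-subject TSV series, a labels TSV and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_digits = len(str(cohort.series.shape[0]))
    for s in range(cohort.series.shape[0]):
        np.savetxt(
            outdir / f"sub-{s:0{n_digits}d}_series.tsv",
            cohort.series[s].T,
            delimiter="\t",
            header="\t".join(f"ROI{r + 1}" for r in range(cohort.series.shape[1])),
            comments="",
        )
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("subject\tgroup\n")
        for s, lab in enumerate(cohort.labels):
            fh.write(f"sub-{s:0{n_digits}d}\t{'case' if lab else 'control'}\n")
    spec = cohort.truth
    truth = {
        "n_per_group": spec.n_per_group,
        "n_rois": spec.n_rois,
        "n_timepoints": spec.n_timepoints,
        "tr_seconds": spec.tr_seconds,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "falff_effects": [list(e) for e in spec.falff_effects],
        "dfc_effects": [list(e) for e in spec.dfc_effects],
        "truth_table": [list(r) for r in effect_truth_table(cohort)],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)


def read_cohort(outdir: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    spec = CohortSpec(
        n_per_group=truth["n_per_group"],
        n_rois=truth["n_rois"],
        n_timepoints=truth["n_timepoints"],
        tr_seconds=truth["tr_seconds"],
        noise_sd=truth["noise_sd"],
        seed=truth["seed"],
        falff_effects=tuple(tuple(e) for e in truth["falff_effects"]),
        dfc_effects=tuple(tuple(e) for e in truth["dfc_effects"]),
    )
    import pandas as pd

    labels_df = pd.read_csv(outdir / "labels.tsv", sep="\t")
    labels = (labels_df["group"] == "case").to_numpy(int)
    series = np.empty((spec.n_subjects, spec.n_rois, spec.n_timepoints))
    for s, sub in enumerate(labels_df["subject"]):
        df = pd.read_csv(outdir / f"{sub}_series.tsv", sep="\t")
        series[s] = df.to_numpy(float).T
    return SyntheticCohort(series=series, labels=labels, truth=spec)


def write_cohort_nifti(
    cohort: SyntheticCohort,
    outdir: str | Path,
    extra_volumes: int = 0,
    grid_shape: tuple[int, int, int] | None = None,
) -> tuple[list[Path], Path]:
    """Write one 4-D NIfTI per subject plus a matching integer-label atlas.

    Exercises the real-data reader path: voxels within an ROI are constant
    (equal to the ROI series), label 0 is background.  ``extra_volumes``
    prepends constant dummy volumes so initial-volume removal can be tested.
    Returns (subject image paths, atlas path).
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_sub, n_rois, n_time = cohort.series.shape
    if grid_shape is None:
        side = int(np.ceil(n_rois ** (1.0 / 3.0))) + 1
        grid_shape = (side, side, side)
    if np.prod(grid_shape) < n_rois + 1:
        raise ValueError("grid too small to place every ROI plus background")
    atlas = np.zeros(grid_shape, dtype=np.int16)
    flat = atlas.ravel()
    flat[1 : n_rois + 1] = np.arange(1, n_rois + 1)  # voxel 0 stays background
    atlas_path = outdir / "atlas.nii"
    nib.save(nib.Nifti1Image(atlas, np.eye(4)), atlas_path)

    paths: list[Path] = []
    n_digits = len(str(n_sub))
    for s in range(n_sub):
        vol = np.zeros(grid_shape + (extra_volumes + n_time,), dtype=np.float64)
        for roi in range(n_rois):
            mask = atlas == roi + 1
            vol[mask, extra_volumes:] = cohort.series[s, roi]
            if extra_volumes:
                vol[mask, :extra_volumes] = cohort.series[s, roi, 0]
        img = nib.Nifti1Image(vol, np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, cohort.tr_seconds))
        p = outdir / f"sub-{s:0{n_digits}d}_bold.nii"
        nib.save(img, p)
        paths.append(p)
    return paths, atlas_path
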
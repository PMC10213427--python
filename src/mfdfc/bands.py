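"""Natural-logarithm (N3L) frequency bands and ideal-mask band-pass filtering.

The N3L partition divides the BOLD frequency axis into oscillation classes
("Slow-k" bands) whose boundaries form a geometric ladder with neighbouring
ratio e: band edges sit at e^(1/2 - k) Hz, so Slow-4 spans
[e^-3.5, e^-2.5] ~ [0.0302, 0.0821] Hz and Slow-5 spans
[e^-4.5, e^-3.5] ~ [0.0111, 0.0302] Hz.  Applied to a sampled series the
ladder is clipped to what the acquisition can resolve: the top edge to the
Nyquist frequency 1/(2 TR) and the bottom edge to a minimal reliable
frequency below which estimates are dominated by drift.

Band-passing is done by zero-padding the series, taking a forward discrete
Fourier transform, zeroing every coefficient whose frequency falls outside
the band (an ideal rectangular mask; the DC term is always removed), inverse
transforming, and truncating back to the original length.  Zero-padding
raises the frequency resolution of the mask, which is what makes the narrow
low-frequency bands separable at typical fMRI series lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyBand",
    "BandScheme",
    "SpectralDecomposition",
    "SpectralConfig",
    "nyquist",
    "n3l_band_limits",
    "conservative_lowest_frequency",
    "band_table",
    "make_scheme",
    "bandpass",
    "spectrum",
    "band_table_tsv",
    "DEFAULT_PADDED_LENGTH",
    "DEFAULT_MIN_RELIABLE_HZ",
    "CONVENTIONAL_BAND",
]

#: Default zero-padded transform length (2**12 samples).
DEFAULT_PADDED_LENGTH = 4096

#: Default minimal reliable frequency in Hz below which band edges are clipped.
DEFAULT_MIN_RELIABLE_HZ = 7.32e-4

_REL_TOL = 1e-12


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency interval in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )

    @property
    def width(self) -> float:
        return self.f_high - self.f_low

    def contains(self, freq: float) -> bool:
        return self.f_low <= freq <= self.f_high


#: The conventional resting-state band used by most single-band analyses.
CONVENTIONAL_BAND = FrequencyBand("Conventional", 0.01, 0.08)


@dataclass(frozen=True)
class BandScheme:
    """An ordered set of frequency bands under a scheme label.

    The ``Combined`` scheme is the ordered pair [Slow-5, Slow-4]; the
    ``Conventional`` scheme is the single literal 0.01-0.08 Hz band.
    """

    label: str
    bands: tuple[FrequencyBand, ...]

    def band(self, name: str) -> FrequencyBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"scheme {self.label!r} has no band {name!r}")

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)


@dataclass(frozen=True)
class SpectralConfig:
    """Sampling and transform parameters shared by the spectral operations."""

    tr_seconds: float = 2.0
    padded_length: int = DEFAULT_PADDED_LENGTH
    min_reliable_hz: float = DEFAULT_MIN_RELIABLE_HZ

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.padded_length < 2:
            raise ValueError(f"padded_length must be >= 2, got {self.padded_length}")

    @property
    def nyquist_hz(self) -> float:
        return nyquist(self.tr_seconds)


@dataclass
class SpectralDecomposition:
    """Cosine/sine amplitudes of a zero-padded series on its frequency grid.

    The padded series is x(t) = sum_k [a_k cos(2 pi f_k t) + b_k sin(2 pi f_k t)]
    with f_k = k / (padded_length * TR).
    """

    frequencies: np.ndarray
    cosine: np.ndarray
    sine: np.ndarray
    padded_length: int
    tr_seconds: float
    amplitudes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (len(self.frequencies) == len(self.cosine) == len(self.sine)):
            raise ValueError("frequency grid and amplitude arrays must align")
        self.amplitudes = np.hypot(self.cosine, self.sine)

    def reconstruct(self) -> np.ndarray:
        """Evaluate the trigonometric sum on the padded time grid."""
        t = np.arange(self.padded_length) * self.tr_seconds
        arg = 2.0 * np.pi * np.outer(self.frequencies, t)
        return self.cosine @ np.cos(arg) + self.sine @ np.sin(arg)


def nyquist(tr_seconds: float) -> float:
    """Highest frequency resolvable at sampling interval ``tr_seconds``: 1/(2 TR)."""
    if tr_seconds <= 0:
        raise ValueError(f"tr_seconds must be positive, got {tr_seconds}")
    return 1.0 / (2.0 * tr_seconds)


def conservative_lowest_frequency(
    padded_length: int = DEFAULT_PADDED_LENGTH, tr_seconds: float = 2.0
) -> float:
    """Conservative lowest resolvable frequency, 1/(padded_length * TR / 2) Hz.

    With the default 4096-point padding at TR = 2 s this is 2.44e-4 Hz.
    """
    if padded_length < 2 or tr_seconds <= 0:
        raise ValueError("padded_length >= 2 and tr_seconds > 0 required")
    return 1.0 / (padded_length * tr_seconds / 2.0)


def n3l_band_limits(band_index: int) -> tuple[float, float]:
    """Theoretical (unclipped) boundaries of the Slow-``band_index`` band in Hz.

    The ladder places edges at e^(1/2 - k): Slow-2 spans [e^-1.5, e^-0.5],
    Slow-3 [e^-2.5, e^-1.5], Slow-4 [e^-3.5, e^-2.5], and so on; each band is
    exactly a factor e wide.
    """
    k = int(band_index)
    if k < 2:
        raise ValueError(f"band index must be >= 2, got {band_index}")
    return math.exp(0.5 - k), math.exp(1.5 - k)


def band_table(
    tr_seconds: float,
    n_timepoints: int,
    padded_length: int = DEFAULT_PADDED_LENGTH,
    min_reliable_hz: float = DEFAULT_MIN_RELIABLE_HZ,
) -> list[FrequencyBand]:
    """N3L bands clipped to what the acquisition resolves, ordered low to high.

    Bands falling entirely outside [min_reliable_hz, nyquist] are dropped;
    the lowest surviving band's lower edge is clipped up to the minimal
    reliable frequency and the highest band's upper edge down to Nyquist.
    At TR = 2 s this yields the seven bands Slow-8 through Slow-2.
    """
    if padded_length < n_timepoints:
        raise ValueError(
            f"padded_length ({padded_length}) must be >= n_timepoints ({n_timepoints})"
        )
    f_nyq = nyquist(tr_seconds)
    if min_reliable_hz <= 0 or min_reliable_hz >= f_nyq:
        raise ValueError(
            f"min_reliable_hz must lie in (0, nyquist={f_nyq}), got {min_reliable_hz}"
        )
    bands: list[FrequencyBand] = []
    k = 2
    while True:
        lo, hi = n3l_band_limits(k)
        if hi <= min_reliable_hz:
            break
        if lo < f_nyq:  # drop bands entirely above nyquist
            bands.append(
                FrequencyBand(f"Slow-{k}", max(lo, min_reliable_hz), min(hi, f_nyq))
            )
        k += 1
    bands.reverse()
    if not bands:
        raise ValueError("no N3L band intersects the resolvable frequency range")
    return bands


def make_scheme(
    label: str,
    tr_seconds: float = 2.0,
    n_timepoints: int = 142,
    padded_length: int = DEFAULT_PADDED_LENGTH,
) -> BandScheme:
    """Build one of the named band schemes: Conventional, Slow-5, Slow-4, Combined."""
    table = {b.name: b for b in band_table(tr_seconds, n_timepoints, padded_length)}
    if label == "Conventional":
        return BandScheme("Conventional", (CONVENTIONAL_BAND,))
    if label in ("Slow-5", "Slow-4"):
        return BandScheme(label, (table[label],))
    if label == "Combined":
        return BandScheme("Combined", (table["Slow-5"], table["Slow-4"]))
    raise ValueError(
        f"unknown scheme {label!r}; expected Conventional, Slow-5, Slow-4 or Combined"
    )


def _frequency_mask(
    band: FrequencyBand, freqs: np.ndarray, f_nyq: float
) -> np.ndarray:
    """Boolean keep-mask on the one-sided grid: [f_low, f_high) half-open,
    closed at the top when the band reaches Nyquist; DC always excluded."""
    keep = (freqs >= band.f_low * (1 - _REL_TOL)) & (
        freqs < band.f_high * (1 - _REL_TOL)
    )
    if band.f_high >= f_nyq * (1 - 1e-9):
        keep |= np.isclose(freqs, f_nyq, rtol=1e-9)
    keep[0] = False
    return keep


def bandpass(
    series: np.ndarray,
    band: FrequencyBand,
    padded_length: int = DEFAULT_PADDED_LENGTH,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Ideal-mask band-pass by zero-padded forward/inverse Fourier transform.

    Zero-pads ``series`` to ``padded_length``, zeroes every spectral
    coefficient outside ``band`` (DC always removed, conjugate symmetry
    preserved so the output is real), inverse transforms and truncates to the
    input length.  Edge ringing from the rectangular mask is expected; callers
    comparing against analytic signals should trim window edges.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-D, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = x.size
    if padded_length < n:
        raise ValueError(f"padded_length {padded_length} < series length {n}")
    f_nyq = nyquist(tr_seconds)
    if band.f_high > f_nyq * (1 + 1e-9):
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_high} exceeds nyquist {f_nyq}"
        )
    freqs = np.fft.rfftfreq(padded_length, d=tr_seconds)
    keep = _frequency_mask(band, freqs, f_nyq)
    if not keep.any():
        raise ValueError(
            f"band {band.name!r} contains no frequency-grid point at "
            f"padded_length={padded_length}, TR={tr_seconds}"
        )
    # demean before padding: a nonzero mean would become a boxcar step with
    # broadband leakage once zeros are appended
    spec = np.fft.rfft(x - x.mean(), n=padded_length)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=padded_length)[:n]


def spectrum(
    series: np.ndarray,
    padded_length: int = DEFAULT_PADDED_LENGTH,
    tr_seconds: float = 2.0,
) -> SpectralDecomposition:
    """Cosine/sine amplitude decomposition of the zero-padded series.

    Returns a_k, b_k on the grid f_k = k/(padded_length * TR) such that
    ``SpectralDecomposition.reconstruct`` reproduces the padded series.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-D, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if padded_length < x.size:
        raise ValueError(f"padded_length {padded_length} < series length {x.size}")
    spec = np.fft.rfft(x, n=padded_length)
    freqs = np.fft.rfftfreq(padded_length, d=tr_seconds)
    a = 2.0 * spec.real / padded_length
    b = -2.0 * spec.imag / padded_length
    a[0] = spec[0].real / padded_length  # DC has no mirror
    b[0] = 0.0
    if padded_length % 2 == 0:  # Nyquist bin is its own mirror
        a[-1] = spec[-1].real / padded_length
        b[-1] = 0.0
    return SpectralDecomposition(
        frequencies=freqs,
        cosine=a,
        sine=b,
        padded_length=padded_length,
        tr_seconds=tr_seconds,
    )


def band_table_tsv(bands: list[FrequencyBand]) -> str:
    """Serialize a band table as TSV text (name, f_low, f_high)."""
    lines = ["name\tf_low\tf_high"]
    lines += [f"{b.name}\t{b.f_low:.10g}\t{b.f_high:.10g}" for b in bands]
    return "\n".join(lines) + "\n"
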
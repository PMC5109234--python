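"""Structure-related sway parameters: ApEn, fractal dimension, MPF.

These parameters describe the temporal/spatial organisation of the sway
rather than its amplitude:

* Approximate entropy (ApEn) of each axis — the Pincus regularity statistic
  with delayed embedding: templates ``u_i = (x_i, x_{i+lag}, ...,
  x_{i+(m-1)lag})``, match tolerance ``r = r_factor * SD(x)`` under the
  Chebyshev distance, self-matches included.  ``ApEn = Phi_m - Phi_{m+1}``
  with ``Phi_m = mean_i ln C_i^m(r)``.  Low values mean predictable sway.
* Stabilogram fractal dimension ``FD = ln(N) / ln(N d / SP)`` where ``N``
  is the number of points, ``SP`` the 2-D sway path and ``d`` the planar
  extent taken from the 95% confidence ellipse axes; FD = 1 for a straight
  line and grows toward 2 for plane-filling trajectories.
* Mean power frequency (MPF) of each axis — the power-weighted mean
  frequency of a multitaper PSD, computed from the *unfiltered* series and
  restricted to a 0.025-Hz-binned band up to 1.5 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from .errors import ValidationError
from .forceplate import COPTrajectory
from .stability import ConfidenceEllipse, confidence_ellipse, sway_path_2d

__all__ = [
    "ApEnSpec",
    "PsdEstimate",
    "StructureMetrics",
    "approximate_entropy",
    "fractal_dimension",
    "multitaper_psd",
    "mean_power_frequency",
    "structure_set",
]


@dataclass(frozen=True)
class ApEnSpec:
    """ApEn parameters: pattern length ``m``, tolerance factor on the SD,
    embedding delay ``lag`` in samples."""

    m: int = 2
    r_factor: float = 0.2
    lag: int = 10

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError("pattern length m must be >= 1")
        if self.r_factor <= 0:
            raise ValidationError("tolerance factor must be positive")
        if self.lag < 1:
            raise ValidationError("lag must be >= 1")


@dataclass(frozen=True)
class PsdEstimate:
    """Binned one-sided PSD: ``freqs`` are bin centers (Hz) on a uniform
    grid, ``power`` the mean PSD amplitude per bin, ``band`` the retained
    frequency range."""

    freqs: np.ndarray
    power: np.ndarray
    band: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if len(self.freqs) != len(self.power) or len(self.freqs) == 0:
            raise ValidationError("freqs and power must be equal-length, non-empty")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValidationError("power must be non-negative")


@dataclass(frozen=True)
class StructureMetrics:
    apen_ap: float
    apen_ml: float
    fd: float
    mpf_ap: float
    mpf_ml: float


# --- ApEn kernels ----------------------------------------------------------
# The O(n^2) template count is the hot loop of the whole pipeline
# (two axes x ~10^8 pairs per trial); a numba kernel keeps it fast, with a
# chunked numpy path as fallback.

def _phi_numpy(x: np.ndarray, m: int, lag: int, r: float) -> float:
    n = len(x) - (m - 1) * lag
    emb = np.stack([x[k * lag: k * lag + n] for k in range(m)], axis=1)
    counts = np.zeros(n, dtype=np.int64)
    block = 512
    for start in range(0, n, block):
        d = np.abs(emb[start:start + block, None, :] - emb[None, :, :]).max(axis=2)
        counts[start:start + block] = np.count_nonzero(d <= r, axis=1)
    return float(np.mean(np.log(counts / n)))


try:  # pragma: no cover - exercised indirectly
    import numba

    @numba.njit(cache=True, fastmath=False)
    def _phi_numba(x, m, lag, r):  # pragma: no cover - compiled
        n = len(x) - (m - 1) * lag
        counts = np.ones(n, dtype=np.int64)  # self-matches
        for i in range(n):
            for j in range(i + 1, n):
                d = 0.0
                for k in range(m):
                    diff = abs(x[i + k * lag] - x[j + k * lag])
                    if diff > d:
                        d = diff
                if d <= r:
                    counts[i] += 1
                    counts[j] += 1
        total = 0.0
        for i in range(n):
            total += np.log(counts[i] / n)
        return total / n

    _phi = _phi_numba
except ImportError:  # pragma: no cover
    _phi = _phi_numpy


def approximate_entropy(series, spec: ApEnSpec | None = None) -> float:
    """Pincus approximate entropy with delayed embedding.

    ``r`` is normalised to ``r_factor`` times the (population) SD of the
    series, which makes the statistic invariant to affine rescaling of the
    input.  Self-matches are counted, so every ``C_i >= 1/N`` and the logs
    are always defined.
    """
    spec = spec or ApEnSpec()
    x = np.ascontiguousarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("series must be 1-D")
    if len(x) <= (spec.m + 1) * spec.lag + 1:
        raise ValidationError(
            f"series too short for ApEn: {len(x)} samples, need > "
            f"{(spec.m + 1) * spec.lag + 1}"
        )
    sd = float(np.std(x))
    if sd == 0:
        raise ValidationError("zero-variance series: ApEn tolerance undefined")
    r = spec.r_factor * sd
    return float(_phi(x, spec.m, spec.lag, r) - _phi(x, spec.m + 1, spec.lag, r))


# --- Fractal dimension -----------------------------------------------------

def fractal_dimension(
    n: int,
    ellipse: ConfidenceEllipse,
    sp: float,
    d_convention: str = "semi_axes",
) -> float:
    """Stabilogram fractal dimension ``FD = ln(n) / ln(n * d / sp)``.

    ``d`` is the geometric-mean diameter of the 95% confidence ellipse.
    With ``d_convention="semi_axes"`` (default) the ellipse's stored
    semi-axes a, b give ``d = sqrt(2a * 2b) = 2 sqrt(ab)``; with
    ``"full_axes"`` the axes entering the product are the full diameters,
    ``d = sqrt(2*(2a) * 2*(2b)) = 4 sqrt(ab)``.
    """
    if n < 2:
        raise ValidationError("fractal dimension needs n >= 2 points")
    if sp <= 0:
        raise ValidationError("sway path must be positive")
    if d_convention == "semi_axes":
        d = 2.0 * np.sqrt(ellipse.a * ellipse.b)
    elif d_convention == "full_axes":
        d = 4.0 * np.sqrt(ellipse.a * ellipse.b)
    else:
        raise ValidationError(f"unknown d_convention {d_convention!r}")
    if d <= 0:
        raise ValidationError("planar extent d must be positive")
    denom = np.log(n * d / sp)
    if denom == 0:
        raise ValidationError("degenerate FD: n*d equals the sway path")
    fd = float(np.log(n) / denom)
    if not 0 <= fd <= 2:
        warnings.warn(
            f"fractal dimension {fd:.3f} outside the nominal [0, 2] range",
            RuntimeWarning,
            stacklevel=2,
        )
    return fd


# --- Multitaper PSD and MPF ------------------------------------------------

def multitaper_psd(
    series,
    fs: float,
    nw: float = 3.0,
    k: int = 5,
    bin_hz: float = 0.025,
    band: tuple[float, float] = (0.025, 1.5),
    include_first_bin: bool = False,
    min_len: int = 1000,
) -> PsdEstimate:
    """Multitaper (Slepian) PSD aggregated onto a uniform frequency-bin grid.

    The mean is removed, ``k`` DPSS eigenspectra with time-bandwidth
    product ``nw`` are averaged, and native FFT frequencies are averaged
    into bins of width ``bin_hz`` whose centers span the requested band.
    The first bin past DC is dropped unless ``include_first_bin`` is set,
    so the default retained grid runs from 0.05 Hz to 1.5 Hz.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("series must be 1-D")
    if len(x) < min_len:
        raise ValidationError(f"series too short for PSD: {len(x)} < {min_len}")
    if not fs > 3.0:
        raise ValidationError("sampling rate must exceed 3 Hz for the sway band")
    if band[1] >= fs / 2:
        raise ValidationError("band upper edge must be below Nyquist")
    x = x - x.mean()
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(n)))
    tapers = dpss(n, nw, Kmax=k)  # rows normalised to unit energy
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], n=nfft)) ** 2
    psd = spectra.mean(axis=0) / fs
    psd[1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)

    first = 2 if not include_first_bin else 1
    centers = np.arange(1, int(round(band[1] / bin_hz)) + 1) * bin_hz
    centers = centers[first - 1:]
    power = np.empty(len(centers))
    for i, c in enumerate(centers):
        sel = (freqs > c - bin_hz / 2) & (freqs <= c + bin_hz / 2)
        if not np.any(sel):
            raise ValidationError(
                f"no native frequencies fall in the {c:.3f} Hz bin; "
                "series too short for this bin width"
            )
        power[i] = psd[sel].mean()
    if not np.any(power > 0):
        raise ValidationError("zero total power in the retained band")
    return PsdEstimate(freqs=centers, power=power, band=(centers[0], centers[-1]))


def mean_power_frequency(psd: PsdEstimate) -> float:
    """Power-weighted mean frequency over the retained bins (Hz)."""
    total = float(np.sum(psd.power))
    if total <= 0:
        raise ValidationError("zero total power: MPF undefined")
    return float(np.sum(psd.freqs * psd.power) / total)


def structure_set(
    filtered: COPTrajectory,
    raw: COPTrajectory,
    apen_spec: ApEnSpec | None = None,
    coverage: float = 0.95,
    d_convention: str = "semi_axes",
    nw: float = 3.0,
    k: int = 5,
    bin_hz: float = 0.025,
    band: tuple[float, float] = (0.025, 1.5),
    include_first_bin: bool = False,
) -> StructureMetrics:
    """Bundle the five structure parameters for one trial.

    ApEn and FD are computed from the filtered trajectory; the PSD feeding
    the MPF is computed from the raw (unfiltered) trajectory.
    """
    if len(filtered) != len(raw):
        raise ValidationError("filtered and raw trajectories must be aligned")
    apen_spec = apen_spec or ApEnSpec()
    ellipse = confidence_ellipse(filtered, coverage)
    sp = sway_path_2d(filtered)
    fd = fractal_dimension(len(filtered), ellipse, sp, d_convention)
    mpf = {}
    for axis in ("AP", "ML"):
        psd = multitaper_psd(
            raw.axis(axis), raw.fs, nw=nw, k=k, bin_hz=bin_hz, band=band,
            include_first_bin=include_first_bin,
        )
        mpf[axis] = mean_power_frequency(psd)
    return StructureMetrics(
        apen_ap=approximate_entropy(filtered.ap, apen_spec),
        apen_ml=approximate_entropy(filtered.ml, apen_spec),
        fd=fd,
        mpf_ap=mpf["AP"],
        mpf_ml=mpf["ML"],
    )
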
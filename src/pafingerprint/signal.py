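"""Deterministic PA signal processing.

FFT spectra (one-sided magnitude, no window by default — the records are
gated transients), dominant-peak search, band-power SNR, onset-based delay
estimation, linear-region concentration fitting, and cosine spectral-library
matching.

Conventions
-----------
* Spectrum: ``magnitudes[k] = |rfft(x)[k]|`` on the uniform grid
  ``0 .. Nyquist``. Parseval: ``sum(x**2) = (1/N) * sum(w_k * M_k**2)``
  with weights ``w_k = 2`` except ``w_0 = 1`` and, for even N, the Nyquist
  weight is 1.
* SNR (dB): ``10*log10(P_signal_band / P_noise_total)`` where the
  broadband noise power extrapolates the noise-band power density over the
  full 0..Nyquist band. For a tone in the signal band over white noise this
  reduces to ``20*log10(rms_tone / rms_noise)``.
* Onset: first of 3 consecutive samples exceeding ``5 x`` a robust
  (median-absolute-deviation) noise scale.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .synth import DEFAULT_NOISE_BAND, DEFAULT_PEAK_BAND, MHZ, PASignal

__all__ = [
    "Spectrum",
    "FingerprintLibrary",
    "SNRReport",
    "ConcentrationFit",
    "compute_spectrum",
    "dominant_peak",
    "estimate_snr",
    "estimate_delay",
    "fit_concentration_response",
    "match_spectrum",
    "build_library",
    "resample_magnitudes",
    "DEFAULT_PEAK_BAND",
    "DEFAULT_NOISE_BAND",
    "SNR_CAP_DB",
    "ONSET_THRESHOLD_K",
    "ONSET_RUN_LENGTH",
]

# DEFAULT_PEAK_BAND (1-10 MHz: all observed PA peaks sit near 4 MHz) and
# DEFAULT_NOISE_BAND (20-40 MHz noise floor) are defined in synth so the
# generator can calibrate against the same convention; re-exported here.
#: Reported SNR for a noiseless record instead of +inf.
SNR_CAP_DB = 200.0
#: Onset detection: threshold multiplier over the robust noise scale and the
#: number of consecutive supra-threshold samples required.
ONSET_THRESHOLD_K = 5.0
ONSET_RUN_LENGTH = 3


class SignalError(ValueError):
    """Invalid signal-processing input."""


class DelayNotDetected(SignalError):
    """No onset crossing found; distinct from a numeric zero delay."""


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum on a uniform frequency grid."""

    frequencies: np.ndarray
    magnitudes: np.ndarray
    source: str = ""
    normalization: str = "raw"  # {"raw", "unit-energy"}

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if f.size != m.size:
            raise SignalError("frequencies and magnitudes must have equal length")
        if f.size < 2 or f[0] != 0.0 or np.any(np.diff(f) <= 0):
            raise SignalError("frequency grid must start at 0 and strictly increase")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise SignalError("magnitudes must be finite and non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitudes", m)

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def unit_energy(self) -> "Spectrum":
        """Return a copy scaled to unit L2 norm."""
        norm = float(np.linalg.norm(self.magnitudes))
        if norm == 0:
            raise SignalError("cannot unit-energy-normalize an all-zero spectrum")
        return Spectrum(
            self.frequencies, self.magnitudes / norm, self.source, "unit-energy"
        )

    def __len__(self) -> int:
        return self.magnitudes.size


@dataclass(frozen=True)
class SNRReport:
    snr_db: float
    signal_band: tuple[float, float]
    noise_band: tuple[float, float]


@dataclass(frozen=True)
class ConcentrationFit:
    """OLS fit of the linear region of an amplitude-vs-concentration series."""

    slope: float
    intercept: float
    linear_region: tuple[int, int]  # half-open index range [start, stop)
    r_squared: float


@dataclass
class FingerprintLibrary:
    """Reference PA fingerprints on one shared frequency grid."""

    entries: list[tuple[str, Spectrum]]
    similarity_metric: str = "cosine"

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise SignalError("library labels must be unique")
        if self.entries:
            grid = self.entries[0][1].frequencies
            for lab, spec in self.entries[1:]:
                if spec.frequencies.size != grid.size or not np.allclose(
                    spec.frequencies, grid
                ):
                    raise SignalError(f"library entry {lab!r} is on a different grid")

    @property
    def grid(self) -> np.ndarray:
        if not self.entries:
            raise SignalError("empty library has no grid")
        return self.entries[0][1].frequencies

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.entries]


# --------------------------------------------------------------------------

def compute_spectrum(signal: PASignal, normalization: str = "raw") -> Spectrum:
    """One-sided FFT magnitude spectrum of a PA trace.

    No window is applied: the records are gated transients that decay to
    the noise floor well before the end of the acquisition.
    """
    x = np.asarray(signal.samples, dtype=float)
    if x.size < 64:
        raise SignalError(f"need >= 64 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise SignalError("samples must be finite")
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / signal.sampling_rate)
    src = hashlib.sha256(x.tobytes()).hexdigest()[:16]
    spec = Spectrum(freqs, mags, source=src, normalization="raw")
    if normalization == "unit-energy":
        return spec.unit_energy()
    if normalization != "raw":
        raise SignalError(f"unknown normalization {normalization!r}")
    return spec


def band_power(spectrum: Spectrum, lo: float, hi: float, n_samples: int | None = None) -> float:
    """Mean time-domain power contributed by the band [lo, hi].

    Uses the documented one-sided Parseval weights. ``n_samples`` defaults
    to the record length implied by the grid.
    """
    if n_samples is None:
        # grid has N//2 + 1 bins; assume even N (rfftfreq of an even record)
        n_samples = 2 * (len(spectrum) - 1)
    w = np.full(len(spectrum), 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    tol = 1e-6 * spectrum.bin_width  # absorb float rounding at band edges
    sel = (spectrum.frequencies >= lo - tol) & (spectrum.frequencies <= hi + tol)
    return float(np.sum(w[sel] * spectrum.magnitudes[sel] ** 2) / n_samples**2)


def dominant_peak(
    spectrum: Spectrum, band: tuple[float, float] = DEFAULT_PEAK_BAND
) -> tuple[float, float]:
    """(frequency, magnitude) of the largest bin inside ``band``.

    Ties break toward the lower frequency.
    """
    lo, hi = band
    sel = np.flatnonzero((spectrum.frequencies >= lo) & (spectrum.frequencies <= hi))
    if sel.size == 0:
        raise SignalError(f"band {band} contains no bins")
    if sel.size < 3:
        raise SignalError(f"band {band} must contain >= 3 bins, has {sel.size}")
    mags = spectrum.magnitudes[sel]
    k = sel[int(np.argmax(mags))]  # argmax returns first (lowest-frequency) maximum
    return float(spectrum.frequencies[k]), float(spectrum.magnitudes[k])


def estimate_snr(
    signal: PASignal,
    signal_band: tuple[float, float] | None = None,
    noise_band: tuple[float, float] = DEFAULT_NOISE_BAND,
) -> SNRReport:
    """Band-power SNR in dB.

    ``signal_band`` defaults to dominant peak +/- 0.5 MHz (peak searched in
    the 1-10 MHz default band). The noise-band power density is
    extrapolated over the full 0..Nyquist band to estimate the total
    broadband noise power; the reported value is
    ``10*log10(P_signal_band / P_noise_total)``, capped at ``SNR_CAP_DB``
    for noiseless records.
    """
    spec = compute_spectrum(signal)
    nyq = signal.sampling_rate / 2.0
    if signal_band is None:
        f0, _ = dominant_peak(spec)
        signal_band = (f0 - 0.5 * MHZ, f0 + 0.5 * MHZ)
    (slo, shi), (nlo, nhi) = signal_band, noise_band
    if not (0 <= slo < shi <= nyq and 0 <= nlo < nhi <= nyq):
        raise SignalError("bands must lie within [0, Nyquist]")
    if max(slo, nlo) < min(shi, nhi):
        raise SignalError("signal and noise bands must be disjoint")

    n = len(signal)
    p_sig = band_power(spec, slo, shi, n)
    p_noise_band = band_power(spec, nlo, nhi, n)
    if p_sig == 0 and p_noise_band == 0:
        raise SignalError("zero power in both bands; SNR undefined")
    p_noise_total = p_noise_band * (nyq / (nhi - nlo))
    if p_noise_total <= 0:
        snr = SNR_CAP_DB
    else:
        snr = min(10.0 * math.log10(p_sig / p_noise_total), SNR_CAP_DB)
    return SNRReport(snr_db=snr, signal_band=(slo, shi), noise_band=(nlo, nhi))


def _robust_noise_scale(x: np.ndarray) -> float:
    """MAD-based sigma estimate from the final 10% of the record, where the
    ring-down transient (damping times of a few microseconds in records of
    tens of microseconds) has decayed to the noise floor."""
    tail = x[-max(x.size // 10, 16):] if x.size >= 32 else x
    mad = float(np.median(np.abs(tail - np.median(tail))))
    return 1.4826 * mad


def estimate_delay(signal: PASignal, reference_onset: float = 0.0) -> float:
    """Excitation-to-readout delay in seconds via onset detection.

    The onset is the first sample of a run of ``ONSET_RUN_LENGTH``
    consecutive samples whose magnitude exceeds ``ONSET_THRESHOLD_K`` times
    the robust noise scale. Raises :class:`DelayNotDetected` if no such
    run exists (distinct from a measured zero delay).
    """
    x = np.abs(np.asarray(signal.samples, dtype=float))
    sigma = _robust_noise_scale(signal.samples)
    thresh = max(ONSET_THRESHOLD_K * sigma, 1e-12 * max(float(x.max()), 1.0))
    above = x > thresh
    run = ONSET_RUN_LENGTH
    if above.size >= run:
        windows = np.lib.stride_tricks.sliding_window_view(above, run)
        hits = np.flatnonzero(windows.all(axis=1))
        if hits.size:
            onset_t = hits[0] / signal.sampling_rate
            return max(onset_t - reference_onset, 0.0)
    raise DelayNotDetected("no sustained onset crossing found")


def fit_concentration_response(points: list[tuple[float, float]]) -> ConcentrationFit:
    """OLS fit of the maximal linear prefix of a concentration series.

    Points must be sorted by concentration. The linear region is the
    longest prefix (>= 3 points) whose ordinary-least-squares r-squared is
    >= 0.99; a perfectly flat prefix counts as linear (slope 0, r² = 1 by
    the zero-residual convention). The returned slope/intercept are the
    OLS fit on that region.
    """
    if len(points) < 4:
        raise SignalError("need >= 4 points")
    c = np.array([p[0] for p in points], dtype=float)
    a = np.array([p[1] for p in points], dtype=float)
    if np.any(np.diff(c) <= 0):
        raise SignalError("concentrations must be strictly increasing")

    def _ols(n):
        res = _stats.linregress(c[:n], a[:n])
        resid = a[:n] - (res.intercept + res.slope * c[:n])
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((a[:n] - a[:n].mean()) ** 2))
        if ss_tot == 0:  # flat data: zero residual => perfect fit
            r2 = 1.0 if ss_res < 1e-20 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        return float(res.slope), float(res.intercept), r2

    for n in range(len(points), 2, -1):
        slope, intercept, r2 = _ols(n)
        if r2 >= 0.99:
            return ConcentrationFit(
                slope=slope,
                intercept=intercept,
                linear_region=(0, n),
                r_squared=r2,
            )
    raise SignalError("no linear prefix of >= 3 points with r^2 >= 0.99")


# --------------------------------------------------------------------------
# Spectral-library matching
# --------------------------------------------------------------------------

def resample_magnitudes(spectrum: Spectrum, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of magnitudes onto ``grid`` (0 outside support)."""
    return np.interp(grid, spectrum.frequencies, spectrum.magnitudes, left=0.0, right=0.0)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_spectrum(
    query: Spectrum, library: FingerprintLibrary
) -> tuple[str, float, list[tuple[str, float]]]:
    """Closest library fingerprint by cosine similarity.

    The query is resampled onto the library grid and unit-energy
    normalized; returns (best label, best similarity, full ranking).
    Ties in similarity keep library order.
    """
    if not library.entries:
        raise SignalError("cannot match against an empty library")
    grid = library.grid
    q = resample_magnitudes(query, grid)
    if not np.any(q):
        raise SignalError("query has no energy on the library grid")
    q = q / np.linalg.norm(q)
    scored = []
    for lab, spec in library.entries:
        m = spec.magnitudes
        scored.append((lab, cosine_similarity(q, m)))
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][1], i))
    ranking = [scored[i] for i in order]
    best_label, best_score = ranking[0]
    return best_label, best_score, ranking


def build_library(
    spectra: list[tuple[str, Spectrum]], grid: np.ndarray | None = None
) -> FingerprintLibrary:
    """Assemble a fingerprint library, resampling everything onto one grid
    and unit-energy normalizing each entry."""
    if not spectra:
        raise SignalError("need at least one reference spectrum")
    if grid is None:
        grid = spectra[0][1].frequencies
    entries = []
    for lab, spec in spectra:
        m = resample_magnitudes(spec, grid)
        norm = float(np.linalg.norm(m))
        if norm == 0:
            raise SignalError(f"reference {lab!r} has no energy on the grid")
        entries.append(
            (lab, Spectrum(grid, m / norm, source=spec.source, normalization="unit-energy"))
        )
    return FingerprintLibrary(entries=entries)
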
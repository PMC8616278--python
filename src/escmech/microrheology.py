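"""Passive micro-rheology from tracer-position time series.

The analysis chain converts a uniformly sampled 1D tracer trajectory
(a trapped lipid granule observed on a quadrant photodiode) into

1. a one-sided power spectral density (Welch averaging),
2. a scaling exponent ``alpha`` of the power law ``P(f) ~ f^-(1+alpha)``
   fitted over a frequency band where thermal fluctuations dominate,
3. the dissipative part of the mechanical response function via the
   fluctuation--dissipation theorem,
4. the elastic part via a Kramers--Kronig principal-value transform,
5. complex shear moduli ``G' + iG''`` through the generalized
   Stokes--Einstein relation ``G*(f) = 1 / (6 pi r chi(f))``, with the
   constant elastic contribution of the optical trap subtracted.

Conventions
-----------
* Positions are stored in nm; moduli are returned in Pa (SI conversion
  happens inside :func:`imag_response_from_psd`).
* The PSD is one-sided and normalised so that ``sum(P) * df = var(x)``.
  The fluctuation--dissipation theorem is applied with the corresponding
  two-sided density, ``chi''(f) = pi f (P(f)/2) / (k_B T)``.
* Kramers--Kronig reconstruction is trustworthy only for frequencies
  below one tenth of the Nyquist frequency; moduli are capped there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.constants import Boltzmann as K_B

from .errors import DataError, ParameterError, StateError

__all__ = [
    "TrajectoryRecord",
    "PowerSpectrum",
    "ScalingFit",
    "ComplexResponse",
    "ShearModuli",
    "MsdCurve",
    "compute_psd",
    "fit_scaling_exponent",
    "classify_regime",
    "imag_response_from_psd",
    "kramers_kronig_real",
    "shear_moduli",
    "subtract_trap",
    "moduli_from_trajectory",
    "log_band_average",
    "compute_msd",
]

#: Default band (Hz) for the scaling-exponent fit: below the trap corner
#: frequency at the laser powers used, above the frequencies where active
#: (non-equilibrium) cellular processes contribute.
DEFAULT_FIT_BAND = (300.0, 3000.0)

#: Default temperature: live-cell experiments at 37 C.
DEFAULT_TEMPERATURE_K = 310.15

#: Half-width of the Brownian classification window around alpha = 1.
BROWNIAN_TOL = 0.05


# ---------------------------------------------------------------------------
# containers


@dataclass
class TrajectoryRecord:
    """Uniformly sampled 1D tracer position.

    Parameters
    ----------
    position_nm:
        Tracer position in nm, uniformly sampled.
    sampling_rate:
        Sampling frequency in Hz.
    bead_radius_nm:
        Tracer radius in nm (required for moduli, not for the exponent fit).
    temperature_K:
        Absolute temperature housing the thermal energy ``k_B T``.
    condition, location:
        Free-text labels (e.g. culture medium, "periphery").
    """

    position_nm: np.ndarray
    sampling_rate: float
    bead_radius_nm: float | None = None
    temperature_K: float = DEFAULT_TEMPERATURE_K
    condition: str = ""
    location: str = ""

    def __post_init__(self) -> None:
        self.position_nm = np.asarray(self.position_nm, dtype=float)
        if self.position_nm.ndim != 1 or self.position_nm.size < 2:
            raise DataError("trajectory must be a 1D array with >= 2 samples")
        if not np.all(np.isfinite(self.position_nm)):
            raise DataError("trajectory contains non-finite values")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.position_nm.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class PowerSpectrum:
    """One-sided power spectral density of a trajectory (nm^2/Hz)."""

    frequency: np.ndarray
    psd: np.ndarray
    n_segments: int
    nyquist: float

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.frequency.size != self.psd.size:
            raise DataError("frequency and psd must have the same length")
        if self.frequency.size:  # empty spectra are legal (e.g. band cuts)
            if np.any(self.frequency <= 0) or \
                    np.any(np.diff(self.frequency) <= 0):
                raise DataError(
                    "frequencies must be positive and strictly increasing")
            if self.frequency[-1] > self.nyquist * (1 + 1e-9):
                raise DataError("maximum frequency exceeds Nyquist")

    def band(self, f_lo: float, f_hi: float) -> "PowerSpectrum":
        """Restrict the spectrum to ``[f_lo, f_hi]`` (inclusive)."""
        sel = (self.frequency >= f_lo) & (self.frequency <= f_hi)
        return PowerSpectrum(self.frequency[sel], self.psd[sel],
                             self.n_segments, self.nyquist)


@dataclass
class ScalingFit:
    """Power-law fit ``P(f) = prefactor * f^-(1+alpha)`` over a band."""

    alpha: float
    prefactor: float
    band: tuple[float, float]
    alpha_stderr: float
    regime: str


@dataclass
class ComplexResponse:
    """Mechanical response function chi(f) of the medium, in m/N."""

    frequency: np.ndarray
    chi_imag: np.ndarray
    chi_real: np.ndarray | None = None
    kk_valid_max: float = np.inf


@dataclass
class ShearModuli:
    """Storage and loss moduli G'(f), G''(f) in Pa."""

    frequency: np.ndarray
    g_storage: np.ndarray
    g_loss: np.ndarray
    radius_nm: float
    trap_corrected: bool = False
    g_trap: float = 0.0
    n_excluded: int = 0


@dataclass
class MsdCurve:
    """Time-averaged mean squared displacement on a log-spaced lag grid."""

    lag_s: np.ndarray
    msd_nm2: np.ndarray
    fitted_alpha: float
    fit_band_s: tuple[float, float] = field(default=(1.0 / 3000.0, 1.0 / 300.0))


# ---------------------------------------------------------------------------
# spectral estimation


def compute_psd(trajectory: TrajectoryRecord,
                segment_length: int | None = None,
                overlap_fraction: float = 0.5,
                window: str = "hann") -> PowerSpectrum:
    """Estimate the one-sided PSD by Welch averaging.

    With ``segment_length=None`` the full series is used as a single
    segment. A single unwindowed (``window="boxcar"``) segment satisfies
    Parseval's identity ``sum(psd) * df == var(x)`` exactly; the windowed,
    overlapped default trades that exactness for variance reduction, which
    matters for the log-log exponent fit.

    The DC bin is excluded (the mean carries no fluctuation information).
    """
    x = trajectory.position_nm
    fs = trajectory.sampling_rate
    if segment_length is None:
        segment_length = x.size
    if segment_length > x.size:
        raise ParameterError("segment_length exceeds the number of samples")
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap_fraction must lie in [0, 1)")
    noverlap = int(segment_length * overlap_fraction)
    freq, psd = signal.welch(x, fs=fs, window=window, nperseg=segment_length,
                             noverlap=noverlap, detrend="constant",
                             scaling="density", return_onesided=True)
    step = segment_length - noverlap
    n_segments = max(1, 1 + (x.size - segment_length) // step)
    keep = freq > 0
    return PowerSpectrum(freq[keep], psd[keep], n_segments, nyquist=fs / 2.0)


def _log_binned(freq: np.ndarray, psd: np.ndarray,
                bins_per_decade: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Average PSD ordinates within log-frequency bins.

    Arithmetic averaging inside each bin de-biases the exponentially
    distributed periodogram ordinates before taking logarithms; the bin
    abscissa is the mean log-frequency of its members.
    """
    logf = np.log10(freq)
    width = 1.0 / bins_per_decade
    edges = np.arange(logf[0], logf[-1] + width, width)
    idx = np.clip(np.digitize(logf, edges) - 1, 0, len(edges) - 1)
    xb, yb = [], []
    for b in np.unique(idx):
        sel = idx == b
        xb.append(logf[sel].mean())
        yb.append(np.log10(psd[sel].mean()))
    return np.asarray(xb), np.asarray(yb)


def fit_scaling_exponent(spectrum: PowerSpectrum,
                         band: tuple[float, float] = DEFAULT_FIT_BAND,
                         bins_per_decade: int = 4) -> ScalingFit:
    """Fit ``P(f) = c * f^-(1+alpha)`` by least squares in log-log space.

    The slope ``m`` of the line through the log-binned band averages gives
    ``alpha = -m - 1``; the standard error is propagated from the
    regression residuals.
    """
    f_lo, f_hi = band
    sub = spectrum.band(f_lo, f_hi)
    if sub.frequency.size < 10:
        raise ParameterError(
            f"need >= 10 spectral points in [{f_lo}, {f_hi}] Hz, "
            f"got {sub.frequency.size}")
    if np.any(sub.psd <= 0):
        raise DataError("non-positive PSD values inside the fit band")
    x, y = _log_binned(sub.frequency, sub.psd, bins_per_decade)
    if x.size < 3:
        raise ParameterError("fewer than 3 log bins in the fit band")
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    m = np.sum((x - xm) * (y - ym)) / sxx
    b = ym - m * xm
    resid = y - (m * x + b)
    s2 = np.sum(resid**2) / (n - 2) if n > 2 else 0.0
    stderr = float(np.sqrt(s2 / sxx))
    alpha = -m - 1.0
    return ScalingFit(alpha=float(alpha), prefactor=float(10**b),
                      band=(f_lo, f_hi), alpha_stderr=stderr,
                      regime=classify_regime(alpha))


def classify_regime(alpha: float, brownian_tol: float = BROWNIAN_TOL) -> str:
    """Classify the diffusion regime of a scaling exponent.

    ``alpha < 1`` is sub-diffusive (elastic-like environment), ``alpha = 1``
    (within ``brownian_tol``) is Brownian, ``alpha > 1`` super-diffusive.
    """
    if not np.isfinite(alpha):
        raise ParameterError("alpha must be finite")
    if abs(alpha - 1.0) <= brownian_tol:
        return "brownian"
    return "subdiffusive" if alpha < 1.0 else "superdiffusive"


# ---------------------------------------------------------------------------
# response function and moduli


def imag_response_from_psd(spectrum: PowerSpectrum,
                           temperature_K: float = DEFAULT_TEMPERATURE_K,
                           ) -> ComplexResponse:
    """Dissipative response from the PSD via the fluctuation--dissipation theorem.

    ``chi''(f) = pi f S(f) / (k_B T)`` with ``S`` the *two-sided* positional
    spectral density; our spectra are one-sided, so ``S = P/2`` (and nm^2/Hz
    is converted to m^2/Hz). Output units are m/N.
    """
    if temperature_K is None or temperature_K <= 0:
        raise ParameterError("temperature must be a positive number in K")
    psd_m2 = spectrum.psd * 1e-18 / 2.0  # one-sided nm^2/Hz -> two-sided m^2/Hz
    chi_imag = np.pi * spectrum.frequency * psd_m2 / (K_B * temperature_K)
    return ComplexResponse(frequency=spectrum.frequency.copy(),
                           chi_imag=chi_imag,
                           kk_valid_max=spectrum.nyquist / 10.0)


def kramers_kronig_real(response: ComplexResponse,
                        f_max: float | None = None,
                        tail: str = "power_law") -> ComplexResponse:
    """Reconstruct chi'(f) from chi''(f) by the Kramers--Kronig relation.

    Evaluates ``chi'(f) = (2/pi) PV int_0^F f'' chi''(f'') / (f''^2 - f^2) df''``
    on the native grid using singularity subtraction: the constant
    ``f chi''(f)`` is removed from the integrand (its principal-value
    integral has a closed form) and the removable singularity at
    ``f'' = f`` is filled with a finite-difference derivative.

    Truncating the integral at the highest measured frequency ``F``
    leaves an O(chi''(F)) error everywhere, so by default the integrand
    is extended beyond ``F`` with the power law fitted to the last
    half-decade of ``chi''`` (``tail="power_law"``; ``tail="none"``
    disables the extension). Even so, the reconstruction degrades as
    ``f`` approaches ``F`` — the sampled spectrum carries no information
    beyond Nyquist — and results are trustworthy only for
    ``f <= kk_valid_max`` (Nyquist/10).
    """
    f = np.asarray(response.frequency, dtype=float)
    chi2 = np.asarray(response.chi_imag, dtype=float)
    if f_max is not None:
        keep = f <= f_max
        f_eval = f[keep]
    else:
        f_eval = f
    F = f[-1]
    # integration grid includes f'' = 0 where the integrand vanishes in the
    # unsubtracted form; with subtraction its value is chi''(f)/f.
    g = np.concatenate(([0.0], f))
    fg = np.concatenate(([0.0], f * chi2))  # f'' chi''(f'')
    # derivative of f'' chi'' on the grid, for the removable singularity
    dfg = np.gradient(f * chi2, f)

    # power-law tail: fit log(chi'') vs log(f) over the last half-decade
    # and extend the integrand to 1e4 * F on a log-spaced grid
    f_tail = None
    if tail == "power_law":
        sel = (f >= F / np.sqrt(10.0)) & (chi2 > 0)
        if sel.sum() >= 3:
            q, logc = np.polyfit(np.log(f[sel]), np.log(chi2[sel]), 1)
            f_tail = np.logspace(np.log10(F), np.log10(F) + 4, 600)[1:]
            chi2_tail = np.exp(logc) * f_tail**q
    elif tail != "none":
        raise ParameterError(f"unknown tail mode {tail!r}")

    chi1 = np.empty_like(f_eval)
    for i, fi in enumerate(f_eval):
        ci = np.interp(fi, f, chi2)
        num = fg - fi * ci
        den = g**2 - fi**2
        h = np.empty_like(num)
        sing = np.isclose(np.abs(den), 0.0, atol=1e-12 * max(fi**2, 1.0))
        h[~sing] = num[~sing] / den[~sing]
        if np.any(sing):
            # limit of (f''chi'' - f chi''(f)) / (f''^2 - f^2) as f'' -> f
            d = np.interp(fi, f, dfg)
            h[sing] = d / (2.0 * fi)
        integral = np.trapezoid(h, g)
        # closed-form PV of the subtracted constant over [0, F]
        if fi < F:
            integral += fi * ci * (1.0 / (2.0 * fi)) * np.log((F - fi) / (F + fi))
        if f_tail is not None:
            # no singularity beyond F (fi <= F); plain trapezoid in log f
            integral += np.trapezoid(f_tail * chi2_tail / (f_tail**2 - fi**2),
                                     f_tail)
        chi1[i] = (2.0 / np.pi) * integral

    out = ComplexResponse(frequency=f_eval,
                          chi_imag=np.interp(f_eval, f, chi2),
                          chi_real=chi1,
                          kk_valid_max=response.kk_valid_max)
    return out


def shear_moduli(response: ComplexResponse, radius_nm: float) -> ShearModuli:
    """Complex shear modulus via the generalized Stokes--Einstein relation.

    ``G*(f) = 1 / (6 pi r chi(f))`` so that
    ``G' = chi' / (6 pi r |chi|^2)`` and ``G'' = chi'' / (6 pi r |chi|^2)``.
    Output is restricted to ``f <= kk_valid_max`` where the KK-reconstructed
    real part is trustworthy. Frequencies where ``|chi| = 0`` are excluded
    and counted.
    """
    if response.chi_real is None:
        raise StateError("chi_real missing: run kramers_kronig_real first")
    if radius_nm is None or radius_nm <= 0:
        raise ParameterError("radius must be positive")
    r_m = radius_nm * 1e-9
    sel = response.frequency <= response.kk_valid_max
    f = response.frequency[sel]
    chi = response.chi_real[sel] + 1j * response.chi_imag[sel]
    mag2 = np.abs(chi) ** 2
    ok = mag2 > 0
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} frequencies with |chi| = 0")
    denom = 6.0 * np.pi * r_m * mag2[ok]
    return ShearModuli(frequency=f[ok],
                       g_storage=np.real(chi[ok]) / denom,
                       g_loss=np.imag(chi[ok]) / denom,
                       radius_nm=radius_nm,
                       n_excluded=n_excluded)


def subtract_trap(moduli: ShearModuli, g_trap: float) -> ShearModuli:
    """Subtract the optical trap's elastic contribution from G'.

    The trap adds a constant ``G'_trap = k / (6 pi r)`` to the storage
    modulus; it is measured once on a calibration bead in water and
    supplied here as a number. Subtracting twice is a state error.
    """
    if moduli.trap_corrected:
        raise StateError("moduli are already trap-corrected")
    return replace(moduli, g_storage=moduli.g_storage - g_trap,
                   trap_corrected=True, g_trap=float(g_trap))


def moduli_from_trajectory(trajectory: TrajectoryRecord,
                           g_trap: float = 0.0,
                           segment_length: int = 4096,
                           radius_nm: float | None = None,
                           ) -> ShearModuli:
    """Full chain: trajectory -> PSD -> FDT -> Kramers--Kronig -> GSER.

    Convenience wrapper running the whole moduli pipeline with the
    settings appropriate for sampled data: Welch PSD, FDT, KK *without*
    tail extrapolation (for a spectrum estimated from a sampled signal
    the aliased power folded below Nyquist already stands in for the
    truncated tail), GSER inversion and trap subtraction.
    """
    spec = compute_psd(trajectory, segment_length=segment_length)
    resp = kramers_kronig_real(
        imag_response_from_psd(spec, trajectory.temperature_K), tail="none")
    r = radius_nm if radius_nm is not None else trajectory.bead_radius_nm
    if r is None:
        raise ParameterError("bead radius required for moduli")
    mod = shear_moduli(resp, r)
    # leave the trap-correction state untouched when no trap term is given,
    # so an explicit subtract_trap call downstream remains possible
    return subtract_trap(mod, g_trap) if g_trap else mod


def log_band_average(frequency: np.ndarray, values: np.ndarray,
                     n_bands: int = 12,
                     band: tuple[float, float] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Average a frequency-resolved quantity in log-spaced bands.

    The reporting convention for moduli curves: single-bin estimates are
    noisy (exponentially distributed ordinates propagate through the
    chain), band averages are what gets plotted and compared.
    """
    f = np.asarray(frequency, dtype=float)
    v = np.asarray(values, dtype=float)
    lo, hi = band if band is not None else (f.min(), f.max())
    edges = np.logspace(np.log10(lo), np.log10(hi * (1 + 1e-12)), n_bands + 1)
    fa, va = [], []
    for i in range(n_bands):
        sel = (f >= edges[i]) & (f < edges[i + 1])
        if sel.any():
            fa.append(f[sel].mean())
            va.append(v[sel].mean())
    return np.asarray(fa), np.asarray(va)


# ---------------------------------------------------------------------------
# mean squared displacement


def compute_msd(trajectory: TrajectoryRecord, max_lag_s: float,
                n_lags: int = 40) -> MsdCurve:
    """Time-averaged MSD on a log-spaced lag grid, with a power-law fit.

    ``MSD(tau) ~ tau^alpha``; the exponent is fitted over the lag window
    corresponding to the default PSD band (tau in [1/3000, 1/300] s),
    clipped to the available lags.
    """
    if max_lag_s >= trajectory.duration_s:
        raise ParameterError("max_lag must be smaller than the duration")
    fs = trajectory.sampling_rate
    max_lag = int(max_lag_s * fs)
    if max_lag < 5:
        raise ParameterError("max_lag too small for >= 5 lag points")
    lags = np.unique(np.round(np.logspace(0, np.log10(max_lag),
                                          n_lags)).astype(int))
    x = trajectory.position_nm
    msd = np.array([np.mean((x[ell:] - x[:-ell]) ** 2) for ell in lags])
    tau = lags / fs
    lo, hi = 1.0 / 3000.0, 1.0 / 300.0
    sel = (tau >= lo) & (tau <= hi) & (msd > 0)
    if sel.sum() >= 3:
        m = np.polyfit(np.log10(tau[sel]), np.log10(msd[sel]), 1)[0]
        fitted_alpha = float(m)
    else:
        fitted_alpha = float("nan")
    return MsdCurve(lag_s=tau, msd_nm2=msd, fitted_alpha=fitted_alpha)
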
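"""Synthetic-data generators with recorded ground truth.

Every input class the analysis pipeline consumes can be generated here
with known parameters, emulating the statistical structure the analysis
assumes:

* sub-diffusive tracer trajectories with a prescribed PSD exponent and a
  low-frequency trap plateau (spectral synthesis, exact target PSD);
* Brownian motion in a harmonic trap in a viscous fluid (exact
  Ornstein--Uhlenbeck discretization -- the water-calibration analogue);
* free Brownian motion (cumulative Gaussian increments);
* blinking-emitter localization tables with known drift and astigmatic
  elongation;
* filament images with known angle distributions;
* spherical-cap colony side-view masks with known contact angle.

All generators are bit-reproducible given (seed, parameters), and each
output is paired with a :class:`SyntheticTruth` recording what was
generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy.constants import Boltzmann as K_B
from scipy.signal import lfilter

from .errors import GeometryError, ParameterError
from .microrheology import TrajectoryRecord
from .morphometry import ColonyProfile
from .storm import LocalizationTable

__all__ = [
    "SyntheticTruth",
    "DefocusModel",
    "simulate_power_law_trajectory",
    "simulate_trapped_viscous_trajectory",
    "simulate_brownian_trajectory",
    "generate_localization_table",
    "render_filament_image",
    "generate_colony_profile",
    "power_law_psd",
    "ou_psd",
    "save_truth",
    "load_truth",
]


@dataclass
class SyntheticTruth:
    """Ground-truth record paired with every generated artifact."""

    kind: str  # trajectory | localization | filament_image | colony_profile
    parameters: dict
    seed: int | None = None
    arrays: dict = dc_field(default_factory=dict, repr=False)


def save_truth(truth: SyntheticTruth, path) -> None:
    """Write the scalar part of a truth record as key->value structured text."""
    doc = {"kind": truth.kind, "seed": truth.seed,
           "parameters": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in truth.parameters.items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SyntheticTruth(kind=doc["kind"], parameters=doc["parameters"],
                          seed=doc.get("seed"))


# ---------------------------------------------------------------------------
# trajectories


def power_law_psd(f: np.ndarray, alpha: float, amplitude: float,
                  corner_frequency: float) -> np.ndarray:
    """Target one-sided PSD: ``A / (f_c^(1+a) + f^(1+a))`` (nm^2/Hz).

    A plateau below the corner frequency emulates the optical trap; above
    it the spectrum follows the anomalous-diffusion power law
    ``f^-(1+alpha)``. At ``alpha = 1`` this is exactly the Lorentzian of
    a trapped bead in a viscous fluid.
    """
    f = np.asarray(f, dtype=float)
    return amplitude / (corner_frequency ** (1 + alpha) + f ** (1 + alpha))


def simulate_power_law_trajectory(alpha: float, n_samples: int,
                                  sampling_rate: float,
                                  psd_amplitude: float = 1e4,
                                  corner_frequency: float = 10.0,
                                  seed: int = 0,
                                  ) -> tuple[TrajectoryRecord, SyntheticTruth]:
    """Trajectory with a prescribed power-law PSD, by spectral synthesis.

    Hermitian-symmetric random Fourier coefficients are drawn with
    variance matching the target one-sided PSD (periodogram ordinates are
    then exponentially distributed, as for a real spectral estimate) and
    inverse-transformed. Requires a power-of-two length so the synthesis
    grid is exact.
    """
    if not 0 < alpha < 2:
        raise ParameterError("alpha must lie in (0, 2)")
    if n_samples < 1024 or (n_samples & (n_samples - 1)) != 0:
        raise ParameterError("n_samples must be a power of two >= 1024")
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    target = power_law_psd(freqs, alpha, psd_amplitude, corner_frequency)
    n_f = freqs.size
    coef = np.zeros(n_f, dtype=complex)
    # interior bins: E|X_k|^2 = P fs n / 2 (one-sided density convention)
    scale = np.sqrt(target[1:-1] * sampling_rate * n_samples / 2.0)
    re, im = rng.standard_normal((2, n_f - 2))
    coef[1:-1] = scale * (re + 1j * im) / np.sqrt(2.0)
    # Nyquist bin is real; one-sided density has no doubling there
    coef[-1] = np.sqrt(target[-1] * sampling_rate * n_samples) * \
        rng.standard_normal()
    x = np.fft.irfft(coef, n=n_samples)
    traj = TrajectoryRecord(position_nm=x, sampling_rate=sampling_rate)
    truth = SyntheticTruth(
        kind="trajectory", seed=seed,
        parameters={"alpha_true": alpha, "psd_amplitude_nm2": psd_amplitude,
                    "corner_frequency_Hz": corner_frequency,
                    "n_samples": n_samples, "sampling_rate_Hz": sampling_rate})
    return traj, truth


def ou_psd(f: np.ndarray, trap_stiffness: float, viscosity: float,
           radius_m: float, temperature_K: float) -> np.ndarray:
    """One-sided PSD (nm^2/Hz) of a bead in a harmonic trap in a viscous fluid.

    Lorentzian ``k_B T / (pi^2 gamma (f_c^2 + f^2))`` with drag
    ``gamma = 6 pi eta r`` and corner frequency ``f_c = k / (2 pi gamma)``.
    """
    gamma = 6.0 * np.pi * viscosity * radius_m
    f_c = trap_stiffness / (2.0 * np.pi * gamma)
    psd_m2 = K_B * temperature_K / (np.pi**2 * gamma) / (f_c**2 + np.asarray(f)**2)
    return psd_m2 * 1e18


def simulate_trapped_viscous_trajectory(trap_stiffness: float,
                                        viscosity: float,
                                        radius: float,
                                        temperature: float,
                                        n_samples: int,
                                        sampling_rate: float,
                                        seed: int = 0,
                                        ) -> tuple[TrajectoryRecord, SyntheticTruth]:
    """Bead in a harmonic optical trap in a purely viscous medium.

    Exact discretization of the Ornstein--Uhlenbeck process (no
    step-size bias): with relaxation time ``tau = gamma/k``,

        x[n+1] = rho x[n] + sqrt(1 - rho^2) * sigma_eq * xi,  rho = e^(-dt/tau)

    and equilibrium standard deviation ``sigma_eq = sqrt(k_B T / k)``
    (equipartition). SI inputs (N/m, Pa s, m, K); positions in nm.
    """
    for name, v in (("trap_stiffness", trap_stiffness), ("viscosity", viscosity),
                    ("radius", radius), ("temperature", temperature),
                    ("sampling_rate", sampling_rate)):
        if v <= 0:
            raise ParameterError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    gamma = 6.0 * np.pi * viscosity * radius
    tau = gamma / trap_stiffness
    sigma_eq_nm = np.sqrt(K_B * temperature / trap_stiffness) * 1e9
    rho = np.exp(-1.0 / (sampling_rate * tau))
    innov_sd = sigma_eq_nm * np.sqrt(1.0 - rho**2)
    eps = rng.standard_normal(n_samples) * innov_sd
    # stationary start: x[0] ~ N(0, sigma_eq)
    eps[0] = rng.standard_normal() * sigma_eq_nm
    x = lfilter([1.0], [1.0, -rho], eps)
    traj = TrajectoryRecord(position_nm=x, sampling_rate=sampling_rate,
                            bead_radius_nm=radius * 1e9,
                            temperature_K=temperature)
    f_c = trap_stiffness / (2.0 * np.pi * gamma)
    truth = SyntheticTruth(
        kind="trajectory", seed=seed,
        parameters={"trap_stiffness_N_per_m": trap_stiffness,
                    "viscosity_Pa_s": viscosity, "radius_m": radius,
                    "temperature_K": temperature,
                    "corner_frequency_Hz": f_c,
                    "g_trap_Pa": trap_stiffness / (6.0 * np.pi * radius),
                    "n_samples": n_samples, "sampling_rate_Hz": sampling_rate})
    return traj, truth


def simulate_brownian_trajectory(n_samples: int, sampling_rate: float,
                                 step_sigma_nm: float = 1.0, seed: int = 0,
                                 ) -> tuple[TrajectoryRecord, SyntheticTruth]:
    """Free Brownian motion: cumulative sum of Gaussian increments.

    The sampled random walk has ``MSD(tau) = (step_sigma^2 fs) tau`` and a
    ``1/f^2`` spectrum well below the Nyquist frequency (scaling exponent
    ``alpha = 1``).
    """
    if n_samples < 2 or sampling_rate <= 0 or step_sigma_nm <= 0:
        raise ParameterError("invalid Brownian simulation parameters")
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.standard_normal(n_samples) * step_sigma_nm)
    traj = TrajectoryRecord(position_nm=x, sampling_rate=sampling_rate)
    truth = SyntheticTruth(
        kind="trajectory", seed=seed,
        parameters={"alpha_true": 1.0, "step_sigma_nm": step_sigma_nm,
                    "n_samples": n_samples, "sampling_rate_Hz": sampling_rate})
    return traj, truth


# ---------------------------------------------------------------------------
# localization tables


@dataclass
class DefocusModel:
    """Astigmatic PSF width model for synthetic 3D localization data.

    ``sigma_x(z) = sigma0 sqrt(1 + ((z + focal_shift)/depth)^2)`` and
    ``sigma_y`` with the opposite focal shift: a cylindrical lens moves
    the x- and y-focal planes apart, so a molecule above focus is
    elongated along one axis and below focus along the other. At z = 0
    the spot is symmetric.
    """

    sigma0_nm: float = 150.0
    focal_shift_nm: float = 300.0
    depth_nm: float = 400.0

    def sigmas(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = np.asarray(z, dtype=float)
        sx = self.sigma0_nm * np.sqrt(1 + ((z + self.focal_shift_nm) /
                                           self.depth_nm) ** 2)
        sy = self.sigma0_nm * np.sqrt(1 + ((z - self.focal_shift_nm) /
                                           self.depth_nm) ** 2)
        return sx, sy

    def elongation(self, z: np.ndarray) -> np.ndarray:
        sx, sy = self.sigmas(z)
        return np.log(sx / sy)


def generate_localization_table(emitter_positions: np.ndarray,
                                n_frames: int,
                                blink_rate: float,
                                localization_sigma: float,
                                drift_per_frame: tuple[float, float] = (0.0, 0.0),
                                astigmatism_model: DefocusModel | None = None,
                                z_positions: np.ndarray | None = None,
                                sigma_jitter: float = 0.02,
                                mean_photons: float = 1000.0,
                                seed: int = 0,
                                ) -> tuple[LocalizationTable, SyntheticTruth]:
    """Blinking-emitter event stream with drift and optional astigmatism.

    Each emitter blinks independently per frame with probability
    ``blink_rate``; an event's coordinates are the true position plus the
    cumulative drift at its frame plus Gaussian localization noise. With
    an astigmatism model and per-emitter ``z_positions``, per-event
    sigma_x/sigma_y follow the model's elongation at the emitter's z
    (with multiplicative jitter ``sigma_jitter``).
    """
    pos = np.atleast_2d(np.asarray(emitter_positions, dtype=float))
    if pos.shape[1] != 2:
        raise ParameterError("emitter_positions must be (n, 2) nm coordinates")
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if not 0 < blink_rate <= 1:
        raise ParameterError("blink_rate must lie in (0, 1]")
    if z_positions is not None and astigmatism_model is None:
        raise ParameterError("z_positions given without an astigmatism_model")
    rng = np.random.default_rng(seed)
    n_em = pos.shape[0]
    on = rng.random((n_frames, n_em)) < blink_rate
    frame_idx, em_idx = np.nonzero(on)
    frames = frame_idx + 1  # 1-based
    drift = np.asarray(drift_per_frame, dtype=float)
    cum_drift = (frames - 1)[:, None] * drift[None, :]
    noise = rng.standard_normal((frames.size, 2)) * localization_sigma
    xy = pos[em_idx] + cum_drift + noise
    data = {
        "frame": frames,
        "x": xy[:, 0],
        "y": xy[:, 1],
        "intensity": rng.gamma(shape=4.0, scale=mean_photons / 4.0,
                               size=frames.size),
        "uncertainty": np.full(frames.size, float(localization_sigma)),
    }
    params = {"n_emitters": n_em, "n_frames": n_frames,
              "blink_rate": blink_rate,
              "localization_sigma_nm": localization_sigma,
              "drift_nm_per_frame": drift.tolist()}
    arrays = {"emitter_positions": pos, "emitter_index": em_idx}
    if astigmatism_model is not None:
        z_em = np.zeros(n_em) if z_positions is None \
            else np.asarray(z_positions, dtype=float)
        sx, sy = astigmatism_model.sigmas(z_em[em_idx])
        jitter = rng.normal(1.0, sigma_jitter, size=(2, frames.size))
        data["sigma_x"] = sx * np.abs(jitter[0])
        data["sigma_y"] = sy * np.abs(jitter[1])
        arrays["z_true"] = z_em
        params.update({"sigma0_nm": astigmatism_model.sigma0_nm,
                       "focal_shift_nm": astigmatism_model.focal_shift_nm,
                       "depth_nm": astigmatism_model.depth_nm})
    else:
        data["sigma"] = np.full(frames.size, float(localization_sigma))
    table = LocalizationTable(pd.DataFrame(data))
    truth = SyntheticTruth(kind="localization", seed=seed,
                           parameters=params, arrays=arrays)
    return table, truth


# ---------------------------------------------------------------------------
# filament images


def render_filament_image(angles: np.ndarray,
                          image_size: int = 256,
                          n_filaments: int | None = None,
                          filament_width_sigma: float = 1.5,
                          intensity: float = 200.0,
                          noise: float = 5.0,
                          length_fraction: float = 0.7,
                          mask: np.ndarray | None = None,
                          seed: int = 0,
                          ) -> tuple[np.ndarray, SyntheticTruth]:
    """Render straight filaments with known orientations.

    Each filament is a straight Gaussian ridge (intensity falls off with
    the analytic distance to the segment, width ``filament_width_sigma``)
    at one of the supplied angles (degrees in [-90, 90), x-axis
    convention); Poisson shot noise with a flat background is added. The
    analytic profile avoids rasterization staircases that would corrupt
    per-pixel orientation ground truth. A per-pixel angle map (NaN where
    no single filament dominates) is stored in the truth's arrays,
    together with the drawn angle list.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ParameterError("empty angle list")
    if np.any(angles < -90) or np.any(angles >= 90):
        raise ParameterError("angles must lie in [-90, 90)")
    rng = np.random.default_rng(seed)
    if n_filaments is None:
        n_filaments = angles.size
        drawn = angles.copy()
    else:
        drawn = rng.choice(angles, size=n_filaments)
    size = int(image_size)
    img = np.zeros((size, size))
    angle_map = np.full((size, size), np.nan)
    owners = np.zeros((size, size), dtype=int)  # how many filaments hit a pixel
    half_len = 0.5 * length_fraction * size
    rows_g, cols_g = np.mgrid[0:size, 0:size]
    for ang in drawn:
        if mask is None:
            cx, cy = rng.uniform(0.15 * size, 0.85 * size, size=2)
        else:
            rows, cols = np.nonzero(mask)
            j = rng.integers(rows.size)
            cy, cx = float(rows[j]), float(cols[j])
        th = np.deg2rad(ang)
        dx, dy = np.cos(th), -np.sin(th)  # y down in raster coords
        # clip the segment to the image rectangle along its own direction,
        # so border-crossing filaments keep their angle
        t_lo, t_hi = -half_len, half_len
        for center, d in ((cy, dy), (cx, dx)):
            if abs(d) > 1e-12:
                ta = (0.0 - center) / d
                tb = (size - 1.0 - center) / d
                t_lo = max(t_lo, min(ta, tb))
                t_hi = min(t_hi, max(ta, tb))
        if t_hi <= t_lo:
            continue
        # analytic distance to the segment on a padded bounding box
        pad = int(np.ceil(4 * filament_width_sigma)) + 1
        ends_r = (cy + t_lo * dy, cy + t_hi * dy)
        ends_c = (cx + t_lo * dx, cx + t_hi * dx)
        r_lo = max(0, int(min(ends_r)) - pad)
        r_hi = min(size, int(max(ends_r)) + pad + 1)
        c_lo = max(0, int(min(ends_c)) - pad)
        c_hi = min(size, int(max(ends_c)) + pad + 1)
        rr = rows_g[r_lo:r_hi, c_lo:c_hi]
        cc = cols_g[r_lo:r_hi, c_lo:c_hi]
        t = (cc - cx) * dx + (rr - cy) * dy
        t = np.clip(t, t_lo, t_hi)
        d2 = (cc - (cx + t * dx)) ** 2 + (rr - (cy + t * dy)) ** 2
        prof = np.exp(-0.5 * d2 / filament_width_sigma**2)
        img[r_lo:r_hi, c_lo:c_hi] += intensity * prof
        hit = prof > 0.3
        angle_map[r_lo:r_hi, c_lo:c_hi][hit] = ang
        owners[r_lo:r_hi, c_lo:c_hi][hit] += 1
    angle_map[owners != 1] = np.nan  # only where a single filament dominates
    if mask is not None:
        img = img * mask
    img = rng.poisson(img + noise).astype(float)
    truth = SyntheticTruth(
        kind="filament_image", seed=seed,
        parameters={"n_filaments": int(n_filaments),
                    "filament_width_sigma_px": filament_width_sigma,
                    "intensity": intensity, "noise": noise,
                    "image_size": size},
        arrays={"angles_deg": drawn, "angle_map": angle_map})
    return img, truth


# ---------------------------------------------------------------------------
# colony profiles


def generate_colony_profile(contact_angle: float, base_radius: float = 120.0,
                            image_size: int = 300,
                            ) -> tuple[ColonyProfile, SyntheticTruth]:
    """Side-view mask of a circular-segment (spherical-cap cross-section).

    A circle of radius ``R = a / sin(theta)`` (``a`` = base half-width)
    centered at height ``-R cos(theta)`` meets the substrate at exactly
    the requested interior angle on both sides (cap height
    ``R (1 - cos theta)``): obtuse angles give overhanging dome-like
    profiles, 90 degrees a half-disk, acute angles a shallow spreading cap.
    """
    if not 0 < contact_angle < 180:
        raise ParameterError("contact_angle must lie in (0, 180) degrees")
    theta = np.deg2rad(contact_angle)
    R = base_radius / np.sin(theta)
    zc = -R * np.cos(theta)  # center height above substrate (positive if obtuse)
    cap_height = zc + R
    size = int(image_size)
    substrate_row = size - 2
    if cap_height >= substrate_row:
        raise ParameterError("cap taller than the image; enlarge image_size")
    cols = np.arange(size, dtype=float)
    rows = np.arange(size, dtype=float)
    xg, rg = np.meshgrid(cols, rows)
    z = substrate_row - rg  # height above substrate, z up
    x0 = size / 2.0
    inside = ((xg - x0) ** 2 + (z - zc) ** 2 <= R**2) & (z >= 0)
    profile = ColonyProfile(mask=inside, substrate_row=substrate_row)
    truth = SyntheticTruth(
        kind="colony_profile",
        parameters={"contact_angle_deg": contact_angle,
                    "base_radius_px": base_radius,
                    "circle_radius_px": float(R),
                    "image_size": size})
    return profile, truth
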
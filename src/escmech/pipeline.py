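"""Condition-comparison studies and group statistics.

Orchestrates the stage modules into the two analyses that compare the
naive (2i) and primed (Serum/LIF) culture conditions:

* a micro-rheology study: per-granule scaling exponents, a two-group
  comparison, and per-condition shear-moduli curves;
* an orientation study: per-cell nematic order parameter S, aspect
  ratio and contact area, with a two-group comparison on S.

Both studies run end-to-end on synthetic inputs whose ground truth is
drawn from a :class:`RunConfig`; identical configs (including seeds)
produce identical reports. Group statistics follow the study's recipe:
a D'Agostino--Pearson omnibus normality test on each group, then a
two-sample Student's t-test (equal variances by default; Welch by flag).
No multiple-testing correction is applied (single pairwise tests).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy import stats

from . import __version__
from .errors import DataError, ParameterError
from .microrheology import (compute_psd, fit_scaling_exponent,
                            imag_response_from_psd, kramers_kronig_real,
                            shear_moduli, subtract_trap, PowerSpectrum)
from .morphometry import measure_contact_area
from .orientation import (fit_cell_axis, gabor_enhance, order_parameter,
                          structure_tensor_orientation)
from .synthetic import render_filament_image, simulate_power_law_trajectory

__all__ = [
    "GroupComparison",
    "RunConfig",
    "compare_groups",
    "run_microrheology_study",
    "run_orientation_study",
]


@dataclass
class GroupComparison:
    """Two-group comparison: normality check plus Student's t-test."""

    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    means: tuple[float, float]
    standard_deviations: tuple[float, float]
    normality_p: tuple[float, float]
    t_statistic: float
    p_value: float
    alpha_level: float
    significant: bool


def compare_groups(values_a, values_b, alpha_level: float = 0.05,
                   labels: tuple[str, str] = ("A", "B"),
                   equal_var: bool = True) -> GroupComparison:
    """Compare two samples the way the study does.

    First a D'Agostino--Pearson omnibus normality test per group (needs
    n >= 8; smaller groups get NaN with a warning), then a two-sample
    t-test; the significance flag applies ``alpha_level``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 values")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        # degenerate but well-defined: identical constant groups
        raise DataError("zero variance in both groups: t undefined")
    norm_p = []
    for g in (a, b):
        if g.size >= 8:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                norm_p.append(float(stats.normaltest(g).pvalue))
        else:
            warnings.warn("group too small for the normality test (n < 8)")
            norm_p.append(float("nan"))
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        group_labels=labels, n_per_group=(a.size, b.size),
        means=(float(a.mean()), float(b.mean())),
        standard_deviations=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        normality_p=(norm_p[0], norm_p[1]),
        t_statistic=float(t), p_value=float(p),
        alpha_level=alpha_level, significant=bool(p < alpha_level))


@dataclass
class RunConfig:
    """Fully serialisable study configuration (reproducibility contract).

    ``conditions`` maps a condition label to its generator parameters;
    for the micro-rheology study these are ``alpha_mean``/``alpha_sd``
    of the per-granule scaling exponents, for the orientation study an
    ``alignment`` mode (``aligned`` with ``spread_deg``, or
    ``isotropic``). Defaults mirror the study conditions: 26 granules or
    16 cells per condition, 22 kHz sampling, the 300-3000 Hz fit band.
    """

    seed: int = 0
    # micro-rheology stage
    n_granules_per_condition: int = 26
    conditions: dict = field(default_factory=lambda: {
        "2i": {"alpha_mean": 0.48, "alpha_sd": 0.11},
        "Serum/LIF": {"alpha_mean": 0.40, "alpha_sd": 0.15},
    })
    n_samples: int = 2**17
    sampling_rate: float = 22000.0
    fit_band: tuple[float, float] = (300.0, 3000.0)
    psd_segment_length: int = 4096
    radius_nm: float = 250.0
    temperature_K: float = 310.15
    g_trap_pa: float = 0.0
    # orientation stage
    n_cells_per_condition: int = 16
    orientation_conditions: dict = field(default_factory=lambda: {
        "Serum/LIF": {"alignment": "aligned", "spread_deg": 8.0},
        "2i": {"alignment": "isotropic"},
    })
    image_size: int = 192
    n_filaments: int = 50
    pixel_size_nm: float = 20.0
    alpha_level: float = 0.05
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out <= lo) | (out >= hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def _write_report(report: dict, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in report.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"config": report["config"],
                        "version": report["version"]}, fh, sort_keys=True)


def run_microrheology_study(config: RunConfig) -> dict:
    """Synthetic two-condition micro-rheology study.

    Per condition, draws per-granule true exponents from a truncated
    normal, synthesises one trajectory per granule, fits the scaling
    exponent over the configured band, compares the two exponent
    distributions, and computes a trap-corrected shear-moduli curve from
    the condition-averaged spectrum. The full config and package version
    are embedded in the report.
    """
    labels = list(config.conditions)
    if len(labels) == 0:
        raise ParameterError("no conditions configured")
    rows = []
    moduli_frames = []
    alphas_by_label: dict[str, np.ndarray] = {}
    truth_by_label: dict[str, np.ndarray] = {}
    for ci, label in enumerate(labels):
        params = config.conditions[label]
        rng = np.random.default_rng([config.seed, 7, ci])
        a_true = _truncated_normal(rng, params["alpha_mean"],
                                   params["alpha_sd"], 0.05, 1.9,
                                   config.n_granules_per_condition)
        spectra = []
        fitted = []
        for gi, at in enumerate(a_true):
            traj, _ = simulate_power_law_trajectory(
                alpha=float(at), n_samples=config.n_samples,
                sampling_rate=config.sampling_rate,
                seed=int(rng.integers(2**31)))
            spec = compute_psd(traj, segment_length=config.psd_segment_length)
            fit = fit_scaling_exponent(spec, band=config.fit_band)
            fitted.append(fit.alpha)
            spectra.append(spec)
            rows.append({"condition": label, "granule": gi,
                         "alpha_true": float(at), "alpha": fit.alpha,
                         "alpha_stderr": fit.alpha_stderr,
                         "regime": fit.regime})
        alphas_by_label[label] = np.asarray(fitted)
        truth_by_label[label] = a_true
        mean_psd = np.mean([s.psd for s in spectra], axis=0)
        mean_spec = PowerSpectrum(spectra[0].frequency, mean_psd,
                                  n_segments=len(spectra) * spectra[0].n_segments,
                                  nyquist=spectra[0].nyquist)
        # tail="none": aliased power in a sampled spectrum stands in for
        # the truncated high-frequency tail (see moduli_from_trajectory)
        resp = kramers_kronig_real(
            imag_response_from_psd(mean_spec, config.temperature_K),
            tail="none")
        mod = subtract_trap(shear_moduli(resp, config.radius_nm),
                            config.g_trap_pa)
        moduli_frames.append(pd.DataFrame({
            "condition": label, "frequency": mod.frequency,
            "g_storage": mod.g_storage, "g_loss": mod.g_loss,
            "trap_corrected": mod.trap_corrected}))
    report: dict = {
        "alpha_table": pd.DataFrame(rows),
        "moduli": pd.concat(moduli_frames, ignore_index=True),
        "truth_means": {lb: float(v.mean()) for lb, v in truth_by_label.items()},
        "config": config.to_dict(),
        "version": __version__,
    }
    if len(labels) >= 2:
        a, b = labels[0], labels[1]
        report["comparison"] = compare_groups(
            alphas_by_label[a], alphas_by_label[b],
            alpha_level=config.alpha_level, labels=(a, b))
    else:
        warnings.warn("single-condition manifest: no group comparison")
    if config.output_dir:
        _write_report(report, config.output_dir)
    return report


def _ellipse_mask(size: int, semi_major: float, semi_minor: float,
                  angle_deg: float) -> np.ndarray:
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    x = xx - c
    y = -(yy - c)  # y up
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def run_orientation_study(config: RunConfig) -> dict:
    """Synthetic two-condition actin-orientation study.

    Per cell, draws an elliptical adherent-area mask and filament angles
    (tightly distributed around the cell's major axis for the aligned
    condition, uniform for the isotropic one), renders the filament
    image, extracts the orientation field (Gabor enhancement followed by
    the structure tensor), and computes S relative to the fitted cell
    axis, plus aspect ratio and contact area. Groups are compared on S.
    """
    labels = list(config.orientation_conditions)
    if len(labels) == 0:
        raise ParameterError("no conditions configured (empty manifest)")
    size = config.image_size
    rows = []
    s_by_label: dict[str, list[float]] = {lb: [] for lb in labels}
    for ci, label in enumerate(labels):
        params = config.orientation_conditions[label]
        rng = np.random.default_rng([config.seed, 11, ci])
        for cell in range(config.n_cells_per_condition):
            axis_true = float(rng.uniform(-90, 90))
            if params["alignment"] == "aligned":
                semi = (0.42 * size, 0.26 * size)
                spread = params.get("spread_deg", 8.0)
                angles = rng.normal(axis_true, spread, size=config.n_filaments)
                angles = (angles + 90) % 180 - 90
            elif params["alignment"] == "isotropic":
                semi = (0.36 * size, 0.33 * size)
                angles = rng.uniform(-90, 90, size=config.n_filaments)
            else:
                raise ParameterError(f"unknown alignment {params['alignment']!r}")
            mask = _ellipse_mask(size, semi[0], semi[1], axis_true)
            img, truth = render_filament_image(
                angles, image_size=size, mask=mask,
                seed=int(rng.integers(2**31)))
            enhanced = gabor_enhance(img, n_orientations=12)
            fld = structure_tensor_orientation(enhanced)
            # erode the cell mask so the ellipse rim (where filaments are
            # cut off) does not contribute rim-tangent orientations
            fld.mask &= ndi.binary_erosion(mask, iterations=8)
            axis = fit_cell_axis(mask)
            res = order_parameter(fld, axis, cell_id=f"{label}-{cell}")
            area = measure_contact_area(mask, config.pixel_size_nm)
            rows.append({"condition": label, "cell_id": res.cell_id,
                         "S": res.S, "n_pixels": res.n_pixels,
                         "major_axis_deg": axis.major_axis_angle,
                         "aspect_ratio": axis.aspect_ratio,
                         "contact_area_um2": area.area_um2,
                         "axis_true_deg": axis_true})
            s_by_label[label].append(res.S)
    report: dict = {
        "cell_table": pd.DataFrame(rows),
        "config": config.to_dict(),
        "version": __version__,
    }
    if len(labels) >= 2:
        a, b = labels[0], labels[1]
        report["comparison"] = compare_groups(
            s_by_label[a], s_by_label[b],
            alpha_level=config.alpha_level, labels=(a, b))
    else:
        warnings.warn("single-condition manifest: no group comparison")
    if config.output_dir:
        _write_report(report, config.output_dir)
    return report
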
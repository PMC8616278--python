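"""Post-processing of single-molecule localization tables.

Raw spot detection and PSF fitting happen upstream (in the established
localization tool); this module consumes its comma-separated output
dialect and implements the downstream steps used in the study:

* reading/writing localization tables (``"x [nm]"``-style headers),
* rendering super-resolution images (histogram or Gaussian splatting),
* lateral drift estimation by cross-correlating temporally binned
  renderings, with sub-pixel (upsampled) peak refinement,
* astigmatism z-calibration from bead stacks scanned through focus, and
  per-event z assignment by inverting the calibration curve.

Coordinates are nm with the origin at the top-left of the field of view
and y increasing downward; frame indices are 1-based.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .errors import (CalibrationError, EstimationError, FormatError,
                     ParameterError, StateError)

__all__ = [
    "LocalizationTable",
    "DriftModel",
    "AstigmatismCalibration",
    "RenderedImage",
    "read_localizations",
    "write_localizations",
    "render_image",
    "estimate_drift",
    "apply_drift",
    "fit_astigmatism_calibration",
    "assign_z",
]

# canonical column -> header written to file
_HEADERS = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "sigma": "sigma [nm]",
    "intensity": "intensity [photon]",
    "uncertainty": "uncertainty [nm]",
    "sigma_x": "sigma_x [nm]",
    "sigma_y": "sigma_y [nm]",
    "z": "z [nm]",
}

_MANDATORY = ("frame", "x", "y")


@dataclass
class LocalizationTable:
    """Typed view of a localization event table.

    ``data`` holds canonical columns (``frame``, ``x``, ``y``, and
    optionally ``sigma``, ``sigma_x``, ``sigma_y``, ``intensity``,
    ``uncertainty``, ``z``); unrecognised input columns are preserved
    untouched in ``extras``. ``meta`` accumulates bookkeeping such as
    dropped-event counts so that filters stay auditable.
    """

    data: pd.DataFrame
    extras: pd.DataFrame | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in _MANDATORY:
            if col not in self.data.columns:
                raise FormatError(f"missing mandatory column {col!r}; "
                                  f"have {list(self.data.columns)}")
        for col in ("sigma", "sigma_x", "sigma_y"):
            if col in self.data.columns and np.any(self.data[col] <= 0):
                raise FormatError(f"column {col!r} must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_z(self) -> bool:
        return "z" in self.data.columns

    def sorted_by_frame(self) -> "LocalizationTable":
        order = np.argsort(self.data["frame"].to_numpy(), kind="stable")
        extras = self.extras.iloc[order].reset_index(drop=True) \
            if self.extras is not None else None
        return LocalizationTable(self.data.iloc[order].reset_index(drop=True),
                                 extras, dict(self.meta))


def _canonical_name(header: str) -> str | None:
    """Map a dialect header like ``"x [nm]"`` / ``"x[nm]"`` to a canonical name."""
    m = re.fullmatch(r"\s*\"?([A-Za-z_ ]+?)\s*(?:\[([^\]]*)\])?\"?\s*", header)
    if m is None:
        return None
    name = m.group(1).strip().lower().replace(" ", "_")
    return name if name in _HEADERS else None


def read_localizations(path, dialect: str = "thunderstorm_csv") -> LocalizationTable:
    """Read a comma-separated localization table in the consumed dialect.

    Units are taken from the bracketed header suffixes (nm assumed);
    header spacing variants (``"x [nm]"`` vs ``"x[nm]"``) are accepted.
    Unknown columns are preserved as opaque extras.
    """
    if dialect != "thunderstorm_csv":
        raise ParameterError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty or headerless file") from exc
    if raw.empty and raw.columns.size == 0:
        raise FormatError(f"{path}: no columns found")
    canon, extras = {}, {}
    for col in raw.columns:
        name = _canonical_name(str(col))
        if name is not None and name not in canon:
            canon[name] = pd.to_numeric(raw[col], errors="coerce")
        else:
            extras[col] = raw[col]
    data = pd.DataFrame(canon)
    if "frame" in data.columns:
        data["frame"] = data["frame"].astype(int)
    extras_df = pd.DataFrame(extras) if extras else None
    return LocalizationTable(data, extras_df)


def write_localizations(table: LocalizationTable, path) -> None:
    """Write a table back out in the same dialect it is read from."""
    out = {}
    for col in table.data.columns:
        out[_HEADERS.get(col, col)] = table.data[col]
    if table.extras is not None:
        for col in table.extras.columns:
            out[col] = table.extras[col]
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderedImage:
    """Super-resolution rendering of an event table (rows = y, cols = x)."""

    data: np.ndarray
    pixel_size: float
    origin: tuple[float, float]  # (x0, y0) nm of pixel (0, 0)


def render_image(table: LocalizationTable, pixel_size: float,
                 mode: str = "histogram",
                 fov: tuple[float, float, float, float] | None = None,
                 ) -> RenderedImage:
    """Render events onto a pixel grid.

    ``histogram`` mode bins event counts; ``gaussian`` mode splats each
    event with its localization uncertainty as sigma, each splat
    normalised to unit mass so the total rendered weight equals the
    number of events. ``fov = (x0, y0, width, height)`` in nm fixes the
    grid; by default it hugs the data.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    x = table.data["x"].to_numpy(float)
    y = table.data["y"].to_numpy(float)
    if len(x) == 0:
        warnings.warn("rendering an empty localization table")
        return RenderedImage(np.zeros((1, 1)), pixel_size, (0.0, 0.0))
    if fov is None:
        x0, y0 = x.min(), y.min()
        w = x.max() - x0 + pixel_size
        h = y.max() - y0 + pixel_size
    else:
        x0, y0, w, h = fov
    ncols = max(1, int(np.ceil(w / pixel_size)))
    nrows = max(1, int(np.ceil(h / pixel_size)))
    img = np.zeros((nrows, ncols))
    col = (x - x0) / pixel_size
    row = (y - y0) / pixel_size
    if mode == "histogram":
        ci = np.clip(col.astype(int), 0, ncols - 1)
        ri = np.clip(row.astype(int), 0, nrows - 1)
        np.add.at(img, (ri, ci), 1.0)
    elif mode == "gaussian":
        if "uncertainty" in table.data.columns:
            sig = table.data["uncertainty"].to_numpy(float) / pixel_size
        else:
            sig = np.full(len(x), 1.0)
        sig = np.clip(sig, 0.3, None)
        half = np.maximum(1, np.ceil(3 * sig).astype(int))
        for cx, cy, s, hw in zip(col, row, sig, half):
            ri = np.clip(np.arange(int(cy) - hw, int(cy) + hw + 1), 0, nrows - 1)
            ci = np.clip(np.arange(int(cx) - hw, int(cx) + hw + 1), 0, ncols - 1)
            gy = np.exp(-0.5 * ((ri - cy) / s) ** 2)
            gx = np.exp(-0.5 * ((ci - cx) / s) ** 2)
            kern = np.outer(gy, gx)
            kern /= kern.sum()  # unit mass regardless of truncation/clipping
            np.add.at(img, (ri[:, None], ci[None, :]), kern)
    else:
        raise ParameterError(f"unknown rendering mode {mode!r}")
    return RenderedImage(img, pixel_size, (float(x0), float(y0)))


# ---------------------------------------------------------------------------
# drift


@dataclass
class DriftModel:
    """Piecewise-linear lateral drift vs frame, anchored at the first bin."""

    bin_center_frame: np.ndarray
    dx: np.ndarray  # nm
    dy: np.ndarray  # nm
    interpolation: str = "linear"

    def __call__(self, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        frames = np.asarray(frames, dtype=float)
        dx = np.interp(frames, self.bin_center_frame, self.dx)
        dy = np.interp(frames, self.bin_center_frame, self.dy)
        return dx, dy


def estimate_drift(table: LocalizationTable, n_bins: int = 10,
                   pixel_size: float = 20.0, upsampling: int = 10,
                   min_events_per_bin: int = 50) -> DriftModel:
    """Estimate lateral drift by cross-correlating temporally binned renderings.

    Events are split into ``n_bins`` equal frame-range bins; each bin is
    rendered on a common grid and registered against the first bin by the
    cross-correlation peak with sub-pixel refinement (``upsampling``-fold).
    Sparse bins are merged into their neighbour with a warning.
    """
    if n_bins < 2:
        raise ParameterError("need at least 2 temporal bins")
    frames = table.data["frame"].to_numpy()
    f_lo, f_hi = frames.min(), frames.max()
    edges = np.linspace(f_lo, f_hi + 1, n_bins + 1)
    idx = np.clip(np.digitize(frames, edges) - 1, 0, n_bins - 1)
    groups = [np.flatnonzero(idx == b) for b in range(n_bins)]
    # merge sparse bins forward
    merged, cur = [], np.array([], dtype=int)
    for g in groups:
        cur = np.concatenate([cur, g])
        if cur.size >= min_events_per_bin:
            merged.append(cur)
            cur = np.array([], dtype=int)
    if cur.size:
        if merged:
            merged[-1] = np.concatenate([merged[-1], cur])
        else:
            merged.append(cur)
    if len(merged) < len(groups):
        warnings.warn("sparse temporal bins were merged")
    if len(merged) < 2:
        raise EstimationError("fewer than 2 usable temporal bins")

    x = table.data["x"].to_numpy(float)
    y = table.data["y"].to_numpy(float)
    pad = 4 * pixel_size
    fov = (x.min() - pad, y.min() - pad,
           x.max() - x.min() + 2 * pad, y.max() - y.min() + 2 * pad)
    imgs, centers = [], []
    for g in merged:
        sub = LocalizationTable(table.data.iloc[g].reset_index(drop=True))
        imgs.append(render_image(sub, pixel_size, "histogram", fov).data)
        centers.append(frames[g].mean())
    ref = imgs[0]
    dx = np.zeros(len(imgs))
    dy = np.zeros(len(imgs))
    for i in range(1, len(imgs)):
        shift, _, _ = phase_cross_correlation(ref, imgs[i],
                                              upsample_factor=upsampling,
                                              normalization=None)
        # shift = displacement that moves imgs[i] onto ref, i.e. minus the drift
        dy[i] = -shift[0] * pixel_size
        dx[i] = -shift[1] * pixel_size
    return DriftModel(np.asarray(centers, dtype=float), dx, dy)


def apply_drift(table: LocalizationTable, model: DriftModel) -> LocalizationTable:
    """Subtract the interpolated drift from each event's coordinates.

    Frames outside the model's bin centers are clamped to the end bins.
    """
    frames = table.data["frame"].to_numpy()
    if frames.min() < model.bin_center_frame[0] - 1 or \
       frames.max() > model.bin_center_frame[-1] + 1:
        warnings.warn("frames outside the drift model range; clamping to end bins")
    dx, dy = model(frames)
    data = table.data.copy()
    data["x"] = data["x"] - dx
    data["y"] = data["y"] - dy
    meta = dict(table.meta)
    meta["drift_corrected"] = True
    return LocalizationTable(data, table.extras, meta)


# ---------------------------------------------------------------------------
# astigmatism z


@dataclass
class AstigmatismCalibration:
    """Odd-cubic map between axial position and PSF elongation.

    The elongation metric is ``log(sigma_x / sigma_y)``: antisymmetric in
    z, zero at focus. The fit is ``e(z) = c1 z + c3 z^3`` through the
    origin; ``valid_z_range`` is the largest interval of strict
    monotonicity, inside which the curve can be inverted.
    """

    coefficients: tuple[float, float]  # (c1, c3)
    valid_z_range: tuple[float, float]
    z_grid: np.ndarray
    elongation_per_plane: np.ndarray

    def elongation(self, z: np.ndarray) -> np.ndarray:
        c1, c3 = self.coefficients
        z = np.asarray(z, dtype=float)
        return c1 * z + c3 * z**3

    def invert(self, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map elongation back to z; returns (z, in_range mask)."""
        z_lo, z_hi = self.valid_z_range
        zs = np.linspace(z_lo, z_hi, 2001)
        es = self.elongation(zs)
        if es[0] > es[-1]:
            zs, es = zs[::-1], es[::-1]
        e = np.asarray(e, dtype=float)
        in_range = (e >= es[0]) & (e <= es[-1])
        z = np.interp(e, es, zs)
        return z, in_range


def fit_astigmatism_calibration(table: LocalizationTable,
                                stage_z_per_frame: np.ndarray,
                                min_planes: int = 5,
                                min_elongation_span: float = 0.05,
                                ) -> AstigmatismCalibration:
    """Calibrate the elongation-vs-z curve from bead stacks scanned through focus.

    ``stage_z_per_frame[i]`` is the known stage z (nm) of frame ``i+1``.
    The median ``log(sigma_x/sigma_y)`` per z plane is fitted with an odd
    cubic through the origin; the valid range is the largest interval on
    which the fitted curve is strictly monotonic.
    """
    for col in ("sigma_x", "sigma_y"):
        if col not in table.data.columns:
            raise ParameterError(f"calibration stacks need column {col!r}")
    frames = table.data["frame"].to_numpy().astype(int)
    stage_z = np.asarray(stage_z_per_frame, dtype=float)
    if frames.max() > stage_z.size:
        raise ParameterError("stage_z_per_frame shorter than the frame range")
    z_event = stage_z[frames - 1]
    elong = np.log(table.data["sigma_x"].to_numpy(float) /
                   table.data["sigma_y"].to_numpy(float))
    z_planes = np.unique(z_event)
    if z_planes.size < min_planes:
        raise ParameterError(f"need >= {min_planes} z planes, got {z_planes.size}")
    if not (z_planes.min() < 0 < z_planes.max()):
        raise ParameterError("z scan must span the focus (z = 0)")
    med = np.array([np.median(elong[z_event == z]) for z in z_planes])
    if np.ptp(med) < min_elongation_span:
        raise CalibrationError("no usable astigmatism: elongation is flat in z")
    # odd cubic through the origin, least squares on basis [z, z^3]
    basis = np.column_stack([z_planes, z_planes**3])
    (c1, c3), *_ = np.linalg.lstsq(basis, med, rcond=None)
    # largest interval of strict monotonicity of c1 z + 3... derivative c1 + 3 c3 z^2
    zs = np.linspace(z_planes.min(), z_planes.max(), 2001)
    deriv = c1 + 3 * c3 * zs**2
    sign0 = np.sign(deriv[np.argmin(np.abs(zs))])
    if sign0 == 0 or not np.any(deriv * sign0 > 0):
        raise CalibrationError("fitted elongation curve is not monotonic anywhere")
    ok = deriv * sign0 > 0
    # maximal run of monotonicity containing the focus
    runs = np.split(np.arange(zs.size), np.flatnonzero(np.diff(ok)) + 1)
    best = max((r for r in runs if ok[r[0]]), key=len)
    valid = (float(zs[best[0]]), float(zs[best[-1]]))
    if valid[0] > 0 or valid[1] < 0:
        raise CalibrationError("monotonic interval does not contain the focus")
    return AstigmatismCalibration((float(c1), float(c3)), valid, z_planes, med)


def assign_z(table: LocalizationTable,
             calibration: AstigmatismCalibration | None) -> LocalizationTable:
    """Assign z to each event by inverting the astigmatism calibration.

    Events whose elongation falls outside the calibration's valid range
    are dropped; the count is recorded in ``meta['dropped_out_of_range']``.
    """
    if calibration is None:
        raise StateError("no astigmatism calibration supplied")
    for col in ("sigma_x", "sigma_y"):
        if col not in table.data.columns:
            raise ParameterError(f"z assignment needs column {col!r}")
    elong = np.log(table.data["sigma_x"].to_numpy(float) /
                   table.data["sigma_y"].to_numpy(float))
    z, in_range = calibration.invert(elong)
    data = table.data.loc[in_range].copy().reset_index(drop=True)
    data["z"] = z[in_range]
    extras = table.extras.loc[in_range].reset_index(drop=True) \
        if table.extras is not None else None
    meta = dict(table.meta)
    meta["dropped_out_of_range"] = int(np.sum(~in_range))
    return LocalizationTable(data, extras, meta)
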
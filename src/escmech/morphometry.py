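"""Colony and cell shape metrics.

Side-view colony masks yield the contact angle between the colony edge
and the substrate (dome-like naive colonies meet the substrate at
obtuse angles; spreading primed colonies at acute ones). Top-view actin
masks within the evanescent illumination depth yield per-cell contact
area and aspect ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as cc_label

from .errors import GeometryError, ParameterError
from .orientation import fit_cell_axis

__all__ = [
    "ColonyProfile",
    "ContactAngleResult",
    "ContactAreaResult",
    "measure_contact_angle",
    "measure_contact_area",
    "measure_aspect_ratio",
    "segment_cells",
]


@dataclass
class ColonyProfile:
    """Binary side-view (x, z) mask of a colony on a horizontal substrate.

    ``substrate_row`` is the pixel row of the substrate line (z = 0);
    rows above it (smaller indices) are above the substrate.
    """

    mask: np.ndarray
    substrate_row: int
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise GeometryError("profile mask must be 2D")
        if not (0 <= self.substrate_row < self.mask.shape[0]):
            raise GeometryError("substrate_row outside the image")


@dataclass
class ContactAngleResult:
    mean_angle: float
    per_sample_angles: list[float]
    n_samples: int


@dataclass
class ContactAreaResult:
    area_um2: float
    n_pixels: int
    pixel_size_nm: float
    cell_id: str = ""


def _boundary_points(mask: np.ndarray, substrate_row: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel boundary of the mask as (x, z) with z up from the substrate.

    Marching squares at the 0.5 level; points below the substrate
    (the artificial cut line) are discarded.
    """
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise GeometryError("mask has no boundary contour")
    pts = np.vstack(contours)  # (row, col)
    z = substrate_row - pts[:, 0]
    x = pts[:, 1]
    keep = z >= 0
    return x[keep], z[keep]


def _edge_angle(x: np.ndarray, z: np.ndarray, fit_height: int,
                side: str, method: str) -> float:
    """Interior angle between the substrate and one colony edge.

    Fits the boundary ``x(z)`` over ``fit_height`` px above the
    substrate. The default ``tangent`` method fits a quadratic and
    evaluates its derivative at z = 0, removing the first-order
    curvature bias a straight secant would have on a circular edge.
    """
    sel = z <= fit_height
    xs_arr, zs_arr = x[sel], z[sel]
    if zs_arr.size < 2 or np.ptp(zs_arr) == 0:
        raise GeometryError("not enough boundary points above the substrate")
    if zs_arr.size < 3:
        warnings.warn("fewer boundary points than requested; 2-point secant")
        i0, i1 = np.argmin(zs_arr), np.argmax(zs_arr)
        slope = (xs_arr[i1] - xs_arr[i0]) / (zs_arr[i1] - zs_arr[i0])
    elif method == "secant" or zs_arr.size < 5:
        slope = np.polyfit(zs_arr, xs_arr, 1)[0]
    else:  # tangent
        slope = np.polyfit(zs_arr, xs_arr, 2)[1]
    if side == "left":
        return float(np.degrees(np.arctan2(1.0, slope)))
    return float(np.degrees(np.arctan2(1.0, -slope)))


def _fit_circle(x: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) circle fit; returns (xc, zc, R)."""
    A = np.column_stack([x, z, np.ones_like(x)])
    b = x**2 + z**2
    c, *_ = np.linalg.lstsq(A, b, rcond=None)
    xc, zc = c[0] / 2.0, c[1] / 2.0
    R = float(np.sqrt(c[2] + xc**2 + zc**2))
    return float(xc), float(zc), R


def measure_contact_angle(profile: ColonyProfile, fit_height: int = 15,
                          method: str = "circle") -> ContactAngleResult:
    """Contact angle between a colony's edge and the substrate.

    The sub-pixel boundary contour within ``fit_height`` px above the
    substrate is extracted by marching squares and fitted at the two
    substrate contact points. The default ``circle`` method fits one
    circle through both near-substrate edge arcs (droplet-goniometry
    style; a pixelated edge moves too little over a short window for a
    reliable local polynomial) and reports the tangent angle where the
    circle crosses the substrate, the same at both contacts for a
    circular segment. ``tangent`` (quadratic per side) and ``secant``
    (line per side) are available for non-circular edges. Angles are in
    degrees, interior to the colony.
    """
    if fit_height < 3:
        raise ParameterError("fit_height must be >= 3 px")
    if method not in ("circle", "tangent", "secant"):
        raise ParameterError(f"unknown method {method!r}")
    row = profile.substrate_row
    support = np.flatnonzero(profile.mask[row])
    if support.size == 0:
        raise GeometryError("mask does not touch the substrate row")
    x, z = _boundary_points(profile.mask, row)
    if method == "circle":
        sel = z <= fit_height
        if sel.sum() < 6:
            raise GeometryError("not enough boundary points above the substrate")
        _, zc, R = _fit_circle(x[sel], z[sel])
        theta = float(np.degrees(np.arccos(np.clip(-zc / R, -1.0, 1.0))))
        angles = [theta, theta]  # one per contact point; equal by the fit
    else:
        mid = 0.5 * (support.min() + support.max())
        angles = [
            _edge_angle(x[x < mid], z[x < mid], fit_height, "left", method),
            _edge_angle(x[x >= mid], z[x >= mid], fit_height, "right", method),
        ]
    return ContactAngleResult(mean_angle=float(np.mean(angles)),
                              per_sample_angles=angles,
                              n_samples=len(angles))


def measure_contact_area(actin_mask: np.ndarray, pixel_size_nm: float,
                         cell_id: str = "") -> ContactAreaResult:
    """Substrate contact area of one cell: pixel count times pixel area."""
    if pixel_size_nm <= 0:
        raise ParameterError("pixel_size must be positive")
    mask = np.asarray(actin_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        warnings.warn("empty actin mask: zero contact area")
    area_um2 = n * (pixel_size_nm / 1000.0) ** 2
    return ContactAreaResult(area_um2=float(area_um2), n_pixels=n,
                             pixel_size_nm=float(pixel_size_nm),
                             cell_id=cell_id)


def measure_aspect_ratio(cell_mask: np.ndarray) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse of a mask."""
    return fit_cell_axis(cell_mask).aspect_ratio


def segment_cells(image: np.ndarray, threshold: str | float = "otsu",
                  min_pixels: int = 50) -> np.ndarray:
    """Threshold a rendered actin image and label per-cell components.

    Returns an integer label image (0 = background). The threshold rule
    is configurable and should be reported alongside downstream metrics.
    """
    image = np.asarray(image, dtype=float)
    t = threshold_otsu(image) if threshold == "otsu" else float(threshold)
    labels = cc_label(image > t)
    for lab in range(1, labels.max() + 1):
        if np.sum(labels == lab) < min_pixels:
            labels[labels == lab] = 0
    return cc_label(labels > 0)
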
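"""Surface orientation and landmark depth measurement.

A footprint surface is a gridded elevation field (cm) together with a boolean
mask of the *undisturbed margin* — sediment around the print that was not
deformed by the foot — and the 14 annotated landmark coordinates.  Analysis
orients each surface so that the least-squares plane through the margin becomes
z = 0, then reads depths (positive downward) at the landmarks.

Landmark identification is taken as input: landmarks are annotated coordinates,
not detected automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .schema import DEPTH_LANDMARKS, N_REGIONS, DepthProfile


class DegenerateMarginError(ValueError):
    """Margin mask has fewer than 3 cells, or all its cells are collinear."""


@dataclass(frozen=True)
class ReferencePlane:
    """Best-fit plane z = a*x + b*y + c through the undisturbed margin."""

    a: float
    b: float
    c: float
    residual_rms: float

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x) + self.b * np.asarray(y) + self.c


@dataclass(frozen=True)
class FootprintSurface:
    """Gridded elevation field with margin mask and landmark annotations.

    ``elevations[i, j]`` is the elevation (cm) at
    ``(x, y) = origin + spacing * (j, i)`` — rows index y, columns index x.
    ``landmarks`` maps each of the 14 canonical region names to (x, y) cm.
    """

    origin: tuple[float, float]
    spacing: float
    elevations: np.ndarray = field(repr=False)
    margin_mask: np.ndarray = field(repr=False)
    landmarks: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        z = np.asarray(self.elevations, dtype=float)
        m = np.asarray(self.margin_mask, dtype=bool)
        if z.ndim != 2 or m.shape != z.shape:
            raise ValueError("elevation and margin grids must be congruent 2-D arrays")
        if set(self.landmarks) != set(DEPTH_LANDMARKS):
            raise ValueError(
                "landmarks must be exactly the canonical 14 region names"
            )
        object.__setattr__(self, "elevations", z)
        object.__setattr__(self, "margin_mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """x (ncols,) and y (nrows,) coordinate vectors of the grid nodes."""
        ny, nx = self.elevations.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return x, y


def fit_reference_plane(surface: FootprintSurface) -> ReferencePlane:
    """Least-squares plane through the margin cells.

    Raises :class:`DegenerateMarginError` if fewer than three margin cells are
    set or the set cells are collinear (the plane would be underdetermined).
    """
    mask = surface.margin_mask
    ii, jj = np.nonzero(mask)
    if ii.size < 3:
        raise DegenerateMarginError(
            f"margin mask has {ii.size} cells; at least 3 non-collinear required"
        )
    x = surface.origin[0] + surface.spacing * jj
    y = surface.origin[1] + surface.spacing * ii
    # collinearity check: centred (x, y) must span 2 dimensions
    xy = np.column_stack([x - x.mean(), y - y.mean()])
    if np.linalg.matrix_rank(xy, tol=1e-9 * max(1.0, np.abs(xy).max())) < 2:
        raise DegenerateMarginError("margin cells are collinear; plane fit degenerate")
    z = surface.elevations[ii, jj]
    design = np.column_stack([x, y, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    return ReferencePlane(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]), residual_rms=rms)


def orient_surface(surface: FootprintSurface, plane: ReferencePlane | None = None) -> FootprintSurface:
    """Replace elevations by residuals from the reference plane.

    After orientation the margin plane is z ≈ 0 and depths can be read directly.
    Landmark (x, y) coordinates are unchanged.  Orienting twice is an identity
    up to numerical round-off.
    """
    if plane is None:
        plane = fit_reference_plane(surface)
    x, y = surface.grid_coords()
    xx, yy = np.meshgrid(x, y)
    residuals = surface.elevations - plane.evaluate(xx, yy)
    return replace(surface, elevations=residuals)


def _bilinear(surface: FootprintSurface, x: float, y: float) -> float:
    """Bilinear interpolation of the elevation grid at (x, y)."""
    gx, gy = surface.grid_coords()
    if not (gx[0] <= x <= gx[-1] and gy[0] <= y <= gy[-1]):
        raise ValueError(f"landmark ({x:.3f}, {y:.3f}) lies outside the grid extent")
    fx = (x - gx[0]) / surface.spacing
    fy = (y - gy[0]) / surface.spacing
    j0 = min(int(np.floor(fx)), len(gx) - 2)
    i0 = min(int(np.floor(fy)), len(gy) - 2)
    tx = fx - j0
    ty = fy - i0
    z = surface.elevations
    return float(
        z[i0, j0] * (1 - tx) * (1 - ty)
        + z[i0, j0 + 1] * tx * (1 - ty)
        + z[i0 + 1, j0] * (1 - tx) * ty
        + z[i0 + 1, j0 + 1] * tx * ty
    )


def measure_depths(
    surface: FootprintSurface,
    *,
    local_minimum_radius: float | None = None,
) -> DepthProfile:
    """Depths at the 14 landmarks of an oriented surface.

    Depth is the negated, bilinearly interpolated elevation at each landmark
    (positive = below the reference plane).  With ``local_minimum_radius`` set,
    the maximum depth within that radius (cm) of the landmark is used instead
    of the point sample.  Negative depths (a displacement rim at a landmark)
    are allowed but trigger a warning.
    """
    depths = np.empty(N_REGIONS)
    if local_minimum_radius is not None and local_minimum_radius > 0:
        gx, gy = surface.grid_coords()
        xx, yy = np.meshgrid(gx, gy)
    for k, name in enumerate(DEPTH_LANDMARKS):
        lx, ly = surface.landmarks[name]
        if local_minimum_radius is not None and local_minimum_radius > 0:
            within = (xx - lx) ** 2 + (yy - ly) ** 2 <= local_minimum_radius**2
            if not within.any():
                raise ValueError(f"no grid cells within radius of landmark {name}")
            depths[k] = -float(surface.elevations[within].min())
        else:
            depths[k] = -_bilinear(surface, lx, ly)
    if np.any(depths < 0):
        rims = [DEPTH_LANDMARKS[k] for k in np.nonzero(depths < 0)[0]]
        warnings.warn(
            f"negative depth (displacement rim?) at landmarks: {rims}",
            stacklevel=2,
        )
    return DepthProfile(depths)


def measure_depths_mesh(
    vertices: np.ndarray, landmarks: dict[str, tuple[float, float]]
) -> DepthProfile:
    """Nearest-vertex depths from an (n, 3) oriented mesh vertex array.

    For triangulated meshes the depth at a landmark is taken from the vertex
    nearest in (x, y); the mesh must already be oriented (margin plane z = 0).
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 3:
        raise ValueError("vertices must be an (n, 3) array")
    tree = cKDTree(verts[:, :2])
    pts = np.array([landmarks[name] for name in DEPTH_LANDMARKS])
    _, idx = tree.query(pts)
    return DepthProfile(-verts[idx, 2])


def mean_depth(
    source: FootprintSurface | DepthProfile,
    *,
    outline_mask: np.ndarray | None = None,
) -> tuple[float, str]:
    """Average depth of a print, with the estimator used.

    Two estimators exist because "average depth" is ambiguous for a surface:

    * surface + ``outline_mask``: mean of (−elevation) over the outline cells
      of an oriented surface (``"outline_mean"``; the default for surfaces);
    * :class:`DepthProfile`: mean of the 14 regional depths (``"region_mean"``).

    Returns ``(depth_cm, estimator_name)``.
    """
    if isinstance(source, DepthProfile):
        return float(np.mean(source.values)), "region_mean"
    if outline_mask is None:
        raise ValueError("surface form of mean_depth requires an outline mask")
    mask = np.asarray(outline_mask, dtype=bool)
    if mask.shape != source.elevations.shape:
        raise ValueError("outline mask must be congruent with the elevation grid")
    if not mask.any():
        raise ValueError("outline mask is empty")
    return float(np.mean(-source.elevations[mask])), "outline_mean"


def forefoot_gradient(profile: DepthProfile) -> dict[str, float]:
    """Medial-to-lateral depth slopes across the forefoot.

    Least-squares slope of depth against position index 1..5 over the five
    metatarsal heads (``mt_slope``) and the five toes (``toe_slope``), in cm
    per position.  The human walking pattern — deeper impressions medially,
    from medial pressure transfer and hallucal toe-off — gives negative slopes.
    """
    idx = np.arange(1, 6, dtype=float)
    mt_slope = float(np.polyfit(idx, profile.mt, 1)[0])
    toe_slope = float(np.polyfit(idx, profile.toes, 1)[0])
    return {"mt_slope": mt_slope, "toe_slope": toe_slope}
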
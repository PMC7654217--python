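"""Cord/lesion phantoms with brute-force spared-tissue ground truth.

The phantom cord is an elliptical cylinder on a voxel grid; lesions are
unions of simple geometric primitives (axis-aligned boxes and per-slice
ellipses) whose projected axial footprint can be enumerated exactly.
The ground-truth spared percentages are computed here by direct pixel
enumeration (plain Python loops over the axial grid), independently of
the vectorised quantification in :mod:`cordmotor.lesion`, so the two can
serve as mutual oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from cordmotor.lesion import (
    REGIONS,
    AxialRegionAtlas,
    LesionStudy,
    SparedTissueProfile,
)

__all__ = [
    "BoxLesion",
    "EllipseLesion",
    "PhantomSpec",
    "make_region_atlas",
    "make_cord_phantom",
    "oracle_spared_profile",
    "random_phantom_spec",
]


@dataclass(frozen=True)
class BoxLesion:
    """Axis-aligned box, half-open voxel ranges [x0, x1) x [y0, y1) x [z0, z1)."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def footprint(self, grid_shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[self.x0 : self.x1, self.y0 : self.y1] = True
        return m


@dataclass(frozen=True)
class EllipseLesion:
    """Elliptical axial footprint replicated over slices [z0, z1)."""

    cx: float
    cy: float
    rx: float
    ry: float
    z0: int
    z1: int

    def footprint(self, grid_shape: tuple[int, int]) -> np.ndarray:
        ix, iy = np.indices(grid_shape)
        return ((ix - self.cx) / self.rx) ** 2 + ((iy - self.cy) / self.ry) ** 2 <= 1.0


LesionPrimitive = BoxLesion | EllipseLesion


@dataclass
class PhantomSpec:
    """Parameters of a cord/lesion phantom.

    grid_shape : (nx, ny, nz) voxel counts; cord_radii : (rx, ry) voxel
    radii of the elliptical cord cross-section; lesion_shapes : lesion
    primitives in voxel coordinates (must lie within the cord).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 12)
    cord_radii: tuple[float, float] = (10.0, 8.0)
    lesion_shapes: list[LesionPrimitive] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 1")
        if any(r <= 0 for r in self.cord_radii):
            raise ValueError("cord radii must be positive")


def _cord_geometry(grid_shape: tuple[int, int], cord_radii: tuple[float, float]):
    nx, ny = grid_shape
    rx, ry = cord_radii
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    return cx, cy, rx, ry


def make_region_atlas(
    grid_shape: tuple[int, int],
    cord_radii: tuple[float, float],
    weighting: str = "binary",
) -> AxialRegionAtlas:
    """Axial atlas: four 90-degree angular sectors of an elliptical cord.

    The cord cross-section is the ellipse ``(dx/rx)^2 + (dy/ry)^2 <= 1``
    centred on the grid. Sector membership uses the radii-normalised
    angle ``theta = atan2(dy/ry, dx/rx)`` with half-open 90-degree bins
    centred on the four axis directions: +y is anterior, -y posterior,
    +x left-lateral, -x right-lateral. With ``weighting="binary"`` every
    cord pixel belongs to exactly one sector (weights partition the
    cord); with ``weighting="radial"`` the sector weight ramps linearly
    from 1 at the cord centre to 0 at the cord boundary,
    ``w = 1 - min(r_norm, 1)``, mimicking soft probabilistic tract maps.
    """
    if weighting not in ("binary", "radial"):
        raise ValueError(f"unknown weighting {weighting!r}")
    nx, ny = grid_shape
    rx, ry = cord_radii
    if rx <= 0 or ry <= 0:
        raise ValueError("degenerate cord radii")
    if 2 * rx + 1 > nx or 2 * ry + 1 > ny:
        raise ValueError("grid does not accommodate the cord ellipse")
    cx, cy, rx, ry = _cord_geometry(grid_shape, cord_radii)
    ix, iy = np.indices(grid_shape)
    dxn = (ix - cx) / rx
    dyn = (iy - cy) / ry
    rnorm = np.hypot(dxn, dyn)
    cord = rnorm <= 1.0

    theta = np.degrees(np.arctan2(dyn, dxn))  # (-180, 180], 0 = +x = left
    t = np.mod(theta + 45.0, 360.0)  # half-open 90-degree bins
    sector = {
        "left": (t >= 0) & (t < 90),
        "anterior": (t >= 90) & (t < 180),
        "right": (t >= 180) & (t < 270),
        "posterior": (t >= 270) & (t < 360),
    }
    if weighting == "binary":
        base = np.ones(grid_shape)
    else:
        base = np.clip(1.0 - rnorm, 0.0, 1.0)
        # keep positive support: boundary pixels of the discrete cord can sit
        # exactly at r_norm >= 1; give them a small positive weight so the
        # discrete sector support matches the binary atlas support
        base[cord & (base <= 0)] = 1e-6
    weights = {
        name: np.where(cord & sector[name], base, 0.0) for name in REGIONS
    }
    return AxialRegionAtlas(region_weights=weights, cord_mask_2d=cord)


def make_cord_phantom(
    spec: PhantomSpec, atlas: AxialRegionAtlas | None = None
) -> tuple[LesionStudy, SparedTissueProfile]:
    """Build a cord/lesion phantom plus its ground-truth spared profile.

    The cord is the same elliptical cross-section on every slice; the
    lesion is the union of ``spec.lesion_shapes``. Primitives reaching
    outside the cord are rejected with a diagnostic. The returned profile
    is computed by :func:`oracle_spared_profile` (direct enumeration),
    not by :func:`cordmotor.lesion.spared_profile`.
    """
    nx, ny, nz = spec.grid_shape
    if atlas is None:
        atlas = make_region_atlas((nx, ny), spec.cord_radii)
    if atlas.grid_shape != (nx, ny):
        raise ValueError("atlas grid does not match phantom grid")
    cord2d = atlas.cord_mask_2d
    cord3d = np.repeat(cord2d[:, :, None], nz, axis=2)

    lesion3d = np.zeros((nx, ny, nz), dtype=bool)
    for prim in spec.lesion_shapes:
        if prim.z0 < 0 or prim.z1 > nz:
            raise ValueError(f"lesion primitive {prim} outside slice range [0, {nz})")
        fp = prim.footprint((nx, ny))
        if np.any(fp & ~cord2d):
            raise ValueError(f"lesion primitive {prim} extends outside the cord")
        lesion3d[:, :, prim.z0 : prim.z1] |= fp[:, :, None]

    study = LesionStudy(cord_mask=cord3d, lesion_mask=lesion3d)
    profile = oracle_spared_profile(lesion3d, atlas)
    return study, profile


def oracle_spared_profile(lesion3d: np.ndarray, atlas: AxialRegionAtlas) -> SparedTissueProfile:
    """Ground-truth spared profile by brute-force pixel enumeration.

    Deliberately written with explicit loops (union along the S-I axis by
    scanning voxels, weight sums pixel by pixel) so it is an independent
    oracle for the vectorised quantification path.
    """
    nx, ny, nz = lesion3d.shape
    projected = [[False] * ny for _ in range(nx)]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if lesion3d[i, j, k]:
                    projected[i][j] = True
                    break

    def spared_percent(weight_at) -> float:
        total = 0.0
        spared = 0.0
        for i in range(nx):
            for j in range(ny):
                w = float(weight_at(i, j))
                total += w
                if not projected[i][j]:
                    spared += w
        if total <= 0:
            raise ValueError("zero total region weight")
        return 100.0 * spared / total

    cord = atlas.cord_mask_2d
    values = {"total": spared_percent(lambda i, j: 1.0 if cord[i, j] else 0.0)}
    for name in REGIONS:
        w = atlas.region_weights[name]
        values[name] = spared_percent(lambda i, j: w[i, j])
    return SparedTissueProfile(
        spared_total=values["total"],
        spared_anterior=values["anterior"],
        spared_posterior=values["posterior"],
        spared_left=values["left"],
        spared_right=values["right"],
    )


def random_phantom_spec(
    seed: int,
    grid_shape: tuple[int, int, int] = (24, 24, 8),
    cord_radii: tuple[float, float] = (8.0, 7.0),
    max_lesions: int = 3,
) -> PhantomSpec:
    """Seed-reproducible random lesion geometry inside the cord.

    Primitives are rejection-sampled until fully contained in the cord;
    lesion morphology across real cohorts is not characterised, so the
    shape family (small boxes and ellipses at random depths) is a free
    modelling choice.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    cord2d = make_region_atlas((nx, ny), cord_radii).cord_mask_2d
    shapes: list[LesionPrimitive] = []
    n_lesions = int(rng.integers(1, max_lesions + 1))
    attempts = 0
    while len(shapes) < n_lesions and attempts < 200:
        attempts += 1
        z0 = int(rng.integers(0, nz))
        z1 = int(rng.integers(z0 + 1, nz + 1))
        if rng.random() < 0.5:
            cx0 = int(rng.integers(2, nx - 2))
            cy0 = int(rng.integers(2, ny - 2))
            hw = int(rng.integers(1, 4))
            hh = int(rng.integers(1, 4))
            prim: LesionPrimitive = BoxLesion(
                max(cx0 - hw, 0), min(cx0 + hw, nx), max(cy0 - hh, 0), min(cy0 + hh, ny), z0, z1
            )
        else:
            prim = EllipseLesion(
                cx=float(rng.uniform(4, nx - 5)),
                cy=float(rng.uniform(4, ny - 5)),
                rx=float(rng.uniform(1.0, 3.5)),
                ry=float(rng.uniform(1.0, 3.5)),
                z0=z0,
                z1=z1,
            )
        fp = prim.footprint((nx, ny))
        if fp.any() and not np.any(fp & ~cord2d):
            shapes.append(prim)
    return PhantomSpec(grid_shape=grid_shape, cord_radii=cord_radii, lesion_shapes=shapes, seed=seed)
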
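"""Digital pelvic phantom: voxel grid, volumes of interest, margin expansion.

Coordinate convention (fixed package-wide): x = LR (+x patient left),
y = AP (+y anterior), z = SI (+z superior).  All lengths are millimetres,
voxel coordinates refer to voxel centers, indices are 0-based.  Arrays are
indexed ``[ix, iy, iz]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GridSpec",
    "VOI",
    "Phantom",
    "Margins",
    "OrganSpec",
    "PhantomConfig",
    "build_phantom",
    "expand_margin",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid.

    ``origin`` is the mm position of the center of voxel (0, 0, 0);
    ``axial_crop`` is an optional inclusive slice range along SI restricting
    the dose-calculation region.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    axial_crop: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1 per axis")
        if self.axial_crop is not None:
            lo, hi = self.axial_crop
            if not (0 <= lo <= hi < self.dims[2]):
                raise ValueError("axial_crop must lie within dims along SI")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    def centers(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """(n, 3) voxel-center positions, optionally restricted to a mask."""
        xs, ys, zs = (self.axis_coords(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1)
        if mask is not None:
            return pts[mask]
        return pts.reshape(-1, 3)

    def crop_mask(self) -> np.ndarray:
        """Boolean mask selecting the axial_crop slab (all True if unset)."""
        m = np.ones(self.dims, dtype=bool)
        if self.axial_crop is not None:
            lo, hi = self.axial_crop
            m[:, :, :lo] = False
            m[:, :, hi + 1 :] = False
        return m

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical extent of the grid (outer voxel faces), mm."""
        o = np.asarray(self.origin, dtype=float)
        sp = np.asarray(self.spacing, dtype=float)
        d = np.asarray(self.dims, dtype=float)
        return o - sp / 2.0, o + (d - 0.5) * sp


@dataclass
class VOI:
    """Named boolean voxel mask on a :class:`GridSpec`."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_cm3(self, grid: GridSpec) -> float:
        return self.n_voxels * grid.voxel_volume_cm3

    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())


@dataclass
class Phantom:
    """Voxel phantom: grid, mass density (g/cm^3) and a set of VOIs."""

    grid: GridSpec
    density: np.ndarray
    vois: dict[str, VOI] = field(default_factory=dict)

    def voi(self, name: str) -> VOI:
        try:
            return self.vois[name]
        except KeyError:
            raise KeyError(f"phantom has no VOI named {name!r}") from None

    def add_voi(self, voi: VOI) -> None:
        if voi.mask.shape != tuple(self.grid.dims):
            raise ValueError("VOI mask shape does not match grid dims")
        self.vois[voi.name] = voi


@dataclass(frozen=True)
class Margins:
    """Per-direction expansion margins in mm (all >= 0)."""

    left: float = 0.0
    right: float = 0.0
    ant: float = 0.0
    post: float = 0.0
    sup: float = 0.0
    inf: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_tuple()):
            raise ValueError("margins must be >= 0")

    @classmethod
    def isotropic(cls, m: float) -> "Margins":
        return cls(m, m, m, m, m, m)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.left, self.right, self.ant, self.post, self.sup, self.inf)

    def positive(self) -> np.ndarray:
        """Margins toward +x, +y, +z."""
        return np.array([self.left, self.ant, self.sup], dtype=float)

    def negative(self) -> np.ndarray:
        """Margins toward -x, -y, -z."""
        return np.array([self.right, self.post, self.inf], dtype=float)


@dataclass(frozen=True)
class OrganSpec:
    """Axis-aligned ellipsoid (``kind='ellipsoid'``) or SI-axis cylinder
    (``kind='cylinder'``, semi_axes = (radius_LR, radius_AP, half_length))."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    kind: str = "ellipsoid"

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "cylinder"):
            raise ValueError(f"unknown organ kind {self.kind!r}")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("organ semi-axes must be positive")

    def analytic_volume_cm3(self) -> float:
        a, b, c = self.semi_axes
        if self.kind == "ellipsoid":
            return 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        return np.pi * a * b * (2 * c) / 1000.0

    def mask(self, grid: GridSpec) -> np.ndarray:
        pts = grid.centers().reshape(*grid.dims, 3)
        q = (pts - np.asarray(self.center)) / np.asarray(self.semi_axes)
        if self.kind == "ellipsoid":
            return (q**2).sum(axis=-1) <= 1.0
        return (q[..., 0] ** 2 + q[..., 1] ** 2 <= 1.0) & (np.abs(q[..., 2]) <= 1.0)

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        s = np.asarray(self.semi_axes, dtype=float)
        return c - s, c + s


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry parameters for :func:`build_phantom`.

    The organ layout mimics a male pelvis: target centrally, rectum
    posterior, bladder anterior/superior; all water-equivalent.
    """

    grid: GridSpec
    body: OrganSpec
    ctv: OrganSpec
    rectum: OrganSpec
    bladder: OrganSpec
    density_body: float = 1.0
    density_outside: float = 1e-3

    @classmethod
    def default(cls) -> "PhantomConfig":
        """~48x48x40 voxel phantom (4 mm transversal, 5 mm SI so SI shifts can
        be commensurate with both the grid and the leaf width); CTV ~53 cm^3."""
        dims = (48, 48, 40)
        spacing = (4.0, 4.0, 5.0)
        origin = tuple(-(d - 1) / 2.0 * s for d, s in zip(dims, spacing))
        return cls(
            grid=GridSpec(origin=origin, spacing=spacing, dims=dims),
            body=OrganSpec((0.0, 0.0, 0.0), (90.0, 90.0, 92.0)),
            ctv=OrganSpec((0.0, 0.0, 0.0), (24.0, 22.0, 24.0)),
            rectum=OrganSpec((0.0, -40.0, 0.0), (13.0, 13.0, 50.0), kind="cylinder"),
            bladder=OrganSpec((0.0, 46.0, 26.0), (27.0, 22.0, 25.0)),
        )

    @classmethod
    def small(cls) -> "PhantomConfig":
        """Compact 32^3 phantom at 5 mm spacing for fast tests."""
        dims = (32, 32, 32)
        spacing = (5.0, 5.0, 5.0)
        origin = tuple(-(d - 1) / 2.0 * s for d, s in zip(dims, spacing))
        return cls(
            grid=GridSpec(origin=origin, spacing=spacing, dims=dims),
            body=OrganSpec((0.0, 0.0, 0.0), (72.0, 72.0, 75.0)),
            ctv=OrganSpec((0.0, 0.0, 0.0), (16.0, 15.0, 16.0)),
            rectum=OrganSpec((0.0, -29.0, 0.0), (10.0, 10.0, 35.0), kind="cylinder"),
            bladder=OrganSpec((0.0, 34.0, 19.0), (18.0, 15.0, 16.0)),
        )


def _check_inside_grid(name: str, organ: OrganSpec, grid: GridSpec) -> None:
    lo, hi = grid.bounds()
    olo, ohi = organ.bbox()
    if np.any(olo < lo) or np.any(ohi > hi):
        raise ValueError(f"organ {name!r} extends beyond the grid")


def build_phantom(config: PhantomConfig) -> Phantom:
    """Voxelize the configured organ geometry into a :class:`Phantom`.

    The phantom carries ``body``, ``CTV``, ``rectum`` and ``bladder`` VOIs;
    density is ``density_body`` inside the body and ``density_outside``
    elsewhere.  Raises ``ValueError`` for degenerate organs, organs leaving
    the grid, or OARs overlapping the CTV.
    """
    grid = config.grid
    for name, organ in (
        ("body", config.body),
        ("CTV", config.ctv),
        ("rectum", config.rectum),
        ("bladder", config.bladder),
    ):
        _check_inside_grid(name, organ, grid)

    body = config.body.mask(grid)
    ctv = config.ctv.mask(grid)
    rectum = config.rectum.mask(grid)
    bladder = config.bladder.mask(grid)

    for name, mask in (("body", body), ("CTV", ctv), ("rectum", rectum), ("bladder", bladder)):
        if not mask.any():
            raise ValueError(f"organ {name!r} voxelizes to an empty mask")
    for name, mask in (("rectum", rectum), ("bladder", bladder)):
        if np.any(mask & ctv):
            raise ValueError(f"organ {name!r} overlaps the CTV; adjust the geometry")
    if not ((ctv | rectum | bladder) <= body).all():
        raise ValueError("all organs must lie inside the body")

    density = np.where(body, config.density_body, config.density_outside)
    phantom = Phantom(grid=grid, density=density)
    for name, mask in (("body", body), ("CTV", ctv), ("rectum", rectum), ("bladder", bladder)):
        phantom.add_voi(VOI(name, mask))
    return phantom


def _structuring_element(margins: Margins, spacing: tuple[float, float, float]) -> np.ndarray:
    """Anisotropic octant-ellipsoid structuring element on the voxel lattice."""
    pos = margins.positive()
    neg = margins.negative()
    sp = np.asarray(spacing, dtype=float)
    radii = np.ceil(np.maximum(pos, neg) / sp).astype(int)
    shape = 2 * radii + 1
    offs = [np.arange(-r, r + 1) * s for r, s in zip(radii, sp)]
    ox, oy, oz = np.meshgrid(*offs, indexing="ij")
    total = np.zeros(shape, dtype=float)
    for d, comp in enumerate((ox, oy, oz)):
        m = np.where(comp >= 0, pos[d], neg[d])
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(comp == 0.0, 0.0, (comp / m) ** 2)
        term = np.where(np.isfinite(term), term, np.inf)
        total += term
    return total <= 1.0 + 1e-12


def expand_margin(base: VOI, margins: Margins, grid: GridSpec, name: Optional[str] = None) -> VOI:
    """Anisotropically expand a VOI (e.g. CTV -> PTV).

    The result contains every voxel whose center lies within the
    direction-dependent margin ellipsoid of some base voxel center; it is a
    superset of the base.  Raises if the base is empty or the continuous
    expansion would exit the grid.
    """
    from scipy import ndimage

    if not base.mask.any():
        raise ValueError("cannot expand an empty VOI")
    lo, hi = grid.bounds()
    pts = grid.centers(base.mask)
    if np.any(pts.min(axis=0) - margins.negative() < lo) or np.any(
        pts.max(axis=0) + margins.positive() > hi
    ):
        raise ValueError("margin expansion exits the grid")
    struct = _structuring_element(margins, grid.spacing)
    mask = ndimage.binary_dilation(base.mask, structure=struct)
    return VOI(name or f"{base.name}+margin", mask)
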
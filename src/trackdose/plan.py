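"""Step-and-shoot IMRT plan objects and a heuristic conformal plan generator.

Beam's-eye-view (BEV) convention: for gantry angle g (degrees),

* u (leaf-travel axis)  = (cos g, sin g, 0)
* v (leaf-width axis)   = (0, 0, 1)  -- always SI
* beam axis (direction of travel) = (sin g, -cos g, 0)

so gantry 0 irradiates from anterior and u/v are orthographic coordinates
at the isocenter plane (no divergence scaling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .phantom import Phantom

__all__ = [
    "bev_axes",
    "BeamletGrid",
    "Aperture",
    "Segment",
    "Beam",
    "Plan",
    "generate_plan",
    "SUPPORTED_U_RES",
]

#: supported beamlet widths along leaf travel (mm); v is fixed at leaf width
SUPPORTED_U_RES = (5.0, 2.5, 1.25)

LEAF_WIDTH_MM = 5.0


def bev_axes(gantry_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (u_hat, v_hat, beam_hat) unit vectors for a gantry angle."""
    g = math.radians(gantry_deg)
    u = np.array([math.cos(g), math.sin(g), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    e = np.array([math.sin(g), -math.cos(g), 0.0])
    return u, v, e


@dataclass(frozen=True)
class BeamletGrid:
    """Rectangular BEV fluence grid; beamlet rows align with MLC leaf rows.

    ``u0``/``v0`` are the low edges of the first column/row, in mm at the
    isocenter plane relative to the isocenter.  Beamlets are enumerated
    row-major: index = iv * n_u + iu.
    """

    u0: float
    v0: float
    n_u: int
    n_v: int
    u_res: float = 5.0
    v_res: float = LEAF_WIDTH_MM

    def __post_init__(self) -> None:
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("beamlet grid must have at least one row and column")
        if self.u_res <= 0 or self.v_res <= 0:
            raise ValueError("beamlet resolutions must be positive")
        if self.v_res != LEAF_WIDTH_MM:
            raise ValueError("beamlet v-resolution must equal the 5 mm leaf width")

    @property
    def n_beamlets(self) -> int:
        return self.n_u * self.n_v

    @property
    def u_edges(self) -> np.ndarray:
        return self.u0 + np.arange(self.n_u + 1) * self.u_res

    @property
    def v_edges(self) -> np.ndarray:
        return self.v0 + np.arange(self.n_v + 1) * self.v_res

    @property
    def u_centers(self) -> np.ndarray:
        return self.u0 + (np.arange(self.n_u) + 0.5) * self.u_res

    @property
    def v_centers(self) -> np.ndarray:
        return self.v0 + (np.arange(self.n_v) + 0.5) * self.v_res

    def index(self, iv: int, iu: int) -> int:
        return iv * self.n_u + iu

    def centers(self) -> np.ndarray:
        """(n_beamlets, 2) array of (u, v) centers in enumeration order."""
        uu, vv = np.meshgrid(self.u_centers, self.v_centers)  # (n_v, n_u)
        return np.stack([uu.ravel(), vv.ravel()], axis=1)

    @classmethod
    def from_projection(
        cls,
        u_pts: np.ndarray,
        v_pts: np.ndarray,
        u_res: float = 5.0,
        margin: float = 25.0,
    ) -> "BeamletGrid":
        """Grid covering the projected target plus an isotropic BEV margin,
        with edges snapped to multiples of the resolution."""
        u0 = math.floor((float(np.min(u_pts)) - margin) / u_res) * u_res
        u1 = math.ceil((float(np.max(u_pts)) + margin) / u_res) * u_res
        v0 = math.floor((float(np.min(v_pts)) - margin) / LEAF_WIDTH_MM) * LEAF_WIDTH_MM
        v1 = math.ceil((float(np.max(v_pts)) + margin) / LEAF_WIDTH_MM) * LEAF_WIDTH_MM
        return cls(
            u0=u0,
            v0=v0,
            n_u=int(round((u1 - u0) / u_res)),
            n_v=int(round((v1 - v0) / LEAF_WIDTH_MM)),
            u_res=u_res,
        )


@dataclass
class Aperture:
    """MLC aperture: per-leaf-row (left_tip, right_tip) plus Y collimators.

    ``rows`` is an (n_rows, 2) array of tip positions on the BEV u axis;
    ``left <= right`` per row, equality meaning a closed row.  ``v0`` is the
    low edge of row 0 so rows align with a :class:`BeamletGrid`.
    """

    rows: np.ndarray
    y_jaws: tuple[float, float]
    v0: float
    leaf_width: float = LEAF_WIDTH_MM

    def __post_init__(self) -> None:
        self.rows = np.array(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != 2:
            raise ValueError("aperture rows must be an (n, 2) array")
        if np.any(self.rows[:, 0] > self.rows[:, 1] + 1e-12):
            raise ValueError("left tip must not exceed right tip")
        if self.y_jaws[0] > self.y_jaws[1]:
            raise ValueError("y_jaws must satisfy v_min <= v_max")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    def row_band(self, r: int) -> tuple[float, float]:
        lo = self.v0 + r * self.leaf_width
        return lo, lo + self.leaf_width

    def area_mm2(self) -> float:
        """Open area (mm^2) of the aperture clipped by the jaws."""
        widths = self.rows[:, 1] - self.rows[:, 0]
        v_lo = self.v0 + np.arange(self.n_rows) * self.leaf_width
        v_hi = v_lo + self.leaf_width
        f_v = np.clip(
            (np.minimum(self.y_jaws[1], v_hi) - np.maximum(self.y_jaws[0], v_lo))
            / self.leaf_width,
            0.0,
            1.0,
        )
        return float(np.sum(widths * f_v * self.leaf_width))

    def copy(self) -> "Aperture":
        return Aperture(self.rows.copy(), tuple(self.y_jaws), self.v0, self.leaf_width)


@dataclass
class Segment:
    aperture: Aperture
    planned_mu: float

    def __post_init__(self) -> None:
        if self.planned_mu < 0:
            raise ValueError("planned_mu must be >= 0")


@dataclass
class Beam:
    gantry_deg: float
    segments: list[Segment]
    beamlet_grid: BeamletGrid
    index: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("beam needs at least one segment")
        if not (0.0 <= self.gantry_deg < 360.0):
            raise ValueError("gantry angle must be in [0, 360)")

    @property
    def planned_mu(self) -> float:
        return float(sum(s.planned_mu for s in self.segments))


@dataclass
class Plan:
    beams: list[Beam]
    isocenter: np.ndarray
    prescription_cgy: float = 725.0
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def total_mu(self) -> float:
        return float(sum(b.planned_mu for b in self.beams))


def _conformal_aperture(
    grid: BeamletGrid, u_pts: np.ndarray, v_pts: np.ndarray, margin: float
) -> Aperture:
    """Aperture conformal to the projected target, widened by ``margin``."""
    rows = np.zeros((grid.n_v, 2))
    v_edges = grid.v_edges
    occupied = np.zeros(grid.n_v, dtype=bool)
    for r in range(grid.n_v):
        sel = (v_pts >= v_edges[r]) & (v_pts < v_edges[r + 1])
        if sel.any():
            rows[r] = (u_pts[sel].min() - margin, u_pts[sel].max() + margin)
            occupied[r] = True
    if not occupied.any():
        raise ValueError("target projects onto no leaf row")
    lo = v_edges[:-1][occupied].min()
    hi = v_edges[1:][occupied].max()
    return Aperture(rows=rows, y_jaws=(float(lo), float(hi)), v0=grid.v0)


def _sub_aperture(
    conformal: Aperture, rng: np.random.Generator, min_area_mm2: float
) -> Aperture:
    """Randomly shrunken/offset sub-aperture honouring the minimum area."""
    for attempt in range(8):
        scale = 0.5**attempt
        shrink = rng.uniform(0.10, 0.30) * scale
        rows = conformal.rows.copy()
        open_rows = rows[:, 1] > rows[:, 0]
        w = rows[:, 1] - rows[:, 0]
        off = rng.uniform(-0.15, 0.15, size=rows.shape[0]) * w * scale
        left = rows[:, 0] + shrink * w / 2.0 + off
        right = rows[:, 1] - shrink * w / 2.0 + off
        bad = left > right
        mid = (left + right) / 2.0
        left[bad] = mid[bad]
        right[bad] = mid[bad]
        rows[open_rows, 0] = left[open_rows]
        rows[open_rows, 1] = right[open_rows]
        ap = Aperture(rows, conformal.y_jaws, conformal.v0, conformal.leaf_width)
        if ap.area_mm2() >= min_area_mm2:
            return ap
    return conformal.copy()


def _snap_to_voxel_center(point: np.ndarray, phantom: Phantom) -> np.ndarray:
    o = np.asarray(phantom.grid.origin, dtype=float)
    sp = np.asarray(phantom.grid.spacing, dtype=float)
    idx = np.clip(
        np.round((point - o) / sp), 0, np.asarray(phantom.grid.dims) - 1
    )
    return o + idx * sp


def generate_plan(
    phantom: Phantom,
    n_beams: int = 7,
    segments_per_beam: int = 3,
    total_mu: float = 700.0,
    seed: int = 0,
    target: str = "PTV",
    u_res: float = 5.0,
    bev_margin: float = 25.0,
    aperture_margin: float = 6.0,
    min_area_mm2: float = 400.0,
    mu_ratio: float = 0.6,
    prescription_cgy: float = 725.0,
) -> Plan:
    """Heuristic step-and-shoot plan: evenly spaced gantry angles, segment 1
    conformal to the target BEV projection, further segments shrunken/offset
    sub-apertures, geometric MU split summing exactly to ``total_mu``.

    This is deliberately not inverse optimization; it produces plausible,
    deterministic (per seed) apertures with a minimum segment area.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    if segments_per_beam < 1:
        raise ValueError("segments_per_beam must be >= 1")
    if total_mu <= 0:
        raise ValueError("total_mu must be positive")
    if u_res not in SUPPORTED_U_RES:
        raise ValueError(f"u_res must be one of {SUPPORTED_U_RES}")

    target_voi = phantom.voi(target)
    ctv = phantom.voi("CTV")
    # snap the isocenter to a voxel center so BEV coordinates stay on a
    # dyadic lattice (keeps the homogeneous-phantom shift-invariance exact)
    iso = _snap_to_voxel_center(phantom.grid.centers(ctv.mask).mean(axis=0), phantom)

    pts = phantom.grid.centers(target_voi.mask) - iso
    rng = np.random.default_rng(seed)
    angles = [i * 360.0 / n_beams for i in range(n_beams)]

    # exact MU bookkeeping: remainder trick at both levels
    mu_beam = [total_mu / n_beams] * n_beams
    mu_beam[-1] = total_mu - sum(mu_beam[:-1])
    ratios = np.array([mu_ratio**i for i in range(segments_per_beam)])
    ratios /= ratios.sum()

    beams: list[Beam] = []
    for bi, g in enumerate(angles):
        u_hat, _, _ = bev_axes(g)
        u = pts @ u_hat
        v = pts[:, 2]
        bgrid = BeamletGrid.from_projection(u, v, u_res=u_res, margin=bev_margin)
        conformal = _conformal_aperture(bgrid, u, v, aperture_margin)
        if conformal.area_mm2() < min_area_mm2:
            raise ValueError(
                "minimum segment area constraint unsatisfiable for the conformal aperture"
            )
        apertures = [conformal]
        for _ in range(1, segments_per_beam):
            apertures.append(_sub_aperture(conformal, rng, min_area_mm2))
        mus = [mu_beam[bi] * r for r in ratios]
        mus[-1] = mu_beam[bi] - sum(mus[:-1])
        segments = [Segment(a, m) for a, m in zip(apertures, mus)]
        beams.append(Beam(gantry_deg=g, segments=segments, beamlet_grid=bgrid, index=bi))

    return Plan(
        beams=beams,
        isocenter=iso,
        prescription_cgy=prescription_cgy,
        seed=seed,
        meta={"n_beams": n_beams, "segments_per_beam": segments_per_beam},
    )
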
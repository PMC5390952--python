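"""Pre-calculated dose influence matrices from a synthetic pencil-beam kernel.

The kernel replaces a treatment-planning-system dose engine with a
documented analytic form adequate for a homogeneous, water-equivalent
pelvis:

    D(voxel) = C * exp(-mu * depth) * exp(-r^2 / (2 sigma^2))

where ``depth`` is measured along the beam axis from a fixed entry plane
(chosen so the isocenter sits at the calibration depth), ``r`` is the
lateral distance from the beamlet ray, and ``C`` is calibrated so a unit
open weight delivers ``cal_cgy_per_mu`` cGy/MU on the central axis at the
calibration depth.  Because the kernel depends only on offsets from the
beamlet ray, translating a beamlet translates its dose column exactly
(shift invariance), which the reconstruction tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse

from .phantom import Phantom
from .plan import Beam, bev_axes

__all__ = ["KernelConfig", "DoseInfluenceMatrix", "compute_dose_influence", "default_region_mask"]


@dataclass(frozen=True)
class KernelConfig:
    mu_mm: float = 0.005          # effective linear attenuation, 1/mm
    sigma_mm: float = 3.0         # lateral Gaussian spread, mm
    cal_cgy_per_mu: float = 1.0   # central-axis dose at cal_depth, cGy/MU
    cal_depth_mm: float = 100.0   # calibration depth (isocenter depth)
    cutoff_sigma: float = 4.0     # lateral truncation radius in sigmas

    def __post_init__(self) -> None:
        if min(self.mu_mm, self.sigma_mm, self.cal_cgy_per_mu, self.cal_depth_mm, self.cutoff_sigma) <= 0:
            raise ValueError("kernel parameters must be positive")


@dataclass
class DoseInfluenceMatrix:
    """Sparse beamlet -> voxel dose map for one beam (cGy per MU at unit weight).

    ``matrix`` has shape (n_region_voxels, n_beamlets); ``region_idx`` maps
    rows to flat voxel indices on the phantom grid.  Columns follow the
    beam's :class:`~trackdose.plan.BeamletGrid` enumeration.
    """

    beam_index: int
    matrix: sparse.csc_matrix
    region_idx: np.ndarray
    grid_dims: tuple[int, int, int]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    def column_dense(self, j: int) -> np.ndarray:
        """Dense dose grid (full dims) of a single beamlet column."""
        out = np.zeros(int(np.prod(self.grid_dims)))
        col = self.matrix.getcol(j)
        out[self.region_idx[col.indices]] = col.data
        return out.reshape(self.grid_dims)


def default_region_mask(phantom: Phantom) -> np.ndarray:
    """Dose-calculation region: the body, intersected with the axial crop."""
    return phantom.voi("body").mask & phantom.grid.crop_mask()


def compute_dose_influence(
    phantom: Phantom,
    beam: Beam,
    isocenter: np.ndarray,
    kernel: KernelConfig = KernelConfig(),
    region_mask: Optional[np.ndarray] = None,
) -> DoseInfluenceMatrix:
    """Rasterize the analytic kernel for every beamlet of one beam.

    A beamlet ray missing the region yields an empty sparse column (not an
    error).  All entries are >= 0 and zero outside the region.
    """
    grid = phantom.grid
    if region_mask is None:
        region_mask = default_region_mask(phantom)
    region_idx = np.flatnonzero(region_mask.ravel())
    pts = grid.centers(region_mask)
    q = pts - np.asarray(isocenter, dtype=float)

    u_hat, _, e_hat = bev_axes(beam.gantry_deg)
    u_p = q @ u_hat
    v_p = q[:, 2]
    depth = q @ e_hat + kernel.cal_depth_mm
    cal_c = kernel.cal_cgy_per_mu * math.exp(kernel.mu_mm * kernel.cal_depth_mm)
    attn = cal_c * np.exp(-kernel.mu_mm * depth)

    cutoff = kernel.cutoff_sigma * kernel.sigma_mm
    inv_2s2 = 1.0 / (2.0 * kernel.sigma_mm**2)

    order = np.argsort(u_p, kind="stable")
    u_sorted = u_p[order]

    bg = beam.beamlet_grid
    centers = bg.centers()
    data_parts: list[np.ndarray] = []
    row_parts: list[np.ndarray] = []
    indptr = np.zeros(bg.n_beamlets + 1, dtype=np.int64)
    nnz = 0
    for j in range(bg.n_beamlets):
        u_c, v_c = centers[j]
        lo = np.searchsorted(u_sorted, u_c - cutoff)
        hi = np.searchsorted(u_sorted, u_c + cutoff, side="right")
        cand = order[lo:hi]
        if cand.size:
            dv = v_p[cand] - v_c
            keep = np.abs(dv) <= cutoff
            cand = cand[keep]
        if cand.size:
            du = u_p[cand] - u_c
            dv = v_p[cand] - v_c
            r2 = du * du + dv * dv
            keep = r2 <= cutoff * cutoff
            cand = cand[keep]
            vals = attn[cand] * np.exp(-r2[keep] * inv_2s2)
        else:
            vals = np.empty(0)
        srt = np.argsort(cand, kind="stable")
        row_parts.append(cand[srt].astype(np.int64))
        data_parts.append(vals[srt])
        nnz += cand.size
        indptr[j + 1] = nnz

    matrix = sparse.csc_matrix(
        (
            np.concatenate(data_parts) if data_parts else np.empty(0),
            np.concatenate(row_parts) if row_parts else np.empty(0, dtype=np.int64),
            indptr,
        ),
        shape=(region_idx.size, bg.n_beamlets),
    )
    return DoseInfluenceMatrix(
        beam_index=beam.index,
        matrix=matrix,
        region_idx=region_idx,
        grid_dims=tuple(grid.dims),
    )
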
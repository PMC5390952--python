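"""Per-aperture dose reconstruction.

For every reported MLC aperture the loop (i) finds the target position
closest in time, (ii) selects the beam's dose influence matrix, (iii)
assigns each beamlet a geometric overlap weight in [0, 1], (iv-v) forms the
dose increment weighted by the incremental MU since the previous report
(beam-off apertures included), and (vi) accumulates it: once onto the
static anatomy and once into the moving target VOIs, sampled by trilinear
interpolation at the displaced/rotated voxel centers ("MLC+VOI").  The
alternative "MLC-only" method instead applies the residual BEV shift
(MLC motion minus target motion) to the planned aperture and keeps every
VOI static.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import compute_metrics
from .delivery import ApertureReport, DeliveryRecord, MachineStateStream, project_to_bev, track_aperture
from .influence import DoseInfluenceMatrix, default_region_mask
from .motion import RotationSpec, Trajectory, displace_and_rotate, nearest_index
from .phantom import Phantom
from .plan import Aperture, BeamletGrid, Plan

__all__ = [
    "METHODS",
    "DeliveredAperture",
    "DoseAccumulator",
    "ReconstructionResult",
    "associate_machine_state",
    "nearest_target_sample",
    "beamlet_weights",
    "aperture_dose_increment",
    "trilinear_sample",
    "accumulate",
    "reconstruct",
    "sweep_offsets",
    "sweep_rotations",
]

METHODS = ("mlc_voi", "mlc_only")


@dataclass
class DeliveredAperture:
    """An aperture report joined with its machine state and target sample."""

    report: ApertureReport
    state_index: int
    incremental_mu: float
    target_d: np.ndarray

    def __post_init__(self) -> None:
        if self.incremental_mu < 0:
            raise ValueError("incremental_mu must be >= 0")


def associate_machine_state(
    report: ApertureReport,
    states: MachineStateStream,
    prev_cum_mu: float = 0.0,
) -> DeliveredAperture:
    """Join one report with the nearest machine state (ties -> earlier).

    ``incremental_mu`` is the associated cumulative MU minus the previous
    report's (0 baseline for the first report).  A decreasing cumulative MU
    indicates stream corruption and raises.
    """
    if len(states) == 0:
        raise ValueError("machine stream is empty")
    idx = nearest_index(states.t, report.t)
    inc = float(states.cum_mu[idx]) - prev_cum_mu
    if inc < -1e-9:
        raise ValueError("cumulative MU decreased: machine stream corrupted")
    return DeliveredAperture(
        report=report, state_index=idx, incremental_mu=max(inc, 0.0), target_d=np.zeros(3)
    )


def nearest_target_sample(t: float, traj: Trajectory) -> np.ndarray:
    """Target displacement closest in time (ties -> earlier; clamps at ends)."""
    return traj.nearest(t)


def beamlet_weights(aperture: Aperture, grid: BeamletGrid) -> np.ndarray:
    """Geometric beamlet transmission weights in [0, 1].

    weight = (open fraction of the beamlet's u-interval within the row's
    [left, right]) x (open fraction of its v-interval within the Y jaws).
    Partially covered beamlets interpolate linearly between closed (0) and
    open (1).
    """
    if aperture.n_rows != grid.n_v:
        raise ValueError("aperture rows must align with the beamlet grid rows")
    if aperture.leaf_width != grid.v_res or aperture.v0 != grid.v0:
        raise ValueError("aperture leaf rows are not aligned with the beamlet grid")
    u_lo = grid.u_edges[:-1]
    u_hi = grid.u_edges[1:]
    left = aperture.rows[:, 0:1]
    right = aperture.rows[:, 1:2]
    f_u = np.clip(
        (np.minimum(right, u_hi[None, :]) - np.maximum(left, u_lo[None, :])) / grid.u_res,
        0.0,
        1.0,
    )
    v_lo = grid.v_edges[:-1]
    v_hi = grid.v_edges[1:]
    f_v = np.clip(
        (np.minimum(aperture.y_jaws[1], v_hi) - np.maximum(aperture.y_jaws[0], v_lo))
        / grid.v_res,
        0.0,
        1.0,
    )
    return (f_v[:, None] * f_u).ravel()


def aperture_dose_increment(
    weights: np.ndarray, dij: DoseInfluenceMatrix, incremental_mu: float
) -> np.ndarray:
    """Dose increment over the calculation region:
    incremental_mu * sum_b weight_b * D_b.  Zero MU yields a zero increment
    but the beamlet dose path is still exercised."""
    vals = dij.matrix @ weights
    vals *= incremental_mu
    return vals


def trilinear_sample(vol: np.ndarray, frac_idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a 3D volume at fractional voxel indices.

    Positions outside the grid contribute zero.  Exact (bitwise) at integer
    indices.
    """
    dims = vol.shape
    i0 = np.floor(frac_idx).astype(np.int64)
    f = frac_idx - i0
    out = np.zeros(frac_idx.shape[0])
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = i0 + off
        w = np.ones(frac_idx.shape[0])
        for a in range(3):
            w = w * (f[:, a] if off[a] else (1.0 - f[:, a]))
        valid = np.all((idx >= 0) & (idx < np.array(dims)), axis=1)
        if not valid.any():
            continue
        vals = np.zeros_like(w)
        vals[valid] = vol[idx[valid, 0], idx[valid, 1], idx[valid, 2]]
        out += np.where(w != 0.0, w * vals, 0.0)
    return out


@dataclass
class DoseAccumulator:
    """Static-anatomy dose grid plus per-VOI target-tracked dose vectors."""

    phantom: Phantom
    region_idx: np.ndarray
    static_region: np.ndarray
    target_dose: dict[str, np.ndarray]
    mu_processed: float = 0.0
    out_of_region_warnings: int = 0

    @classmethod
    def empty(cls, phantom: Phantom, region_idx: np.ndarray, moving_vois: Sequence[str]) -> "DoseAccumulator":
        return cls(
            phantom=phantom,
            region_idx=region_idx,
            static_region=np.zeros(region_idx.size),
            target_dose={
                name: np.zeros(phantom.voi(name).n_voxels) for name in moving_vois
            },
        )

    @property
    def static_dose(self) -> np.ndarray:
        """Dense static-anatomy dose grid (cGy)."""
        flat = np.zeros(self.phantom.grid.n_voxels)
        flat[self.region_idx] = self.static_region
        return flat.reshape(self.phantom.grid.dims)


class _TargetMapper:
    """Precomputed displaced-sampling machinery for the moving VOIs."""

    def __init__(
        self,
        phantom: Phantom,
        region_mask: np.ndarray,
        moving_vois: Sequence[str],
        rotation: Optional[RotationSpec],
        offset: Optional[np.ndarray],
        pivot: np.ndarray,
    ) -> None:
        grid = phantom.grid
        self.origin = np.asarray(grid.origin, dtype=float)
        self.spacing = np.asarray(grid.spacing, dtype=float)
        self.dims = np.asarray(grid.dims)
        self.region_mask = region_mask
        self.offset = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
        if rotation is not None and rotation.pivot is None:
            rotation = RotationSpec(rotation.pitch_deg, rotation.roll_deg, tuple(pivot))
        self.base: dict[str, np.ndarray] = {}
        self.flat_idx: dict[str, np.ndarray] = {}
        for name in moving_vois:
            voi = phantom.voi(name)
            pts = grid.centers(voi.mask)
            self.base[name] = displace_and_rotate(pts, rotation, np.zeros(3))
            self.flat_idx[name] = voi.flat_indices()

    def sample(self, buf3d: np.ndarray, name: str, d: np.ndarray) -> tuple[np.ndarray, int]:
        pts = self.base[name] + (d + self.offset)
        frac = (pts - self.origin) / self.spacing
        vals = trilinear_sample(buf3d, frac)
        ni = np.round(frac).astype(np.int64)
        inside = np.all((ni >= 0) & (ni < self.dims), axis=1)
        n_out = int(inside.size - inside.sum())
        if inside.any():
            sub = ni[inside]
            n_out += int((~self.region_mask[sub[:, 0], sub[:, 1], sub[:, 2]]).sum())
        return vals, n_out


def accumulate(
    acc: DoseAccumulator,
    inc_region: np.ndarray,
    delivered: DeliveredAperture,
    method: str,
    mapper: _TargetMapper,
    buf: np.ndarray,
) -> DoseAccumulator:
    """Apply one aperture's dose increment to the accumulator.

    ``static_dose`` always receives the increment.  Under ``mlc_voi`` the
    moving VOIs additionally sample the increment at their displaced/rotated
    voxel centers; samples escaping the calculation region contribute zero
    and bump a warning counter.  Under ``mlc_only`` the moving VOIs read
    static positions.
    """
    acc.static_region += inc_region
    acc.mu_processed += delivered.incremental_mu
    if not acc.target_dose:
        return acc
    flat = buf.ravel()
    flat[:] = 0.0
    flat[acc.region_idx] = inc_region
    if method == "mlc_voi":
        for name in acc.target_dose:
            vals, n_out = mapper.sample(buf, name, delivered.target_d)
            acc.target_dose[name] += vals
            acc.out_of_region_warnings += n_out
    else:
        for name in acc.target_dose:
            acc.target_dose[name] += flat[mapper.flat_idx[name]]
    return acc


@dataclass
class ReconstructionResult:
    accumulator: DoseAccumulator
    method: str
    mode: str
    voi_doses: dict[str, np.ndarray]
    n_updates: int
    provenance: dict = field(default_factory=dict)

    @property
    def static_dose(self) -> np.ndarray:
        return self.accumulator.static_dose

    @property
    def mu_processed(self) -> float:
        return self.accumulator.mu_processed


def reconstruct(
    record: DeliveryRecord,
    phantom: Phantom,
    plan: Plan,
    dijs: dict[int, DoseInfluenceMatrix],
    trajectory: Optional[Trajectory] = None,
    method: str = "mlc_voi",
    rotation: Optional[RotationSpec] = None,
    offset: Optional[np.ndarray] = None,
    moving_vois: Sequence[str] = ("CTV", "PTV"),
    region_mask: Optional[np.ndarray] = None,
) -> ReconstructionResult:
    """Run the per-aperture reconstruction loop over a delivery record.

    ``trajectory`` defaults to the record's own trajectory; for static
    records it may be None (zero displacement).  ``offset`` is a constant
    interfractional displacement added to every target sample; ``rotation``
    is applied to the entire fraction in the target mapping only (tracking
    is unchanged).  ``mlc_only`` replaces each reported aperture by the
    planned aperture shifted by (applied tracking shift - projected target
    shift) and keeps all VOIs static.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; options: {METHODS}")
    if method == "mlc_only" and record.mode == "static":
        raise ValueError("mlc_only is only defined for tracked/conventional deliveries")
    traj = trajectory if trajectory is not None else record.trajectory
    if traj is None and record.mode != "static":
        raise ValueError(f"{record.mode} reconstruction requires a trajectory")

    moving_vois = [n for n in moving_vois if n in phantom.vois]
    grid = phantom.grid
    if region_mask is None:
        region_mask = default_region_mask(phantom)
    region_idx = np.flatnonzero(region_mask.ravel())

    report_t = np.array([r.t for r in record.reports])
    if np.any(np.diff(report_t) < 0):
        raise ValueError("aperture reports are out of time order")
    states = record.states
    if np.any(np.diff(states.cum_mu) < -1e-12):
        raise ValueError("cumulative MU decreased: machine stream corrupted")
    for bi in sorted({r.beam_index for r in record.reports}):
        if bi not in dijs:
            raise KeyError(f"missing dose influence matrix for beam {bi}")
        if dijs[bi].region_idx.size != region_idx.size or not np.array_equal(
            dijs[bi].region_idx, region_idx
        ):
            raise ValueError("dose influence matrices use a different calculation region")

    # vectorized state association (nearest, ties -> earlier)
    j = np.searchsorted(states.t, report_t)
    j = np.clip(j, 1, len(states) - 1)
    pick_left = (report_t - states.t[j - 1]) <= (states.t[j] - report_t)
    state_idx = np.where(pick_left, j - 1, j)
    state_idx[report_t <= states.t[0]] = 0
    cum = states.cum_mu[state_idx]
    inc_mu = np.diff(np.concatenate([[0.0], cum]))

    acc = DoseAccumulator.empty(phantom, region_idx, moving_vois)
    mapper = _TargetMapper(
        phantom, region_mask, moving_vois, rotation, offset, np.asarray(plan.isocenter)
    )
    buf = np.zeros(grid.dims)

    for k, rpt in enumerate(record.reports):
        beam = plan.beams[rpt.beam_index]
        d_t = traj.nearest(rpt.t) if traj is not None else np.zeros(3)
        if method == "mlc_only":
            target_shift = project_to_bev(
                d_t + mapper.offset, beam.gantry_deg
            )
            residual = (
                rpt.applied_shift[0] - target_shift[0],
                rpt.applied_shift[1] - target_shift[1],
            )
            planned_ap = beam.segments[rpt.segment_index].aperture
            ap, _ = track_aperture(planned_ap, residual)
        else:
            ap = rpt.aperture
        w = beamlet_weights(ap, beam.beamlet_grid)
        inc_region = aperture_dose_increment(w, dijs[rpt.beam_index], float(inc_mu[k]))
        delivered = DeliveredAperture(
            report=rpt,
            state_index=int(state_idx[k]),
            incremental_mu=float(inc_mu[k]),
            target_d=d_t,
        )
        if inc_mu[k] != 0.0:
            accumulate(acc, inc_region, delivered, method, mapper, buf)
        else:
            acc.static_region += inc_region  # all zeros; path exercised

    voi_doses: dict[str, np.ndarray] = {}
    static_flat = np.zeros(grid.n_voxels)
    static_flat[region_idx] = acc.static_region
    for name, voi in phantom.vois.items():
        if method == "mlc_voi" and name in acc.target_dose:
            voi_doses[name] = acc.target_dose[name].copy()
        else:
            voi_doses[name] = static_flat[voi.flat_indices()]

    provenance = {
        "mode": record.mode,
        "method": method,
        "seed": record.seed,
        "plan_seed": plan.seed,
        "trajectory_archetype": getattr(traj, "archetype", None),
        "rotation": (rotation.pitch_deg, rotation.roll_deg) if rotation else None,
        "offset_mm": None if offset is None else list(np.asarray(offset, dtype=float)),
        "beamlet_u_res_mm": plan.beams[0].beamlet_grid.u_res,
        "out_of_region_warnings": acc.out_of_region_warnings,
    }
    return ReconstructionResult(
        accumulator=acc,
        method=method,
        mode=record.mode,
        voi_doses=voi_doses,
        n_updates=len(record.reports),
        provenance=provenance,
    )


def _metric_row(result: ReconstructionResult, phantom: Phantom, prescription: float) -> dict:
    rep = compute_metrics(result, phantom, prescription_cgy=prescription)
    return dict(rep.values)


def sweep_offsets(
    record: DeliveryRecord,
    static_record: DeliveryRecord,
    phantom: Phantom,
    plan: Plan,
    dijs: dict[int, DoseInfluenceMatrix],
    offsets: Sequence[np.ndarray],
    trajectory: Optional[Trajectory] = None,
    moving_vois: Sequence[str] = ("CTV", "PTV"),
) -> pd.DataFrame:
    """One conventional reconstruction per interfractional offset, paired
    with the offset-shifted static reference (static delivery whose target
    mapping is displaced by the same offset)."""
    if record.mode != "conventional":
        raise ValueError("offset sweeps are defined for conventional deliveries")
    rows = []
    for off in offsets:
        res = reconstruct(
            record, phantom, plan, dijs, trajectory=trajectory, offset=off,
            moving_vois=moving_vois,
        )
        ref = reconstruct(
            static_record, phantom, plan, dijs, offset=off, moving_vois=moving_vois,
        )
        row = {
            "offset_lr_mm": off[0],
            "offset_ap_mm": off[1],
            "offset_si_mm": off[2],
        }
        met = _metric_row(res, phantom, plan.prescription_cgy)
        ref_met = _metric_row(ref, phantom, plan.prescription_cgy)
        row.update(met)
        row.update({f"static_{k}": v for k, v in ref_met.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_rotations(
    record: DeliveryRecord,
    phantom: Phantom,
    plan: Plan,
    dijs: dict[int, DoseInfluenceMatrix],
    rotations: Sequence[RotationSpec],
    trajectory: Optional[Trajectory] = None,
    moving_vois: Sequence[str] = ("CTV", "PTV"),
) -> pd.DataFrame:
    """One tracked reconstruction per rotation; the rotation is constant over
    the fraction and applied only in the target-dose mapping."""
    if record.mode != "tracked":
        raise ValueError("rotation sweeps are defined for tracked deliveries")
    rows = []
    for rot in rotations:
        res = reconstruct(
            record, phantom, plan, dijs, trajectory=trajectory, rotation=rot,
            moving_vois=moving_vois,
        )
        row = {"pitch_deg": rot.pitch_deg, "roll_deg": rot.roll_deg}
        row.update(_metric_row(res, phantom, plan.prescription_cgy))
        rows.append(row)
    return pd.DataFrame(rows)
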
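"""Step-and-shoot delivery simulation: asynchronous aperture and
machine-state streams in three modes (static / conventional / tracked).

Apertures are reported on a 40 ms cadence and machine states on a 20 ms
cadence; additional reports are emitted at the exact beam-on/beam-off phase
boundaries so incremental monitor units telescope exactly onto the segment
that delivered them.  Leaf dynamics are idealized (infinite leaf speed):
the tracked aperture equals the ideal shifted aperture at each report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .motion import LatencyModel, Trajectory, delayed_view
from .plan import Aperture, Plan

__all__ = [
    "MODES",
    "TimingConfig",
    "MachineStateStream",
    "ApertureReport",
    "DeliveryRecord",
    "project_to_bev",
    "track_aperture",
    "simulate_delivery",
]

MODES = ("static", "conventional", "tracked")


@dataclass(frozen=True)
class TimingConfig:
    aperture_interval_s: float = 0.040
    state_interval_s: float = 0.020
    hold_s: float = 2.0               # beam-off hold at each segment change
    dose_rate_mu_min: float = 300.0

    def __post_init__(self) -> None:
        if self.aperture_interval_s <= 0 or self.state_interval_s <= 0:
            raise ValueError("stream intervals must be positive")
        if self.hold_s < 0:
            raise ValueError("hold must be >= 0")

    @property
    def dose_rate_mu_s(self) -> float:
        return self.dose_rate_mu_min / 60.0


@dataclass
class MachineStateStream:
    """Columnar machine-state stream (time-sorted)."""

    t: np.ndarray
    cum_mu: np.ndarray
    dose_rate: np.ndarray     # MU/min
    gantry_deg: np.ndarray
    beam_on: np.ndarray       # bool

    def __post_init__(self) -> None:
        n = self.t.size
        if any(a.shape != (n,) for a in (self.cum_mu, self.dose_rate, self.gantry_deg, self.beam_on)):
            raise ValueError("machine state columns must share one length")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("machine states must be time-sorted")
        if np.any(np.diff(self.cum_mu) < -1e-12):
            raise ValueError("cumulative MU must be non-decreasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class ApertureReport:
    """One timestamped MLC aperture, tagged with beam/segment and the BEV
    tracking shift actually applied (zero for static/conventional)."""

    t: float
    beam_index: int
    segment_index: int
    aperture: Aperture
    applied_shift: tuple[float, float] = (0.0, 0.0)
    clamped: bool = False


@dataclass
class DeliveryRecord:
    mode: str
    reports: list[ApertureReport]
    states: MachineStateStream
    timing: TimingConfig
    plan: Plan
    trajectory: Optional[Trajectory] = None
    latency: Optional[LatencyModel] = None
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def final_cum_mu(self) -> float:
        return float(self.states.cum_mu[-1])

    @property
    def duration_s(self) -> float:
        return float(self.states.t[-1])


def project_to_bev(d: np.ndarray, gantry_deg: float) -> tuple[float, float]:
    """Orthographic BEV projection of a 3D displacement.

    u (leaf travel) = d_LR cos g + d_AP sin g; v (leaf width) = d_SI.
    The component along the beam axis is discarded.
    """
    g = math.radians(gantry_deg)
    return (float(d[0] * math.cos(g) + d[1] * math.sin(g)), float(d[2]))


def track_aperture(
    planned: Aperture,
    shift: tuple[float, float],
    leaf_travel_mm: tuple[float, float] = (-200.0, 200.0),
    jaw_travel_mm: tuple[float, float] = (-200.0, 200.0),
) -> tuple[Aperture, bool]:
    """Translate the planned open region by a BEV shift (u, v).

    Each output row takes the planned open interval of the row containing
    (row center - v), shifted by +u; rows mapping outside the planned grid
    close.  Y jaws shift by v.  Values escaping the travel ranges are
    clamped and flagged (second return value).
    """
    u, v = shift
    n = planned.n_rows
    lw = planned.leaf_width
    out = np.zeros((n, 2))
    centers = planned.v0 + (np.arange(n) + 0.5) * lw
    src = np.floor((centers - v - planned.v0) / lw).astype(int)
    valid = (src >= 0) & (src < n)
    out[valid] = planned.rows[src[valid]] + u
    # closed rows park at the shifted planned row midline
    closed_mid = planned.rows.mean(axis=1).mean() + u if n else 0.0
    out[~valid] = closed_mid

    clamped = False
    lo, hi = leaf_travel_mm
    if np.any(out < lo) or np.any(out > hi):
        clamped = True
        out = np.clip(out, lo, hi)
    jaws = [planned.y_jaws[0] + v, planned.y_jaws[1] + v]
    jlo, jhi = jaw_travel_mm
    if jaws[0] < jlo or jaws[1] > jhi:
        clamped = True
        jaws = [min(max(jaws[0], jlo), jhi), min(max(jaws[1], jlo), jhi)]
    ap = Aperture(rows=out, y_jaws=(jaws[0], jaws[1]), v0=planned.v0, leaf_width=lw)
    return ap, clamped


@dataclass(frozen=True)
class _Phase:
    t0: float
    t1: float
    beam: int
    segment: int
    on: bool
    mu0: float
    mu1: float


def _build_phases(plan: Plan, timing: TimingConfig) -> list[_Phase]:
    phases: list[_Phase] = []
    t = 0.0
    mu = 0.0
    rate = timing.dose_rate_mu_s
    for beam in plan.beams:
        for si, seg in enumerate(beam.segments):
            t1 = t + timing.hold_s
            phases.append(_Phase(t, t1, beam.index, si, False, mu, mu))
            t = t1
            dur = seg.planned_mu / rate
            mu1 = mu + seg.planned_mu
            phases.append(_Phase(t, t + dur, beam.index, si, True, mu, mu1))
            t += dur
            mu = mu1
    last = plan.beams[-1]
    phases.append(_Phase(t, t + timing.hold_s, last.index, len(last.segments) - 1, False, mu, mu))
    return phases


def _phase_at(phase_ends: np.ndarray, phases: list[_Phase], t: float, side: str = "left") -> _Phase:
    """Phase containing t.  side='left' treats phases as (start, end] (used
    for aperture shapes, so the boundary report at a beam-on end still
    carries the delivering segment); side='right' treats them as
    [start, end) (used for machine states, so beam_on flips exactly at the
    transition time)."""
    i = int(np.searchsorted(phase_ends, t, side=side))
    return phases[min(i, len(phases) - 1)]


def _cum_mu_at(phase: _Phase, t: float, rate: float) -> float:
    if not phase.on:
        return phase.mu0
    if t >= phase.t1:
        return phase.mu1
    return min(phase.mu0 + rate * (t - phase.t0), phase.mu1)


def simulate_delivery(
    plan: Plan,
    mode: str,
    trajectory: Optional[Trajectory] = None,
    latency: Optional[LatencyModel] = None,
    timing: TimingConfig = TimingConfig(),
    seed: int = 0,
) -> DeliveryRecord:
    """Simulate one full delivery as asynchronous aperture + state streams.

    Beams are delivered sequentially; each segment is a beam-off hold (the
    aperture moves to the segment shape) followed by beam-on for
    planned_mu / dose_rate.  Beam-off apertures are still reported.  In
    tracked mode every report is shifted by the BEV projection of the
    latency-delayed target position.
    """
    if mode not in MODES:
        raise ValueError(f"unknown delivery mode {mode!r}; options: {MODES}")
    if timing.dose_rate_mu_min <= 0:
        raise ValueError("dose rate must be positive")
    if mode in ("conventional", "tracked") and trajectory is None:
        raise ValueError(f"{mode} delivery requires a trajectory")
    if mode == "tracked" and latency is None:
        latency = LatencyModel(seed=seed)

    rate = timing.dose_rate_mu_s
    phases = _build_phases(plan, timing)
    phase_ends = np.array([p.t1 for p in phases])
    t_end = phases[-1].t1
    boundaries = np.array([p.t0 for p in phases] + [t_end])

    def _cadence(interval: float) -> np.ndarray:
        n = int(math.floor(t_end / interval + 1e-9)) + 1
        return np.arange(n) * interval

    state_t = np.unique(np.concatenate([_cadence(timing.state_interval_s), boundaries]))
    cum = np.empty_like(state_t)
    dr = np.empty_like(state_t)
    gan = np.empty_like(state_t)
    on = np.empty(state_t.size, dtype=bool)
    gantry_of = {b.index: b.gantry_deg for b in plan.beams}
    for i, ts in enumerate(state_t):
        ph = _phase_at(phase_ends, phases, ts, side="right")
        cum[i] = _cum_mu_at(ph, ts, rate)
        on[i] = ph.on
        dr[i] = timing.dose_rate_mu_min if on[i] else 0.0
        gan[i] = gantry_of[ph.beam]
    states = MachineStateStream(t=state_t, cum_mu=cum, dose_rate=dr, gantry_deg=gan, beam_on=on)

    report_t = np.unique(np.concatenate([_cadence(timing.aperture_interval_s), boundaries]))
    reports: list[ApertureReport] = []
    for k, tr in enumerate(report_t):
        ph = _phase_at(phase_ends, phases, tr)
        planned_ap = plan.beams[ph.beam].segments[ph.segment].aperture
        if mode == "tracked":
            d = delayed_view(trajectory, latency, float(tr), query_index=k)
            shift = project_to_bev(d, gantry_of[ph.beam])
            ap, clamped = track_aperture(planned_ap, shift)
            reports.append(
                ApertureReport(float(tr), ph.beam, ph.segment, ap, shift, clamped)
            )
        else:
            reports.append(
                ApertureReport(float(tr), ph.beam, ph.segment, planned_ap.copy())
            )

    return DeliveryRecord(
        mode=mode,
        reports=reports,
        states=states,
        timing=timing,
        plan=plan,
        trajectory=trajectory,
        latency=latency,
        seed=seed,
        meta={"t_end_s": t_end},
    )
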
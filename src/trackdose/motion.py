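"""Prostate motion: trajectory archetypes, tracker latency, offset and
rotation grids.

Displacements are (d_LR, d_AP, d_SI) in mm relative to the planning
position; times are seconds from delivery start.  Four trajectory
archetypes are emulated parametrically (drift velocity, transient
amplitude/rate, noise level): ``continuous_drift`` (posterior + inferior
baseline drift), ``erratic`` (that drift plus sudden anterior transients),
``high_frequency`` (slow anterior + superior drift with frequent short
transients) and ``stable`` (bounded small motion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "LatencyModel",
    "RotationSpec",
    "ARCHETYPES",
    "generate_trajectory",
    "delayed_view",
    "offset_grid",
    "rotation_grid",
    "displace_and_rotate",
    "nearest_index",
]

ARCHETYPES = ("continuous_drift", "erratic", "high_frequency", "stable")


def nearest_index(times: np.ndarray, t: float) -> int:
    """Index of the sample nearest in time; ties break toward the earlier one."""
    j = int(np.searchsorted(times, t))
    if j <= 0:
        return 0
    if j >= times.size:
        return times.size - 1
    # tie -> earlier sample
    return j - 1 if (t - times[j - 1]) <= (times[j] - t) else j


@dataclass
class Trajectory:
    """Uniformly sampled 3D target displacement (default 25 Hz)."""

    t: np.ndarray
    d: np.ndarray
    archetype: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.t.ndim != 1 or self.d.shape != (self.t.size, 3):
            raise ValueError("trajectory needs t (n,) and d (n, 3)")
        if self.t.size < 1:
            raise ValueError("trajectory must contain at least one sample")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.d)):
            raise ValueError("trajectory samples must be finite")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ValueError("trajectory sampling must be uniform")

    @property
    def rate_hz(self) -> float:
        if self.t.size < 2:
            return 0.0
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def nearest(self, t: float) -> np.ndarray:
        """Displacement of the sample nearest ``t`` (clamped at the ends)."""
        return self.d[nearest_index(self.t, t)]

    @classmethod
    def constant(cls, d: Sequence[float], duration_s: float, rate_hz: float = 25.0) -> "Trajectory":
        n = int(math.floor(duration_s * rate_hz)) + 1
        t = np.arange(n) / rate_hz
        return cls(t=t, d=np.tile(np.asarray(d, dtype=float), (n, 1)), archetype=None)


@dataclass(frozen=True)
class LatencyModel:
    """Gaussian localisation latency (ms), clipped at zero.

    One value is drawn per query, seeded by (seed, query index) so "online"
    runs are bit-reproducible.
    """

    mean_ms: float = 100.0
    sd_ms: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_ms < 0:
            raise ValueError("latency sd must be >= 0")

    def draw_ms(self, query_index: int) -> float:
        rng = np.random.default_rng([self.seed, int(query_index)])
        return float(max(0.0, rng.normal(self.mean_ms, self.sd_ms)))

    def draws_ms(self, n: int) -> np.ndarray:
        return np.array([self.draw_ms(i) for i in range(n)])


@dataclass(frozen=True)
class _ArchetypeParams:
    drift_mm_s: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd_mm: float = 0.15
    noise_corr_s: float = 2.0
    transient_rate_hz: float = 0.0
    transient_amp_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    transient_width_s: float = 2.0
    stable_amp_mm: float = 0.0


_PARAMS: dict[str, _ArchetypeParams] = {
    "continuous_drift": _ArchetypeParams(
        drift_mm_s=(0.0, -0.020, -0.013), noise_sd_mm=0.15
    ),
    "erratic": _ArchetypeParams(
        drift_mm_s=(0.0, -0.015, -0.010),
        noise_sd_mm=0.15,
        transient_rate_hz=1.0 / 45.0,
        transient_amp_mm=(0.0, 4.5, 1.0),
        transient_width_s=2.5,
    ),
    "high_frequency": _ArchetypeParams(
        drift_mm_s=(0.0, 0.010, 0.007),
        noise_sd_mm=0.2,
        transient_rate_hz=1.0 / 12.0,
        transient_amp_mm=(0.0, 2.5, 2.0),
        transient_width_s=0.8,
    ),
    "stable": _ArchetypeParams(noise_sd_mm=0.3, stable_amp_mm=1.0),
}


def _smooth_noise(rng: np.random.Generator, n: int, rate_hz: float, sd: float, corr_s: float) -> np.ndarray:
    """Temporally correlated zero-mean noise, (n, 3)."""
    white = rng.standard_normal((n, 3))
    half = max(1, int(round(corr_s * rate_hz)))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / (half / 2.0)) ** 2)
    k /= k.sum()
    sm = np.apply_along_axis(lambda c: np.convolve(c, k, mode="same"), 0, white)
    std = sm.std()
    if std > 0:
        sm *= sd / std
    return sm


def generate_trajectory(
    archetype: str,
    duration_s: float,
    rate_hz: float = 25.0,
    seed: int = 0,
    stable_amp_mm: float = 1.0,
) -> Trajectory:
    """Deterministic (per seed) parametric emulation of one motion archetype."""
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; options: {ARCHETYPES}")
    p = _PARAMS[archetype]
    rng = np.random.default_rng(seed)
    n = int(math.floor(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz

    noise = _smooth_noise(rng, n, rate_hz, p.noise_sd_mm, p.noise_corr_s)

    if archetype == "stable":
        # bounded by construction: rescale so max |component| <= amplitude
        amp = stable_amp_mm
        peak = np.abs(noise).max()
        if peak > amp and peak > 0:
            noise *= amp / peak
        return Trajectory(t=t, d=noise, archetype=archetype, seed=seed)

    d = t[:, None] * np.asarray(p.drift_mm_s) + noise

    if p.transient_rate_hz > 0:
        n_ev = rng.poisson(p.transient_rate_hz * duration_s)
        t_ev = np.sort(rng.uniform(0.0, duration_s, n_ev))
        scale = rng.uniform(0.5, 1.5, n_ev)
        amp = np.asarray(p.transient_amp_mm)
        for te, sc in zip(t_ev, scale):
            pulse = np.exp(-0.5 * ((t - te) / p.transient_width_s) ** 2)
            d += sc * pulse[:, None] * amp
    return Trajectory(t=t, d=d, archetype=archetype, seed=seed)


def delayed_view(
    traj: Trajectory,
    lat: LatencyModel,
    query_t: float,
    query_index: Optional[int] = None,
) -> np.ndarray:
    """Latency-delayed target position seen by the tracker at ``query_t``.

    Returns the sample nearest ``query_t - L`` where L is drawn once per
    query; queries before the first available delayed sample return zero
    displacement (the tracker starts at the planning position).
    """
    if query_index is None:
        query_index = int(round(query_t * 1000.0))
    latency_s = lat.draw_ms(query_index) / 1000.0
    tq = query_t - latency_s
    if tq < traj.t[0]:
        return np.zeros(3)
    return traj.nearest(tq)


def offset_grid(half_range_mm: float, step_mm: float) -> list[np.ndarray]:
    """Full Cartesian grid of constant interfractional offset vectors over
    the three patient axes: ((2*half_range/step)+1)^3 vectors."""
    if step_mm <= 0:
        raise ValueError("step must be positive")
    k = half_range_mm / step_mm
    if abs(k - round(k)) > 1e-9:
        raise ValueError("half_range must be a multiple of step")
    k = int(round(k))
    vals = np.arange(-k, k + 1) * step_mm
    return [
        np.array([lr, ap, si])
        for lr in vals
        for ap in vals
        for si in vals
    ]


@dataclass(frozen=True)
class RotationSpec:
    """Rigid target rotation: pitch about +LR then roll about +SI, both
    right-handed, about the target centre of volume (``pivot``)."""

    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    pivot: Optional[tuple[float, float, float]] = None

    def matrix(self) -> np.ndarray:
        p = math.radians(self.pitch_deg)
        r = math.radians(self.roll_deg)
        cp, sp = math.cos(p), math.sin(p)
        cr, sr = math.cos(r), math.sin(r)
        r_pitch = np.array([[1.0, 0.0, 0.0], [0.0, cp, -sp], [0.0, sp, cp]])
        r_roll = np.array([[cr, -sr, 0.0], [sr, cr, 0.0], [0.0, 0.0, 1.0]])
        return r_roll @ r_pitch  # pitch first, then roll


def rotation_grid(
    pitch: tuple[float, float, float],
    roll: tuple[float, float, float] = (0.0, 0.0, 1.0),
    pivot: Optional[tuple[float, float, float]] = None,
) -> list[RotationSpec]:
    """Cartesian product of pitch and roll values, each given as
    (min_deg, max_deg, step_deg) inclusive; a pitch-only grid uses
    roll = (0, 0, step)."""
    specs = []
    axes = []
    for rng_spec in (pitch, roll):
        lo, hi, step = rng_spec
        if step <= 0:
            raise ValueError("rotation step must be positive")
        if hi < lo:
            raise ValueError("rotation range is empty")
        n = int(math.floor((hi - lo) / step + 1e-9)) + 1
        axes.append(lo + step * np.arange(n))
    for p in axes[0]:
        for r in axes[1]:
            specs.append(RotationSpec(pitch_deg=float(p), roll_deg=float(r), pivot=pivot))
    return specs


def displace_and_rotate(
    points: np.ndarray, rot: Optional[RotationSpec], shift: np.ndarray
) -> np.ndarray:
    """R_roll . R_pitch . (p - pivot) + pivot + shift, vectorized over points.

    With ``shift = 0`` this preserves distances to the pivot.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    shift = np.asarray(shift, dtype=float)
    if rot is None or (rot.pitch_deg == 0.0 and rot.roll_deg == 0.0):
        out = pts + shift
    else:
        if rot.pivot is None:
            raise ValueError("rotation pivot must be defined")
        pivot = np.asarray(rot.pivot, dtype=float)
        out = (pts - pivot) @ rot.matrix().T + pivot + shift
    return out[0] if np.asarray(points).ndim == 1 else out
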
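"""Readers/writers: trajectory CSV, delivery-log CSVs, HDF5 containers and
the run configuration schema.

One CSV dialect everywhere: comma separator, ``.`` decimal, single header
row.  Floats are written with ``repr``-level precision so write -> read ->
write is byte-stable and numerically exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import yaml

from .delivery import ApertureReport, DeliveryRecord, MachineStateStream, TimingConfig
from .influence import DoseInfluenceMatrix
from .motion import LatencyModel, Trajectory
from .phantom import GridSpec, Phantom, VOI
from .plan import Aperture, Beam, BeamletGrid, Plan, Segment, SUPPORTED_U_RES

__all__ = [
    "CsvFormatError",
    "ConfigError",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_delivery_csvs",
    "read_delivery_csvs",
    "save_scene",
    "load_scene",
    "save_result",
    "load_result_summary",
    "RunConfig",
    "load_config",
]

PathLike = Union[str, Path]


class CsvFormatError(ValueError):
    """Malformed CSV row; message names the offending 1-based line."""


class ConfigError(ValueError):
    """Configuration schema violation; message names the offending key."""


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------- trajectory

TRAJ_HEADER = "t_s,d_lr_mm,d_ap_mm,d_si_mm"


def write_trajectory_csv(traj: Trajectory, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(TRAJ_HEADER + "\n")
        for t, d in zip(traj.t, traj.d):
            fh.write(f"{_fmt(t)},{_fmt(d[0])},{_fmt(d[1])},{_fmt(d[2])}\n")


def read_trajectory_csv(path: PathLike) -> Trajectory:
    """Parse a trajectory CSV, validating uniform sample spacing."""
    ts, ds = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != TRAJ_HEADER:
            raise CsvFormatError(f"line 1: expected header {TRAJ_HEADER!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise CsvFormatError(f"line {lineno}: expected 4 fields, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise CsvFormatError(f"line {lineno}: non-numeric field") from None
            ts.append(vals[0])
            ds.append(vals[1:])
    if not ts:
        raise CsvFormatError("line 2: trajectory file contains no samples")
    return Trajectory(t=np.array(ts), d=np.array(ds))


# ------------------------------------------------------------- delivery logs


def write_delivery_csvs(record: DeliveryRecord, aperture_path: PathLike, state_path: PathLike) -> None:
    """Write the aperture stream and machine-state stream as two CSVs."""
    st = record.states
    with open(state_path, "w") as fh:
        fh.write("t_s,cum_mu,dose_rate,gantry_deg,beam_on\n")
        for i in range(len(st)):
            fh.write(
                f"{_fmt(st.t[i])},{_fmt(st.cum_mu[i])},{_fmt(st.dose_rate[i])},"
                f"{_fmt(st.gantry_deg[i])},{int(st.beam_on[i])}\n"
            )
    n_rows = record.reports[0].aperture.n_rows
    cols = ["t_s", "beam", "segment", "applied_u_mm", "applied_v_mm", "v0_mm", "leaf_width_mm"]
    for r in range(n_rows):
        cols += [f"row{r}_left_mm", f"row{r}_right_mm"]
    cols += ["vmin_mm", "vmax_mm"]
    with open(aperture_path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for rpt in record.reports:
            ap = rpt.aperture
            if ap.n_rows != n_rows:
                raise ValueError("all apertures in one log must share a row count")
            vals = [
                _fmt(rpt.t),
                str(rpt.beam_index),
                str(rpt.segment_index),
                _fmt(rpt.applied_shift[0]),
                _fmt(rpt.applied_shift[1]),
                _fmt(ap.v0),
                _fmt(ap.leaf_width),
            ]
            for r in range(n_rows):
                vals += [_fmt(ap.rows[r, 0]), _fmt(ap.rows[r, 1])]
            vals += [_fmt(ap.y_jaws[0]), _fmt(ap.y_jaws[1])]
            fh.write(",".join(vals) + "\n")


def read_delivery_csvs(
    aperture_path: PathLike, state_path: PathLike, mode: str = "conventional",
    timing: Optional[TimingConfig] = None,
) -> tuple[list[ApertureReport], MachineStateStream]:
    """Parse delivery logs back into report objects and a state stream."""
    t, cum, dr, gan, on = [], [], [], [], []
    with open(state_path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "t_s,cum_mu,dose_rate,gantry_deg,beam_on":
            raise CsvFormatError("line 1: unexpected machine-state header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise CsvFormatError(f"line {lineno}: expected 5 fields, got {len(parts)}")
            try:
                t.append(float(parts[0]))
                cum.append(float(parts[1]))
                dr.append(float(parts[2]))
                gan.append(float(parts[3]))
                on.append(bool(int(parts[4])))
            except ValueError:
                raise CsvFormatError(f"line {lineno}: non-numeric field") from None
    states = MachineStateStream(
        t=np.array(t), cum_mu=np.array(cum), dose_rate=np.array(dr),
        gantry_deg=np.array(gan), beam_on=np.array(on),
    )

    reports: list[ApertureReport] = []
    with open(aperture_path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        row_cols = [c for c in header if c.startswith("row") and c.endswith("_left_mm")]
        n_rows = len(row_cols)
        expected = 7 + 2 * n_rows + 2
        if len(header) != expected or n_rows == 0:
            raise CsvFormatError("line 1: unexpected aperture-log header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != expected:
                raise CsvFormatError(
                    f"line {lineno}: expected {expected} fields, got {len(parts)}"
                )
            try:
                tr = float(parts[0])
                beam = int(parts[1])
                seg = int(parts[2])
                shift = (float(parts[3]), float(parts[4]))
                v0 = float(parts[5])
                lw = float(parts[6])
                rows = np.array(
                    [[float(parts[7 + 2 * r]), float(parts[8 + 2 * r])] for r in range(n_rows)]
                )
                jaws = (float(parts[-2]), float(parts[-1]))
            except ValueError:
                raise CsvFormatError(f"line {lineno}: non-numeric field") from None
            ap = Aperture(rows=rows, y_jaws=jaws, v0=v0, leaf_width=lw)
            reports.append(ApertureReport(tr, beam, seg, ap, shift))
    if not reports:
        raise CsvFormatError("line 2: aperture log contains no reports")
    return reports, states


# --------------------------------------------------------------- HDF5 scene


def save_scene(
    path: PathLike,
    phantom: Phantom,
    plan: Optional[Plan] = None,
    dijs: Optional[dict[int, DoseInfluenceMatrix]] = None,
) -> None:
    """Serialize phantom (+ optional plan and influence matrices) to HDF5.

    Layout: ``/grid`` attrs origin/spacing/dims/axial_crop; ``/density``;
    ``/vois/<name>``; ``/plan`` attrs isocenter/prescription/seed and per
    beam ``gantry_deg``, beamlet-grid attrs, ``mu``, ``jaws``, ``rows``;
    ``/dij/beam<i>`` holds CSC arrays data/indices/indptr/shape/region_idx.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        g.attrs["origin"] = phantom.grid.origin
        g.attrs["spacing"] = phantom.grid.spacing
        g.attrs["dims"] = phantom.grid.dims
        g.attrs["axial_crop"] = (
            phantom.grid.axial_crop if phantom.grid.axial_crop is not None else (-1, -1)
        )
        f.create_dataset("density", data=phantom.density, compression="gzip")
        vg = f.create_group("vois")
        for name, voi in phantom.vois.items():
            vg.create_dataset(name, data=voi.mask, compression="gzip")
        if plan is not None:
            pg = f.create_group("plan")
            pg.attrs["isocenter"] = np.asarray(plan.isocenter, dtype=float)
            pg.attrs["prescription_cgy"] = plan.prescription_cgy
            pg.attrs["seed"] = -1 if plan.seed is None else plan.seed
            pg.attrs["n_beams"] = len(plan.beams)
            for b in plan.beams:
                bg = pg.create_group(f"beam{b.index}")
                bg.attrs["gantry_deg"] = b.gantry_deg
                for key in ("u0", "v0", "n_u", "n_v", "u_res", "v_res"):
                    bg.attrs[key] = getattr(b.beamlet_grid, key)
                bg.create_dataset("mu", data=[s.planned_mu for s in b.segments])
                bg.create_dataset("jaws", data=[s.aperture.y_jaws for s in b.segments])
                bg.create_dataset(
                    "rows", data=np.stack([s.aperture.rows for s in b.segments])
                )
        if dijs is not None:
            dg = f.create_group("dij")
            for bi, dij in dijs.items():
                sg = dg.create_group(f"beam{bi}")
                sg.create_dataset("data", data=dij.matrix.data, compression="gzip")
                sg.create_dataset("indices", data=dij.matrix.indices, compression="gzip")
                sg.create_dataset("indptr", data=dij.matrix.indptr)
                sg.attrs["shape"] = dij.matrix.shape
                sg.create_dataset("region_idx", data=dij.region_idx, compression="gzip")


def load_scene(
    path: PathLike,
) -> tuple[Phantom, Optional[Plan], Optional[dict[int, DoseInfluenceMatrix]]]:
    from scipy import sparse

    with h5py.File(path, "r") as f:
        g = f["grid"]
        crop = tuple(int(v) for v in g.attrs["axial_crop"])
        grid = GridSpec(
            origin=tuple(float(v) for v in g.attrs["origin"]),
            spacing=tuple(float(v) for v in g.attrs["spacing"]),
            dims=tuple(int(v) for v in g.attrs["dims"]),
            axial_crop=None if crop == (-1, -1) else crop,
        )
        phantom = Phantom(grid=grid, density=f["density"][()])
        for name in f["vois"]:
            phantom.add_voi(VOI(name, f["vois"][name][()]))
        plan = None
        if "plan" in f:
            pg = f["plan"]
            beams = []
            for bi in range(int(pg.attrs["n_beams"])):
                bg = pg[f"beam{bi}"]
                bgrid = BeamletGrid(
                    u0=float(bg.attrs["u0"]), v0=float(bg.attrs["v0"]),
                    n_u=int(bg.attrs["n_u"]), n_v=int(bg.attrs["n_v"]),
                    u_res=float(bg.attrs["u_res"]),
                )
                mu = bg["mu"][()]
                jaws = bg["jaws"][()]
                rows = bg["rows"][()]
                segments = [
                    Segment(
                        Aperture(rows[si], (float(jaws[si][0]), float(jaws[si][1])), bgrid.v0),
                        float(mu[si]),
                    )
                    for si in range(len(mu))
                ]
                beams.append(
                    Beam(float(bg.attrs["gantry_deg"]), segments, bgrid, index=bi)
                )
            seed = int(pg.attrs["seed"])
            plan = Plan(
                beams=beams,
                isocenter=np.asarray(pg.attrs["isocenter"], dtype=float),
                prescription_cgy=float(pg.attrs["prescription_cgy"]),
                seed=None if seed == -1 else seed,
            )
        dijs = None
        if "dij" in f:
            dijs = {}
            for key in f["dij"]:
                sg = f["dij"][key]
                bi = int(key.removeprefix("beam"))
                mat = sparse.csc_matrix(
                    (sg["data"][()], sg["indices"][()], sg["indptr"][()]),
                    shape=tuple(sg.attrs["shape"]),
                )
                dijs[bi] = DoseInfluenceMatrix(
                    beam_index=bi, matrix=mat, region_idx=sg["region_idx"][()],
                    grid_dims=tuple(grid.dims),
                )
    return phantom, plan, dijs


def save_result(path: PathLike, result) -> None:
    """Serialize a ReconstructionResult (dose grids + provenance) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("static_dose", data=result.static_dose, compression="gzip")
        tg = f.create_group("target_dose")
        for name, vec in result.accumulator.target_dose.items():
            tg.create_dataset(name, data=vec, compression="gzip")
        vg = f.create_group("voi_doses")
        for name, vec in result.voi_doses.items():
            vg.create_dataset(name, data=vec, compression="gzip")
        f.attrs["mode"] = result.mode
        f.attrs["method"] = result.method
        f.attrs["mu_processed"] = result.mu_processed
        f.attrs["n_updates"] = result.n_updates
        f.attrs["out_of_region_warnings"] = result.accumulator.out_of_region_warnings
        f.attrs["provenance"] = json.dumps(result.provenance, default=str)


def load_result_summary(path: PathLike) -> dict:
    with h5py.File(path, "r") as f:
        out = {k: f.attrs[k] for k in f.attrs}
        out["static_dose"] = f["static_dose"][()]
        out["voi_doses"] = {name: f["voi_doses"][name][()] for name in f["voi_doses"]}
    return out


# -------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Validated run configuration for the CLI pipeline."""

    phantom_size: str = "default"        # "default" | "small"
    margin_mm: dict = field(default_factory=lambda: {"isotropic": 5.0})
    n_beams: int = 7
    segments_per_beam: int = 3
    total_mu: float = 700.0
    beamlet_u_res: float = 5.0
    mode: str = "tracked"
    method: str = "mlc_voi"
    trajectory: dict = field(default_factory=lambda: {"archetype": "continuous_drift"})
    latency: dict = field(default_factory=lambda: {"mean_ms": 100.0, "sd_ms": 15.0})
    dose_rate_mu_min: float = 600.0
    hold_s: float = 2.0
    seed: int = 0

    def latency_model(self) -> LatencyModel:
        return LatencyModel(
            mean_ms=float(self.latency.get("mean_ms", 100.0)),
            sd_ms=float(self.latency.get("sd_ms", 15.0)),
            seed=self.seed,
        )

    def timing(self) -> TimingConfig:
        return TimingConfig(dose_rate_mu_min=self.dose_rate_mu_min, hold_s=self.hold_s)


_ALLOWED_KEYS = {
    "phantom_size", "margin_mm", "n_beams", "segments_per_beam", "total_mu",
    "beamlet", "mode", "method", "trajectory", "latency",
    "dose_rate_mu_min", "hold_s", "seed",
}


def load_config(path: PathLike) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Violations raise :class:`ConfigError` naming the offending key, e.g.
    an unsupported beamlet resolution reports ``beamlet.u_res``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key in raw:
        if key not in _ALLOWED_KEYS:
            raise ConfigError(f"unknown config key: {key}")
    cfg = RunConfig()
    if "phantom_size" in raw:
        if raw["phantom_size"] not in ("default", "small"):
            raise ConfigError("phantom_size: must be 'default' or 'small'")
        cfg.phantom_size = raw["phantom_size"]
    if "beamlet" in raw:
        u_res = raw["beamlet"].get("u_res", 5.0)
        if float(u_res) not in SUPPORTED_U_RES:
            raise ConfigError(
                f"beamlet.u_res: {u_res} not in supported set {SUPPORTED_U_RES}"
            )
        cfg.beamlet_u_res = float(u_res)
    if "mode" in raw:
        if raw["mode"] not in ("static", "conventional", "tracked"):
            raise ConfigError("mode: must be static, conventional or tracked")
        cfg.mode = raw["mode"]
    if "method" in raw:
        if raw["method"] not in ("mlc_voi", "mlc_only"):
            raise ConfigError("method: must be mlc_voi or mlc_only")
        cfg.method = raw["method"]
    for key, typ in (
        ("n_beams", int), ("segments_per_beam", int), ("total_mu", float),
        ("dose_rate_mu_min", float), ("hold_s", float), ("seed", int),
    ):
        if key in raw:
            try:
                setattr(cfg, key, typ(raw[key]))
            except (TypeError, ValueError):
                raise ConfigError(f"{key}: expected {typ.__name__}") from None
    if cfg.n_beams < 1:
        raise ConfigError("n_beams: must be >= 1")
    if cfg.total_mu <= 0:
        raise ConfigError("total_mu: must be positive")
    if cfg.dose_rate_mu_min <= 0:
        raise ConfigError("dose_rate_mu_min: must be positive")
    if "margin_mm" in raw:
        if not isinstance(raw["margin_mm"], dict):
            raise ConfigError("margin_mm: must be a mapping")
        cfg.margin_mm = raw["margin_mm"]
    if "trajectory" in raw:
        if not isinstance(raw["trajectory"], dict):
            raise ConfigError("trajectory: must be a mapping")
        arche = raw["trajectory"].get("archetype")
        if arche is not None and arche not in (
            "continuous_drift", "erratic", "high_frequency", "stable",
        ):
            raise ConfigError(f"trajectory.archetype: unknown archetype {arche!r}")
        cfg.trajectory = raw["trajectory"]
    if "latency" in raw:
        if not isinstance(raw["latency"], dict):
            raise ConfigError("latency: must be a mapping")
        if float(raw["latency"].get("sd_ms", 0.0)) < 0:
            raise ConfigError("latency.sd_ms: must be >= 0")
        cfg.latency = raw["latency"]
    return cfg
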
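"""DVH construction and dosimetric metrics over non-exclusive VOIs.

VOIs may overlap; shared voxels are counted fully in every structure they
belong to.  Dx values use the exact empirical DVH (sorted per-voxel doses
with linear rank interpolation, no binning).  Doses are cGy throughout;
NTID is reported in litre*Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .phantom import GridSpec, VOI, Phantom

if TYPE_CHECKING:  # pragma: no cover
    from .recon import ReconstructionResult

__all__ = [
    "DVHCurve",
    "MetricsReport",
    "cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "v95_overlap",
    "ntid",
    "compute_metrics",
    "compare_to_static",
]


@dataclass
class DVHCurve:
    """Exact empirical cumulative DVH for one VOI."""

    voi_name: str
    doses_cgy: np.ndarray       # sorted ascending
    voxel_volume_cm3: float

    def __post_init__(self) -> None:
        self.doses_cgy = np.sort(np.asarray(self.doses_cgy, dtype=float))
        if self.doses_cgy.size == 0:
            raise ValueError("DVH over an empty VOI is undefined")

    @property
    def n_voxels(self) -> int:
        return self.doses_cgy.size

    @property
    def total_volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_cm3

    def dose_at_volume(self, x_percent: float) -> float:
        return dose_at_volume(self, x_percent)

    def volume_at_dose(self, threshold_cgy: float) -> float:
        return volume_at_dose(self, threshold_cgy)

    def curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(dose_cgy, volume_fraction receiving >= dose); starts at (0, 1)."""
        d = np.concatenate([[0.0], self.doses_cgy])
        frac = 1.0 - np.arange(d.size) / self.n_voxels
        frac[0] = 1.0
        return d, frac


def cumulative_dvh(dose: np.ndarray, voi: VOI, grid: GridSpec) -> DVHCurve:
    """DVH from a dense dose grid (cGy) restricted to one VOI.

    Accepts either the full 3D dose grid or a per-VOI dose vector of
    matching length.  Raises on an empty VOI.
    """
    dose = np.asarray(dose, dtype=float)
    if voi.n_voxels == 0:
        raise ValueError(f"VOI {voi.name!r} is empty")
    if dose.shape == tuple(grid.dims):
        vec = dose[voi.mask]
    elif dose.ndim == 1 and dose.size == voi.n_voxels:
        vec = dose
    else:
        raise ValueError("dose must be the full grid or a per-VOI vector")
    return DVHCurve(voi.name, vec, grid.voxel_volume_cm3)


def dose_at_volume(dvh: DVHCurve, x_percent: float) -> float:
    """Dx: minimum dose received by the hottest x% of the volume, with
    linear interpolation between sorted voxel ranks."""
    if not (0.0 < x_percent <= 100.0):
        raise ValueError("x must be in (0, 100]")
    return float(np.quantile(dvh.doses_cgy, 1.0 - x_percent / 100.0, method="linear"))


def volume_at_dose(dvh: DVHCurve, threshold_cgy: float) -> float:
    """Volume (cm^3) receiving at least the threshold dose."""
    return float((dvh.doses_cgy >= threshold_cgy).sum()) * dvh.voxel_volume_cm3


def v95_overlap(
    dose: np.ndarray, oar: VOI, prescription_cgy: float, grid: GridSpec
) -> float:
    """Volume (cm^3) of OAR voxels receiving >= 95% of the prescription
    (a proxy for the target-to-OAR distance)."""
    if prescription_cgy <= 0:
        raise ValueError("prescription must be positive")
    dvh = cumulative_dvh(dose, oar, grid)
    return volume_at_dose(dvh, 0.95 * prescription_cgy)


def ntid(
    dose: np.ndarray,
    non_tumour: VOI,
    grid: GridSpec,
    density_g_cm3: float = 1.0,
) -> float:
    """Non-tumour integral dose, litre*Gy:

        I = rho * (V / N) * sum_i D_i

    with the organ volume V in litres and voxel doses D_i in Gy.  The
    non-tumour organ is conventionally body minus CTV.
    """
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    if non_tumour.n_voxels == 0:
        raise ValueError("non-tumour VOI is empty")
    dose = np.asarray(dose, dtype=float)
    if dose.shape == tuple(grid.dims):
        vec = dose[non_tumour.mask]
    else:
        vec = dose
        if vec.size != non_tumour.n_voxels:
            raise ValueError("dose vector does not match the VOI")
    v_litre = non_tumour.volume_cm3(grid) / 1000.0
    return density_g_cm3 * (v_litre / non_tumour.n_voxels) * float(np.sum(vec / 100.0))


#: default Dx points of interest per VOI
DEFAULT_DX = {"CTV": (98,), "PTV": (95,), "rectum": (2,), "bladder": (2,)}


@dataclass
class MetricsReport:
    """Named dosimetric metrics for one reconstruction (doses in cGy,
    volumes in cm^3, NTID in litre*Gy)."""

    values: dict[str, float]
    prescription_cgy: float = 725.0
    reference: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def delta(self, other: "MetricsReport") -> dict[str, float]:
        keys = set(self.values) & set(other.values)
        return {k: self.values[k] - other.values[k] for k in sorted(keys)}


def compute_metrics(
    result: "ReconstructionResult",
    phantom: Phantom,
    prescription_cgy: float = 725.0,
    dx_points: Optional[dict[str, tuple[int, ...]]] = None,
) -> MetricsReport:
    """Dx points, V95 overlaps and NTID for one reconstruction result.

    Moving-VOI doses come from the target-tracked vectors; OAR and body
    doses from the static-anatomy grid.
    """
    dx_points = dx_points or DEFAULT_DX
    grid = phantom.grid
    values: dict[str, float] = {}
    for name, points in dx_points.items():
        if name not in phantom.vois or name not in result.voi_doses:
            continue
        dvh = cumulative_dvh(result.voi_doses[name], phantom.voi(name), grid)
        for x in points:
            values[f"{name}_D{x}"] = dose_at_volume(dvh, x)
    static = result.static_dose
    for oar in ("rectum", "bladder"):
        if oar in phantom.vois:
            values[f"{oar}_V95_cm3"] = v95_overlap(
                static, phantom.voi(oar), prescription_cgy, grid
            )
    if "body" in phantom.vois and "CTV" in phantom.vois:
        nt = VOI("non_tumour", phantom.voi("body").mask & ~phantom.voi("CTV").mask)
        values["NTID_litre_gy"] = ntid(static, nt, grid)
    return MetricsReport(values=values, prescription_cgy=prescription_cgy)


def compare_to_static(
    result: "ReconstructionResult",
    static_ref: "ReconstructionResult",
    phantom: Phantom,
    prescription_cgy: float = 725.0,
    dx_points: Optional[dict[str, tuple[int, ...]]] = None,
) -> MetricsReport:
    """Metric deltas relative to a static reference reconstruction:
    delta(m) = m(result) - m(static_ref); antisymmetric under swap.
    Raises on mismatched geometry."""
    if result.static_dose.shape != static_ref.static_dose.shape or result.static_dose.shape != tuple(
        phantom.grid.dims
    ):
        raise ValueError("result and reference geometry mismatch")
    m = compute_metrics(result, phantom, prescription_cgy, dx_points)
    s = compute_metrics(static_ref, phantom, prescription_cgy, dx_points)
    return MetricsReport(
        values=m.delta(s),
        prescription_cgy=prescription_cgy,
        reference=static_ref.mode,
        meta={"kind": "delta_vs_static"},
    )
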
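"""Shared fixtures: a compact phantom/plan/influence scene built once per
session so individual tests stay fast."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import trackdose as td
from trackdose.delivery import TimingConfig, simulate_delivery
from trackdose.influence import compute_dose_influence
from trackdose.recon import reconstruct


@dataclass
class Scene:
    phantom: td.Phantom
    plan: td.Plan
    dijs: dict
    timing: TimingConfig


@pytest.fixture(scope="session")
def small_scene() -> Scene:
    phantom = td.build_phantom(td.PhantomConfig.small())
    ptv = td.expand_margin(
        phantom.voi("CTV"), td.Margins.isotropic(5.0), phantom.grid, name="PTV"
    )
    phantom.add_voi(ptv)
    plan = td.generate_plan(
        phantom, n_beams=3, segments_per_beam=2, total_mu=325.0, seed=1
    )
    dijs = {
        b.index: compute_dose_influence(phantom, b, plan.isocenter)
        for b in plan.beams
    }
    timing = TimingConfig(dose_rate_mu_min=600.0, hold_s=2.0)
    return Scene(phantom=phantom, plan=plan, dijs=dijs, timing=timing)


@pytest.fixture(scope="session")
def static_record(small_scene: Scene):
    return simulate_delivery(
        small_scene.plan, "static", timing=small_scene.timing, seed=0
    )


@pytest.fixture(scope="session")
def static_result(small_scene: Scene, static_record):
    return reconstruct(
        static_record, small_scene.phantom, small_scene.plan, small_scene.dijs
    )


@pytest.fixture(scope="session")
def drift_trajectory(static_record):
    """Constant 5 mm posterior displacement covering the delivery."""
    return td.Trajectory.constant(
        (0.0, -5.0, 0.0), static_record.duration_s + 1.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
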
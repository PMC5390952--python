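"""Reconstruction loop: state association, weights, increments, accumulation,
method equivalences and sweeps."""

import numpy as np
import pytest

import trackdose as td
from trackdose.delivery import ApertureReport, MachineStateStream, simulate_delivery
from trackdose.motion import RotationSpec, Trajectory, nearest_index
from trackdose.plan import Aperture, BeamletGrid
from trackdose.recon import (
    DoseAccumulator,
    aperture_dose_increment,
    associate_machine_state,
    beamlet_weights,
    nearest_target_sample,
    reconstruct,
    sweep_offsets,
    sweep_rotations,
    trilinear_sample,
)


def _states(t, mu):
    t = np.asarray(t, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return MachineStateStream(
        t=t,
        cum_mu=mu,
        dose_rate=np.zeros_like(t),
        gantry_deg=np.zeros_like(t),
        beam_on=np.ones(t.size, dtype=bool),
    )


def _report(t):
    ap = Aperture(rows=np.array([[-5.0, 5.0]]), y_jaws=(0.0, 5.0), v0=0.0)
    return ApertureReport(t, 0, 0, ap)


class TestAssociateMachineState:
    def test_exact_time_match(self):
        st = _states([0.0, 0.02, 0.04], [0.0, 1.0, 2.0])
        d = associate_machine_state(_report(0.02), st)
        assert d.state_index == 1
        assert d.incremental_mu == 1.0

    def test_tie_breaks_earlier(self):
        st = _states([0.0, 0.02], [0.0, 1.0])
        d = associate_machine_state(_report(0.01), st)
        assert d.state_index == 0

    def test_beam_off_zero_increment(self):
        st = _states([0.0, 0.02, 0.04], [3.0, 3.0, 3.0])
        d1 = associate_machine_state(_report(0.0), st, prev_cum_mu=3.0)
        d2 = associate_machine_state(_report(0.04), st, prev_cum_mu=3.0)
        assert d1.incremental_mu == 0.0 and d2.incremental_mu == 0.0

    def test_decreasing_mu_rejected(self):
        st = _states([0.0, 0.02], [5.0, 5.0])
        with pytest.raises(ValueError, match="corrupted"):
            associate_machine_state(_report(0.0), st, prev_cum_mu=9.0)

    def test_telescoping_sum(self):
        """40 ms reports against 20 ms states with a linear MU ramp."""
        t = np.arange(0, 1.0001, 0.02)
        st = _states(t, 10.0 * t)
        prev = 0.0
        total = 0.0
        for rt in np.arange(0, 1.0001, 0.04):
            d = associate_machine_state(_report(rt), st, prev_cum_mu=prev)
            total += d.incremental_mu
            prev += d.incremental_mu
        assert total == pytest.approx(st.cum_mu[-1], rel=1e-12)


class TestNearestTargetSample:
    def test_exact_and_tie(self):
        tr = Trajectory(t=np.arange(4) * 0.04, d=np.arange(12.0).reshape(4, 3))
        assert np.array_equal(nearest_target_sample(0.08, tr), tr.d[2])
        assert np.array_equal(nearest_target_sample(0.06, tr), tr.d[1])  # tie -> earlier

    def test_brute_force_oracle(self, rng):
        t = np.arange(100) * 0.04
        tr = Trajectory(t=t, d=rng.normal(size=(100, 3)))
        for q in rng.uniform(-0.5, 4.5, size=1000):
            got = nearest_index(tr.t, q)
            dist = np.abs(tr.t - q)
            best = np.flatnonzero(dist == dist.min())[0]  # earliest minimizer
            assert got == best


class TestBeamletWeights:
    def test_fully_open_and_closed(self):
        g = BeamletGrid(u0=-10.0, v0=0.0, n_u=4, n_v=2, u_res=5.0)
        ap = Aperture(
            rows=np.array([[-10.0, 10.0], [0.0, 0.0]]), y_jaws=(0.0, 10.0), v0=0.0
        )
        w = beamlet_weights(ap, g).reshape(2, 4)
        assert np.all(w[0] == 1.0)
        assert np.all(w[1] == 0.0)

    def test_half_covered_is_half_exactly(self):
        g = BeamletGrid(u0=-10.0, v0=0.0, n_u=4, n_v=1, u_res=5.0)
        # leaf tip bisects the beamlet covering u in [-5, 0]
        ap = Aperture(rows=np.array([[-2.5, 20.0]]), y_jaws=(0.0, 5.0), v0=0.0)
        w = beamlet_weights(ap, g)
        assert w[1] == 0.5

    def test_jaw_partial_coverage(self):
        g = BeamletGrid(u0=0.0, v0=0.0, n_u=1, n_v=2, u_res=5.0)
        ap = Aperture(
            rows=np.array([[0.0, 5.0], [0.0, 5.0]]), y_jaws=(0.0, 7.5), v0=0.0
        )
        w = beamlet_weights(ap, g)
        assert w[0] == 1.0 and w[1] == 0.5

    def test_misaligned_grid_rejected(self):
        g = BeamletGrid(u0=0.0, v0=0.0, n_u=1, n_v=2, u_res=5.0)
        ap = Aperture(rows=np.array([[0.0, 5.0]]), y_jaws=(0.0, 5.0), v0=0.0)
        with pytest.raises(ValueError):
            beamlet_weights(ap, g)


class TestApertureDoseIncrement:
    def test_zero_mu_zero_increment(self, small_scene):
        dij = small_scene.dijs[0]
        w = np.ones(dij.n_beamlets)
        inc = aperture_dose_increment(w, dij, 0.0)
        assert inc.shape == (dij.region_idx.size,)
        assert not inc.any()

    def test_single_beamlet_equals_column(self, small_scene):
        dij = small_scene.dijs[0]
        j = dij.n_beamlets // 2
        w = np.zeros(dij.n_beamlets)
        w[j] = 1.0
        inc = aperture_dose_increment(w, dij, 1.0)
        expected = np.zeros_like(inc)
        col = dij.matrix.getcol(j)
        expected[col.indices] = col.data
        assert np.array_equal(inc, expected)

    def test_dense_matvec_oracle(self, small_scene, rng):
        dij = small_scene.dijs[1]
        w = rng.uniform(0.0, 1.0, dij.n_beamlets)
        inc = aperture_dose_increment(w, dij, 2.5)
        dense = dij.matrix.toarray()
        oracle = 2.5 * (dense @ w)
        assert np.allclose(inc, oracle, atol=1e-10)


class TestTrilinearSample:
    def test_exact_at_integer_indices(self, rng):
        vol = rng.uniform(size=(6, 7, 8))
        idx = np.array([[2.0, 3.0, 4.0], [0.0, 0.0, 0.0], [5.0, 6.0, 7.0]])
        got = trilinear_sample(vol, idx)
        assert np.array_equal(got, vol[[2, 0, 5], [3, 0, 6], [4, 0, 7]])

    def test_midpoint_average(self):
        vol = np.zeros((2, 1, 1))
        vol[1] = 4.0
        got = trilinear_sample(vol, np.array([[0.5, 0.0, 0.0]]))
        assert got[0] == pytest.approx(2.0)

    def test_outside_contributes_zero(self, rng):
        vol = rng.uniform(size=(4, 4, 4))
        got = trilinear_sample(vol, np.array([[-5.0, 0.0, 0.0], [10.0, 2.0, 2.0]]))
        assert np.array_equal(got, [0.0, 0.0])


class TestAccumulateMapping:
    """Target-dose mapping contracts exercised through reconstruct."""

    def test_zero_displacement_target_equals_static(self, small_scene, static_result):
        ph = small_scene.phantom
        static = static_result.static_dose
        for name in ("CTV", "PTV"):
            assert np.array_equal(
                static_result.voi_doses[name], static[ph.voi(name).mask]
            )

    def test_integer_voxel_shift_identity(self, small_scene, static_record):
        """Constant displacement of one voxel pitch samples the static dose
        exactly one voxel away."""
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        shift = Trajectory.constant((0.0, 0.0, 5.0), static_record.duration_s + 1)
        res = reconstruct(static_record, ph, plan, dijs, trajectory=shift)
        static = reconstruct(static_record, ph, plan, dijs).static_dose
        mask = ph.voi("CTV").mask
        shifted = np.zeros_like(static)
        shifted[:, :, :-1] = static[:, :, 1:]  # sample at z + 1 voxel
        assert np.array_equal(res.voi_doses["CTV"], shifted[mask])

    def test_out_of_region_displacement_warns(self, small_scene, static_record):
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        far = Trajectory.constant((500.0, 0.0, 0.0), static_record.duration_s + 1)
        res = reconstruct(static_record, ph, plan, dijs, trajectory=far)
        assert res.accumulator.out_of_region_warnings > 0
        assert np.all(res.voi_doses["CTV"] == 0.0)

    def test_rotation_symmetry_of_radial_dose(self, small_scene, static_record):
        """A rotation of a spherical target inside a radially symmetric dose
        leaves the target DVH unchanged to interpolation tolerance."""
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        # radially symmetric synthetic dose about the isocenter
        pts = ph.grid.centers() - plan.isocenter
        radial = np.exp(-((np.linalg.norm(pts, axis=1) / 40.0) ** 2)).reshape(ph.grid.dims)

        from trackdose.recon import _TargetMapper

        region = td.influence.default_region_mask(ph)
        base = _TargetMapper(ph, region, ["CTV"], None, None, np.asarray(plan.isocenter))
        rot = _TargetMapper(
            ph, region, ["CTV"],
            RotationSpec(16.0, -8.0, tuple(plan.isocenter)), None,
            np.asarray(plan.isocenter),
        )
        v0, _ = base.sample(radial, "CTV", np.zeros(3))
        v1, _ = rot.sample(radial, "CTV", np.zeros(3))
        d98_0 = np.quantile(v0, 0.02)
        d98_1 = np.quantile(v1, 0.02)
        assert d98_1 == pytest.approx(d98_0, rel=0.02)


class TestReconstruct:
    def test_method_validation(self, small_scene, static_record):
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        with pytest.raises(ValueError, match="unknown method"):
            reconstruct(static_record, ph, plan, dijs, method="magic")
        with pytest.raises(ValueError, match="mlc_only"):
            reconstruct(static_record, ph, plan, dijs, method="mlc_only")

    def test_missing_dij_raises(self, small_scene, static_record):
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        partial = {0: dijs[0]}
        with pytest.raises(KeyError, match="missing dose influence"):
            reconstruct(static_record, ph, plan, partial)

    def test_out_of_order_reports_rejected(self, small_scene, static_record):
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        import copy

        rec = copy.copy(static_record)
        rec.reports = [static_record.reports[1], static_record.reports[0]]
        with pytest.raises(ValueError, match="out of time order"):
            reconstruct(rec, ph, plan, dijs)

    def test_conventional_zero_trajectory_equals_static_bitwise(
        self, small_scene, static_record, static_result
    ):
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        zero = Trajectory.constant((0.0, 0.0, 0.0), static_record.duration_s + 1)
        rec = simulate_delivery(plan, "conventional", zero, None, small_scene.timing, seed=0)
        res = reconstruct(rec, ph, plan, dijs, trajectory=zero)
        assert np.array_equal(
            res.accumulator.static_region, static_result.accumulator.static_region
        )
        for name in res.voi_doses:
            assert np.array_equal(res.voi_doses[name], static_result.voi_doses[name])

    def test_mu_conservation_all_modes(self, small_scene, static_record, drift_trajectory):
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        conv = simulate_delivery(
            plan, "conventional", drift_trajectory, None, small_scene.timing, seed=0
        )
        trk = simulate_delivery(
            plan, "tracked", drift_trajectory, td.LatencyModel(seed=0),
            small_scene.timing, seed=0,
        )
        runs = [
            reconstruct(static_record, ph, plan, dijs),
            reconstruct(conv, ph, plan, dijs, trajectory=drift_trajectory),
            reconstruct(conv, ph, plan, dijs, trajectory=drift_trajectory, method="mlc_only"),
            reconstruct(trk, ph, plan, dijs, trajectory=drift_trajectory),
            reconstruct(trk, ph, plan, dijs, trajectory=drift_trajectory, method="mlc_only"),
        ]
        for res in runs:
            assert res.mu_processed == pytest.approx(plan.total_mu, rel=1e-9)

    def test_mlc_only_tracked_target_close_to_voi(self, small_scene, drift_trajectory):
        """Both methods agree on the target; OAR doses differ under drift."""
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        trk = simulate_delivery(
            plan, "tracked", drift_trajectory, td.LatencyModel(seed=0),
            small_scene.timing, seed=0,
        )
        voi = reconstruct(trk, ph, plan, dijs, trajectory=drift_trajectory)
        only = reconstruct(trk, ph, plan, dijs, trajectory=drift_trajectory, method="mlc_only")
        d98v = np.quantile(voi.voi_doses["CTV"], 0.02)
        d98o = np.quantile(only.voi_doses["CTV"], 0.02)
        assert d98o == pytest.approx(d98v, rel=0.02)
        # posterior drift: MLC+VOI sees higher rectum dose than MLC-only
        rect = ph.voi("rectum").mask
        assert np.quantile(voi.static_dose[rect], 0.98) > np.quantile(
            only.static_dose[rect], 0.98
        )


@pytest.fixture(scope="module")
def sweep_setup(small_scene):
    ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
    traj = Trajectory.constant((0.0, -2.0, 0.0), 120.0)
    conv = simulate_delivery(plan, "conventional", traj, None, small_scene.timing, seed=0)
    stat = simulate_delivery(plan, "static", timing=small_scene.timing, seed=0)
    return ph, plan, dijs, traj, conv, stat


class TestSweeps:
    def test_offset_sweep_rows_and_zero_offset(self, sweep_setup, small_scene):
        ph, plan, dijs, traj, conv, stat = sweep_setup
        offsets = td.offset_grid(1.0, 1.0)  # 27 vectors, keeps the test fast
        df = sweep_offsets(conv, stat, ph, plan, dijs, offsets, trajectory=traj)
        assert len(df) == 27
        base = reconstruct(conv, ph, plan, dijs, trajectory=traj)
        from trackdose.analysis import compute_metrics

        base_met = compute_metrics(base, ph, plan.prescription_cgy)
        zero_row = df[
            (df.offset_lr_mm == 0) & (df.offset_ap_mm == 0) & (df.offset_si_mm == 0)
        ].iloc[0]
        assert zero_row["CTV_D98"] == pytest.approx(base_met.values["CTV_D98"], rel=1e-12)

    def test_offset_cancels_constant_trajectory(self, sweep_setup):
        """An offset exactly opposing the constant drift recovers static CTV."""
        ph, plan, dijs, traj, conv, stat = sweep_setup
        df = sweep_offsets(
            conv, stat, ph, plan, dijs, [np.array([0.0, 2.0, 0.0])], trajectory=traj
        )
        static_res = reconstruct(stat, ph, plan, dijs)
        from trackdose.analysis import compute_metrics

        sm = compute_metrics(static_res, ph, plan.prescription_cgy)
        assert df.iloc[0]["CTV_D98"] == pytest.approx(sm.values["CTV_D98"], rel=5e-3)

    def test_monotone_degradation_with_posterior_offset(self, sweep_setup):
        """CTV D98 is non-increasing as a posterior offset grows beyond the
        margin (conventional mode, conformal plan)."""
        ph, plan, dijs, traj, conv, stat = sweep_setup
        offsets = [np.array([0.0, -a, 0.0]) for a in (0.0, 2.0, 4.0, 6.0, 8.0)]
        df = sweep_offsets(conv, stat, ph, plan, dijs, offsets, trajectory=traj)
        d98 = df["CTV_D98"].to_numpy()
        assert np.all(np.diff(d98) <= 0.1)  # small slack for interpolation wiggle

    def test_rotation_sweep_rows_and_identity(self, small_scene, drift_trajectory):
        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        trk = simulate_delivery(
            plan, "tracked", drift_trajectory, td.LatencyModel(seed=0),
            small_scene.timing, seed=0,
        )
        rotations = td.rotation_grid((-8.0, 8.0, 8.0), (-8.0, 8.0, 8.0))
        df = sweep_rotations(trk, ph, plan, dijs, rotations, trajectory=drift_trajectory)
        assert len(df) == 9
        base = reconstruct(trk, ph, plan, dijs, trajectory=drift_trajectory)
        from trackdose.analysis import compute_metrics

        bm = compute_metrics(base, ph, plan.prescription_cgy)
        zero = df[(df.pitch_deg == 0) & (df.roll_deg == 0)].iloc[0]
        assert zero["CTV_D98"] == pytest.approx(bm.values["CTV_D98"], rel=1e-12)

    def test_sweep_mode_validation(self, sweep_setup):
        ph, plan, dijs, traj, conv, stat = sweep_setup
        with pytest.raises(ValueError):
            sweep_offsets(stat, stat, ph, plan, dijs, [np.zeros(3)])
        with pytest.raises(ValueError):
            sweep_rotations(conv, ph, plan, dijs, [RotationSpec()])


class TestUpdateCostScaling:
    def test_per_aperture_cost_independent_of_history(self, small_scene):
        """Incremental accumulation: total time grows ~linearly in the number
        of reports (no per-report dependence on processed history)."""
        import time

        ph, plan, dijs = small_scene.phantom, small_scene.plan, small_scene.dijs
        from trackdose.delivery import TimingConfig

        def run(rate):
            timing = TimingConfig(dose_rate_mu_min=rate, hold_s=0.5)
            rec = simulate_delivery(plan, "static", timing=timing, seed=0)
            t0 = time.perf_counter()
            reconstruct(rec, ph, plan, dijs, moving_vois=())
            return len(rec.reports), time.perf_counter() - t0

        n1, t1 = run(2400.0)
        n2, t2 = run(600.0)   # ~4x the reports
        assert n2 > 2.5 * n1
        per1 = t1 / n1
        per2 = t2 / n2
        # O(1) per update: per-report cost must not grow with history length
        assert per2 < 5.0 * per1
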
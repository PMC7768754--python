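"""Wedge assignment, Eq.-style weighted predictor, smoothing, calibration, RMSE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcnflow import (
    Canaliculus,
    FlowSolution,
    LCNNetwork,
    Node,
    PredictorConfig,
    StrainRateField,
    SurfaceProfile,
    assign_wedges,
    calibrate,
    circular_geometry,
    flow_predictor,
    r_sensitivity,
    rmse,
    strain_predictor,
    triangular_smooth,
)
from lcnflow.errors import ValidationError


def solution_with_speeds(speeds):
    m = len(speeds)
    return FlowSolution(
        node_pressure=np.empty(0),
        edge_pressure_drop=np.zeros(m),
        edge_flow_rate=np.zeros(m),
        edge_velocity=np.asarray(speeds, dtype=float),
        boundary_rows=np.empty(0, dtype=int),
        boundary_outflux=np.empty(0),
    )


class TestAssignWedges:
    geometry = circular_geometry(70.0, 100.0)

    def _net_with_midpoint_angles(self, angles_deg, radius=85.0):
        nodes, edges = [], []
        for i, a in enumerate(np.radians(angles_deg)):
            c = radius * np.array([np.cos(a), np.sin(a)])
            d = np.array([-np.sin(a), np.cos(a)])  # tangential canaliculus
            nodes.append(Node(2 * i, (*(c - d), 0.0)))
            nodes.append(Node(2 * i + 1, (*(c + d), 0.0)))
            edges.append(Canaliculus(i, 2 * i, 2 * i + 1, 2.0))
        return LCNNetwork.from_components(nodes, edges)

    def test_midpoint_angle_to_half_open_wedge(self):
        net = self._net_with_midpoint_angles([1.0, 2.0, 359.9])
        asg = assign_wedges(net, self.geometry)
        # wedge w covers [2w, 2w+2): 1.0° → 0; exactly 2.0° → 1; 359.9° → 179
        assert asg.wedge.tolist() == [0, 1, 179]

    def test_every_canaliculus_in_exactly_one_wedge(self, small_experiment):
        asg = small_experiment.assignment
        net = small_experiment.network
        assert len(asg.wedge) == net.n_edges
        counts = np.bincount(asg.wedge, minlength=asg.wedge_count)
        assert counts.sum() == net.n_edges
        assert asg.wedge.min() >= 0 and asg.wedge.max() < asg.wedge_count

    def test_distances_to_both_surfaces(self):
        net = self._net_with_midpoint_angles([45.0], radius=80.0)
        asg = assign_wedges(net, self.geometry)
        # circular boundaries: distances are radial (within polygonization error)
        assert asg.r_endocortical[0] == pytest.approx(10.0, abs=0.05)
        assert asg.r_periosteal[0] == pytest.approx(20.0, abs=0.05)


class TestFlowPredictor:
    geometry = circular_geometry(70.0, 100.0, wedge_count=180)

    def _assignment(self, vlr):
        """Synthetic one-wedge assignment from (v, l, r) triples."""
        from lcnflow.predictor import WedgeAssignment

        v, l, r = map(np.asarray, zip(*vlr))
        return (
            solution_with_speeds(v),
            WedgeAssignment(
                wedge=np.zeros(len(v), dtype=int),
                lengths=l.astype(float),
                r_endocortical=r.astype(float),
                r_periosteal=r.astype(float),
                wedge_count=180,
            ),
        )

    def test_single_canaliculus_at_surface(self):
        sol, asg = self._assignment([(3.3, 7.0, 0.0)])
        prof = flow_predictor(sol, asg, PredictorConfig(), "endocortical")
        assert prof.values[0] == pytest.approx(3.3)

    def test_constant_speed_wedge_returns_constant(self):
        sol, asg = self._assignment([(2.5, 1.0, 0.0), (2.5, 9.0, 12.0), (2.5, 4.0, 40.0)])
        prof = flow_predictor(sol, asg, PredictorConfig(), "endocortical")
        assert prof.values[0] == pytest.approx(2.5, rel=1e-12)

    def test_hand_evaluated_three_canaliculus_wedge(self):
        """Direct evaluation of the weighted mean for (v,l,r) triples, R=15."""
        triples = [(2.0, 10.0, 0.0), (4.0, 5.0, 15.0), (6.0, 20.0, 30.0)]
        sol, asg = self._assignment(triples)
        prof = flow_predictor(sol, asg, PredictorConfig(decay_length=15.0),
                              "periosteal")
        w = [np.exp(-r / 15.0) for _, _, r in triples]
        num = sum(v * l * wi for (v, l, _), wi in zip(triples, w))
        den = sum(l * wi for (_, l, _), wi in zip(triples, w))
        assert prof.values[0] == pytest.approx(num / den, abs=1e-12)
        assert not prof.values[1:].any()  # empty wedges are 0

    def test_weights_bound_predictor_between_extreme_speeds(self):
        rng = np.random.default_rng(10)
        vlr = [
            (float(rng.uniform(1, 9)), float(rng.uniform(1, 20)),
             float(rng.uniform(0, 50)))
            for _ in range(12)
        ]
        sol, asg = self._assignment(vlr)
        prof = flow_predictor(sol, asg, PredictorConfig(), "endocortical")
        speeds = [v for v, _, _ in vlr]
        assert min(speeds) <= prof.values[0] <= max(speeds)


class TestStrainPredictor:
    geometry = circular_geometry(70.0, 100.0)

    def test_constant_field_gives_constant_profile(self):
        field = StrainRateField(lambda p: np.full(len(p), -2e-3), "imported")
        prof = strain_predictor(field, self.geometry, PredictorConfig(), "periosteal")
        np.testing.assert_allclose(prof.values, 2e-3, rtol=1e-12)

    def test_zero_field_gives_zeros(self):
        field = StrainRateField(lambda p: np.zeros(len(p)), "imported")
        prof = strain_predictor(field, self.geometry, PredictorConfig(), "endocortical")
        assert not prof.values.any()

    def test_linear_field_matches_fine_grid_quadrature(self):
        field = StrainRateField(lambda p: 1e-5 * p[:, 1], "imported")
        cfg = PredictorConfig(sampling_step=2.0)
        fine = PredictorConfig(sampling_step=0.2)
        # smooth over the 30° window first: single 2° wedges hold only a
        # handful of 2-µm samples, the smoothed profile is the quantity used
        prof = triangular_smooth(
            strain_predictor(field, self.geometry, cfg, "endocortical"), 30.0
        )
        ref = triangular_smooth(
            strain_predictor(field, self.geometry, fine, "endocortical"), 30.0
        )
        big = ref.values > 0.25 * ref.values.max()
        np.testing.assert_allclose(prof.values[big], ref.values[big], rtol=0.02)


class TestTriangularSmooth:
    def test_constant_profile_unchanged(self):
        prof = SurfaceProfile(np.full(180, 4.2), "endocortical", "flow_predictor")
        out = triangular_smooth(prof, 30.0)
        np.testing.assert_allclose(out.values, 4.2, rtol=1e-12)

    def test_impulse_response_is_normalized_kernel(self):
        values = np.zeros(180)
        values[90] = 1.0
        out = triangular_smooth(
            SurfaceProfile(values, "endocortical", "flow_predictor"), 30.0
        )
        assert out.values.sum() == pytest.approx(1.0, rel=1e-12)
        assert out.values[90] == out.values.max()
        # support is ±(15° − one wedge) around the impulse
        assert out.values[82] == 0.0 and out.values[98] == 0.0
        assert out.values[83] > 0.0 and out.values[97] > 0.0

    def test_matches_brute_force_circular_convolution(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=180)
        out = triangular_smooth(
            SurfaceProfile(values, "periosteal", "flow_predictor"), 30.0
        )
        kernel = np.array([max(0.0, 1.0 - abs(k) / 7.5) for k in range(-7, 8)])
        kernel /= kernel.sum()
        brute = np.array(
            [
                sum(
                    kernel[k + 7] * values[(i + k) % 180]
                    for k in range(-7, 8)
                )
                for i in range(180)
            ]
        )
        np.testing.assert_allclose(out.values, brute, rtol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(st.floats(-100, 100), min_size=180, max_size=180),
        st.sampled_from([4.0, 10.0, 30.0, 60.0]),
    )
    def test_circular_mean_preserved(self, values, window):
        prof = SurfaceProfile(np.asarray(values), "endocortical", "flow_predictor")
        out = triangular_smooth(prof, window)
        assert out.values.mean() == pytest.approx(prof.values.mean(), abs=1e-9)

    def test_incommensurate_window_rejected(self):
        prof = SurfaceProfile(np.zeros(180), "endocortical", "flow_predictor")
        with pytest.raises(ValidationError):
            triangular_smooth(prof, 5.0)


class TestCalibrationAndRmse:
    def _profiles(self, pred_values, meas_values):
        return (
            SurfaceProfile(pred_values, "endocortical", "flow_predictor"),
            SurfaceProfile(meas_values, "endocortical", "remodeling_thickness"),
        )

    def test_exact_affine_relation_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, size=180)
        pred, meas = self._profiles(x, 3.0 * x + 1.0)
        cal = calibrate(pred, meas)
        assert cal.slope == pytest.approx(3.0)
        assert cal.intercept == pytest.approx(1.0)
        assert rmse(cal.calibrated[0], meas) == pytest.approx(0.0, abs=1e-10)

    def test_identity_when_measured_equals_predicted(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 2, size=180)
        pred, meas = self._profiles(x, x.copy())
        cal = calibrate(pred, meas)
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noisy_affine_recovered_within_ci(self):
        """Ordinary-least-squares oracle on a noisy affine relation."""
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, size=360)
        y = 2.0 * x + 5.0 + rng.normal(0, 0.5, size=360)
        pred = SurfaceProfile(x, "endocortical", "flow_predictor")
        meas = SurfaceProfile(y, "endocortical", "remodeling_thickness")
        cal = calibrate(pred, meas)
        X = np.column_stack([x, np.ones_like(x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert cal.slope == pytest.approx(beta[0], rel=1e-9)
        assert cal.intercept == pytest.approx(beta[1], rel=1e-9)
        sigma = 0.5 / (np.std(x) * np.sqrt(len(x)))
        assert abs(cal.slope - 2.0) < 4 * sigma

    def test_constant_predictor_degenerates_to_mean(self):
        pred, meas = self._profiles(np.full(180, 2.0), np.arange(180.0))
        cal = calibrate(pred, meas)
        assert cal.slope == 0.0
        assert cal.intercept == pytest.approx(np.mean(np.arange(180.0)))

    def test_rmse_offset_and_random_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=180)
        pa = SurfaceProfile(a, "endocortical", "remodeling_thickness")
        assert rmse(pa, pa) == 0.0
        pb = SurfaceProfile(a + 3.5, "endocortical", "remodeling_thickness")
        assert rmse(pa, pb) == pytest.approx(3.5)
        b = rng.normal(size=180)
        pc = SurfaceProfile(b, "endocortical", "remodeling_thickness")
        assert rmse(pa, pc) == pytest.approx(np.sqrt(np.mean((a - b) ** 2)))

    def test_rmse_length_mismatch(self):
        pa = SurfaceProfile(np.zeros(180), "endocortical", "remodeling_thickness")
        pb = SurfaceProfile(np.zeros(90), "endocortical", "remodeling_thickness")
        with pytest.raises(ValidationError):
            rmse(pa, pb)

    def test_calibrated_rmse_invariant_to_velocity_rescaling(self, small_experiment):
        from lcnflow import score_calibrated, triangular_smooth

        exp = small_experiment
        cfg = PredictorConfig()
        surfs = ("endocortical", "periosteal")
        base = [
            triangular_smooth(flow_predictor(exp.solution, exp.assignment, cfg, s), 30)
            for s in surfs
        ]
        meas = [exp.measured[s] for s in surfs]
        r0 = score_calibrated(base, meas)["rmse"]
        scaled = [SurfaceProfile(7.0 * p.values, p.surface, p.quantity) for p in base]
        r1 = score_calibrated(scaled, meas)["rmse"]
        for s in surfs:
            assert r1[s] == pytest.approx(r0[s], rel=1e-9)


class TestRSensitivity:
    def test_single_and_duplicate_R(self, small_experiment):
        exp = small_experiment
        tab = r_sensitivity(exp.solution, exp.assignment, exp.measured, [15.0])
        assert len(tab) == 1
        tab2 = r_sensitivity(exp.solution, exp.assignment, exp.measured, [9.0, 9.0])
        assert tab2["rmse_um"].iloc[0] == tab2["rmse_um"].iloc[1]

    def test_minimum_near_generating_R(self, small_experiment):
        exp = small_experiment  # responses generated with true R = 15 µm
        Rs = [3.0, 5.0, 8.0, 10.0, 12.0, 15.0, 18.0, 22.0, 26.0, 30.0]
        tab = r_sensitivity(exp.solution, exp.assignment, exp.measured, Rs)
        best = float(tab.loc[tab["rmse_um"].idxmin(), "R_um"])
        assert 10.0 <= best <= 20.0
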
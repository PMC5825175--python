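"""GQM forward model, likelihood, fitting, canonicalization, sigmoid
diagnostics, order selection, significance, and contours."""

import math

import numpy as np
import pytest
from scipy.special import expit

import erfield as ef
from erfield.gqm_fit import (GQMModel, contour_points, plane_stimulus,
                             subspace_principal_cosines)
from erfield.stimulus_gen import DesignMatrix
from erfield.synthetic_rgc import SpikeResponse


def _toy_model(rng, dim=5, n_exc=1, n_sup=1, sigmoid=(3.0, 2.0, 1.0)):
    comps = [(rng.standard_normal(dim), +1) for _ in range(n_exc)]
    comps += [(rng.standard_normal(dim), -1) for _ in range(n_sup)]
    return GQMModel(v0=rng.standard_normal(dim), components=comps,
                    sigmoid=sigmoid)


class TestGeneratorSignal:
    def test_unit_component_gives_one(self):
        v = np.zeros(4)
        v[1] = 1.0
        m = GQMModel(v0=np.zeros(4), components=[(v, +1)],
                     sigmoid=(1.0, 1.0, 0.0))
        assert ef.generator_signal(m, v) == pytest.approx(1.0)
        m_sup = GQMModel(v0=np.zeros(4), components=[(v, -1)],
                         sigmoid=(1.0, 1.0, 0.0))
        assert ef.generator_signal(m_sup, v) == pytest.approx(-1.0)

    def test_matches_scalar_loop_oracle(self, rng):
        # brute-force scalar reference on random small instances
        for _ in range(100):
            m = _toy_model(rng)
            S = rng.standard_normal(5)
            ref = sum(float(m.v0[i] * S[i]) for i in range(5))
            for v, w in m.components:
                proj = sum(float(v[i] * S[i]) for i in range(5))
                ref += w * proj ** 2
            assert ef.generator_signal(m, S) == pytest.approx(ref, abs=1e-10)

    def test_dimension_mismatch(self, rng):
        m = _toy_model(rng)
        with pytest.raises(ValueError):
            ef.generator_signal(m, np.zeros(7))


class TestExpectedResponse:
    def test_midpoint_and_asymptotes(self, rng):
        m = _toy_model(rng, n_exc=0, n_sup=0, sigmoid=(3.0, 2.0, 1.0))
        m.v0 = np.ones(5) / 5.0
        # g = c -> a / 2
        assert ef.expected_response(m, np.ones(5) * 1.0) == pytest.approx(1.5)
        assert ef.expected_response(m, np.ones(5) * 1e4) == pytest.approx(3.0)
        assert ef.expected_response(m, -np.ones(5) * 1e4) == pytest.approx(0.0)


class TestPoissonLogLikelihood:
    @pytest.mark.parametrize("rates,counts,expected", [
        ([1.0], [1], -1.0),
        ([2.0], [0], -2.0),
        ([1.0, 2.0], [1, 2], -1.0 + 2 * math.log(2.0) - 2.0),
    ])
    def test_hand_computed(self, rates, counts, expected):
        val = ef.poisson_log_likelihood(np.array(rates), np.array(counts))
        assert val == pytest.approx(expected, abs=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        rates = rng.uniform(0.1, 5.0, size=100)
        counts = rng.poisson(rates)
        ref = sum(c * math.log(r) - r for r, c in zip(rates, counts))
        assert ef.poisson_log_likelihood(rates, counts) == pytest.approx(
            ref, abs=1e-10)

    def test_zero_rate_with_spike(self):
        assert ef.poisson_log_likelihood(np.array([0.0]), np.array([1])) == -math.inf

    def test_zero_rate_zero_count_ok(self):
        assert ef.poisson_log_likelihood(np.array([0.0, 1.0]),
                                         np.array([0, 0])) == pytest.approx(-1.0)


class TestFitGQM:
    def test_single_component_recovery(self, medium_fit):
        design, gt, resp, stc, model = medium_fit
        v_true = gt.components[0][0]
        v_fit = next(v for v, w in model.components if w > 0)
        cos = abs(v_fit @ v_true) / (np.linalg.norm(v_fit) * np.linalg.norm(v_true))
        assert cos >= 0.9

    def test_loglik_trace_nondecreasing(self, medium_fit):
        *_, model = medium_fit
        trace = model.fit_meta["ll_trace"]
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-6 * (1.0 + np.abs(trace[:-1])))

    def test_deterministic(self, small_design, small_cell):
        gt, resp = small_cell
        a = ef.fit_gqm(small_design, resp, 1, 0, seed=3)
        b = ef.fit_gqm(small_design, resp, 1, 0, seed=3)
        assert np.array_equal(a.v0, b.v0)
        assert a.sigmoid == b.sigmoid

    def test_order_zero_is_linear_fit(self, small_design, small_cell):
        gt, resp = small_cell
        model = ef.fit_gqm(small_design, resp, 0, 0, seed=0)
        assert model.components == []
        assert model.fit_meta["loglik"] > -np.inf

    def test_direct_cell_v0_recovery(self, small_design):
        gt = ef.make_ground_truth(0, 0, small_design.L,
                                  small_design.n_electrodes, seed=50,
                                  mode="direct")
        resp = ef.simulate_responses(gt, small_design, seed=51)
        model = ef.fit_gqm(small_design, resp, 0, 0, seed=0)
        cos = abs(model.v0 @ gt.v0) / (np.linalg.norm(model.v0)
                                       * np.linalg.norm(gt.v0))
        assert cos >= 0.9


class TestCanonicalization:
    def test_generator_invariant(self, rng):
        m = _toy_model(rng, dim=8, n_exc=2, n_sup=1)
        canon = ef.canonicalize_components(m)
        S = rng.standard_normal((1000, 8))
        assert np.allclose(ef.generator_signal(m, S),
                           ef.generator_signal(canon, S), atol=1e-10)

    def test_component_norms_are_sqrt_eigenvalues(self, rng):
        m = _toy_model(rng, dim=6, n_exc=2, n_sup=1)
        canon = ef.canonicalize_components(m)
        lam = canon.fit_meta["kernel_eigenvalues"]
        for (v, w), l in zip(canon.components, lam):
            assert np.linalg.norm(v) == pytest.approx(math.sqrt(abs(l)))
            assert w == (1 if l > 0 else -1)

    def test_orthogonal_components_unchanged(self):
        v1 = np.array([1.0, 0.0, 0.0])
        v2 = np.array([0.0, 2.0, 0.0])
        m = GQMModel(v0=np.zeros(3), components=[(v2, +1), (v1, +1)],
                     sigmoid=(1.0, 1.0, 0.0))
        canon = ef.canonicalize_components(m)
        V = np.abs(canon.component_matrix())
        assert np.allclose(V[:, 0], np.abs(v2))
        assert np.allclose(V[:, 1], np.abs(v1))

    def test_parallel_components_collapse(self):
        v = np.array([1.0, 1.0, 0.0]) / math.sqrt(2)
        m = GQMModel(v0=np.zeros(3), components=[(v, +1), (2 * v, +1)],
                     sigmoid=(1.0, 1.0, 0.0))
        canon = ef.canonicalize_components(m)
        assert len(canon.components) == 1
        # combined eigenvalue = 1^2 + 2^2
        assert np.linalg.norm(canon.components[0][0]) == pytest.approx(
            math.sqrt(5.0))


class TestSigmoidDiagnostic:
    def test_recovers_known_sigmoid(self, rng):
        g = rng.normal(1.0, 1.2, size=20000)
        rates = 3.0 * expit(2.0 * (g - 1.0))
        counts = rng.poisson(rates)
        fit = ef.fit_sigmoid_nonlinearity(g, counts)
        assert fit.a == pytest.approx(3.0, rel=0.1)
        assert fit.b == pytest.approx(2.0, rel=0.1)
        assert fit.c == pytest.approx(1.0, rel=0.1)

    def test_bin_means_are_exact_means(self, rng):
        g = rng.standard_normal(1000)
        counts = rng.poisson(1.0, size=1000)
        fit = ef.fit_sigmoid_nonlinearity(g, counts, bin_size=200)
        order = np.argsort(g, kind="stable")
        first_bin = counts[order][:200]
        assert fit.binned_curve[0, 1] == pytest.approx(first_bin.mean())
        assert fit.binned_curve.shape[0] == 5

    def test_flat_data_flagged(self):
        g = np.linspace(-1, 1, 1000)
        counts = np.full(1000, 2)
        fit = ef.fit_sigmoid_nonlinearity(g, counts)
        assert fit.flat
        assert fit.a == pytest.approx(2.0)

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            ef.fit_sigmoid_nonlinearity(rng.standard_normal(300),
                                        np.zeros(300))


class TestOrderSelection:
    def test_linear_cell_selects_small_order(self, small_design):
        gt = ef.make_ground_truth(1, 0, small_design.L,
                                  small_design.n_electrodes, seed=60,
                                  mode="direct")
        resp = ef.simulate_responses(gt, small_design, seed=61)
        order = ef.select_model_order(small_design, resp, max_exc=2,
                                      max_sup=2, seed=0)
        assert order[0] + order[1] <= 1

    def test_pure_noise_selects_zero(self, small_design, rng):
        counts = rng.poisson(0.5, size=small_design.n_responses)
        order = ef.select_model_order(small_design,
                                      SpikeResponse(counts=counts),
                                      max_exc=2, max_sup=2, seed=0)
        assert order == (0, 0)


class TestElectrodeSignificance:
    def test_planted_entries_flagged(self, medium_fit):
        design, gt, resp, stc, model = medium_fit
        mask = ef.electrode_significance(model, design, resp, n_boot=100,
                                         seed=0)
        assert mask.shape == (3, design.rows.shape[1])
        # the fitted excitatory component slot should flag the planted
        # excitatory electrodes (slot order: v0, exc, sup)
        exc_idx = gt.sig_electrodes[0]
        assert mask[1, exc_idx].mean() >= 0.75
        sup_idx = gt.sig_electrodes[1]
        assert mask[2, sup_idx].mean() >= 0.75

    def test_batched_matches_scipy_mask(self, small_design, small_cell):
        gt, resp = small_cell
        stc = ef.compute_stc(small_design, resp)
        m1 = ef.fit_gqm(small_design, resp, 1, 1, init=stc, seed=0)
        m2 = ef.fit_gqm(small_design, resp, 1, 1, init=stc, seed=0)
        mask_b = ef.electrode_significance(m1, small_design, resp,
                                           n_boot=100, seed=4,
                                           method="batched")
        mask_s = ef.electrode_significance(m2, small_design, resp,
                                           n_boot=100, seed=4,
                                           method="scipy")
        sd_b = m1.fit_meta["null_sd"]
        sd_s = m2.fit_meta["null_sd"]
        ratio = np.median(sd_b / sd_s)
        assert 0.7 < ratio < 1.4
        assert (mask_b == mask_s).mean() > 0.8

    def test_low_boot_warns(self, small_design, small_cell):
        gt, resp = small_cell
        model = ef.fit_gqm(small_design, resp, 1, 0, seed=0)
        with pytest.warns(UserWarning):
            ef.electrode_significance(model, small_design, resp, n_boot=30,
                                      seed=0, n_iter=20)


@pytest.fixture(scope="module")
def canon_model():
    rng = np.random.default_rng(7)
    m = _toy_model(rng, dim=6, n_exc=2, n_sup=1, sigmoid=(3.0, 1.5, 0.5))
    return ef.canonicalize_components(m)


class TestResponseContour:
    def test_exc_exc_is_ellipse(self, canon_model):
        c = ef.response_contour(canon_model, 0, 1, level=1.0)
        assert c["kind"] == "ellipse"
        assert c["w_i"] == c["w_j"] == 1

    def test_exc_sup_is_hyperbola(self, canon_model):
        c = ef.response_contour(canon_model, 0, 2, level=1.0)
        assert c["kind"] == "hyperbola"

    def test_points_on_contour_give_level(self, canon_model):
        m = canon_model
        for i, j in ((0, 1), (0, 2)):
            c = ef.response_contour(m, i, j, level=1.2)
            pts = contour_points(c, x_range=(-3.0, 3.0), n=50)
            assert len(pts) > 0
            for x, y in pts[:20]:
                S = plane_stimulus(m, i, j, x, y)
                assert ef.expected_response(m, S) == pytest.approx(
                    1.2, abs=1e-9)

    def test_level_out_of_range(self, canon_model):
        with pytest.raises(ValueError):
            ef.response_contour(canon_model, 0, 1, level=5.0)
        with pytest.raises(ValueError):
            ef.response_contour(canon_model, 0, 0, level=1.0)


class TestPrincipalCosines:
    def test_identical_subspaces(self, rng):
        A = rng.standard_normal((8, 2))
        Q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
        cos = subspace_principal_cosines(A, A @ Q)   # rotated basis
        assert np.allclose(cos, 1.0, atol=1e-12)

    def test_orthogonal_subspaces(self):
        A = np.eye(4)[:, :2]
        B = np.eye(4)[:, 2:]
        cos = subspace_principal_cosines(A, B)
        assert np.allclose(cos, 0.0, atol=1e-12)
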
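"""Consensus OPLS: scaling, decomposition geometry, CV, permutations, loadings."""

import numpy as np
import pytest

import mbopls as m
from mbopls.opls import AlignmentError, NotFittedError, OplsError

from conftest import run_scenario
from oracles import pls1_single_component


@pytest.fixture(scope="module")
def noise_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 15))
    y = X[:, 0] + 0.5 * rng.normal(size=30)
    return X, y


class TestScaleBlock:
    def test_uv_gives_zero_mean_unit_sd(self, noise_data):
        X, _ = noise_data
        Xs, params = m.scale_block(X, "uv")
        assert np.allclose(Xs.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Xs.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_center_is_idempotent(self, noise_data):
        X, _ = noise_data
        Xc, _ = m.scale_block(X, "center")
        Xcc, _ = m.scale_block(Xc, "center")
        assert np.allclose(Xc, Xcc)

    def test_pareto_vs_uv_hand_matrix(self):
        X = np.array([[1.0, 10.0, 0.0],
                      [2.0, 30.0, 0.0],
                      [3.0, 50.0, 0.0]])
        sd = X.std(axis=0, ddof=1)
        Xu, pu = m.scale_block(X, "uv")
        Xp, pp = m.scale_block(X, "pareto")
        centered = X - X.mean(axis=0)
        assert np.allclose(Xu[:, :2], centered[:, :2] / sd[:2])
        assert np.allclose(Xp[:, :2], centered[:, :2] / np.sqrt(sd[:2]))
        # zero-variance column centered only and flagged
        assert np.allclose(Xu[:, 2], 0) and pu.zero_variance[2]


class TestFitGeometry:
    def test_orthogonal_scores_uncorrelated_with_predictive(self, noise_data):
        X, y = noise_data
        model = m.fit_consensus_opls([X], y, n_ortho=2)
        for k in range(model.T_ortho.shape[1]):
            r = np.corrcoef(model.t_pred, model.T_ortho[:, k])[0, 1]
            assert abs(r) < 1e-6

    def test_duplicated_block_symmetry(self, noise_data):
        X, y = noise_data
        m1 = m.fit_consensus_opls([X], y, n_ortho=1)
        m2 = m.fit_consensus_opls([X, X.copy()], y, n_ortho=1)
        assert np.allclose(m2.block_weights, [0.5, 0.5], atol=1e-12)
        assert np.max(np.abs(m2.t_pred - m1.t_pred)) < 1e-8
        assert abs(m2.r2y - m1.r2y) < 1e-8

    def test_single_block_no_ortho_equals_pls1_oracle(self, noise_data):
        X, y = noise_data
        model = m.fit_consensus_opls([X], y, n_ortho=0)
        Xs, _ = m.scale_block(X, "uv")
        expected = pls1_single_component(Xs, y)
        assert np.max(np.abs(model.predict([X]) - expected)) < 1e-8

    def test_rotation_invariance_of_kernel_quantities(self, noise_data):
        X, y = noise_data
        rng = np.random.default_rng(7)
        Q, _ = np.linalg.qr(rng.normal(size=(X.shape[1],) * 2))
        m1 = m.fit_consensus_opls([X], y, n_ortho=1, scaling="center")
        m2 = m.fit_consensus_opls([X @ Q], y, n_ortho=1, scaling="center")
        assert abs(m1.r2y - m2.r2y) < 1e-8
        assert np.max(np.abs(m1.t_pred - m2.t_pred)) < 1e-8
        q1 = m.cross_validated_q2([X], y, 1, 5, seed=0, scaling="center")
        q2 = m.cross_validated_q2([X @ Q], y, 1, 5, seed=0, scaling="center")
        assert abs(q1 - q2) < 1e-8

    def test_predictive_score_oriented_with_response(self, noise_data):
        X, y = noise_data
        for yy in (y, -y):
            model = m.fit_consensus_opls([X], yy, n_ortho=1)
            assert np.corrcoef(model.t_pred, yy)[0, 1] > 0

    def test_zero_variance_response_rejected(self, noise_data):
        X, _ = noise_data
        with pytest.raises(OplsError):
            m.fit_consensus_opls([X], np.ones(30), n_ortho=1)

    def test_misaligned_blocks_rejected(self, noise_data):
        X, y = noise_data
        with pytest.raises(AlignmentError):
            m.fit_consensus_opls([X, X[:-1]], y, n_ortho=1)

    def test_q2_never_exceeds_r2_on_training_data(self):
        for seed in range(5):
            res = run_scenario(seed, n_ions_neg=60, n_ions_pos=50,
                               n_clones_neg=0, n_clones_pos=0,
                               n_subthreshold_neg=0, n_subthreshold_pos=0)
            q2 = m.cross_validated_q2([res["neg_f"], res["pos_f"]], res["y"],
                                      1, 7, seed=seed)
            assert q2 <= res["model"].r2y


class TestSyntheticRecovery:
    def test_default_scenario_fit_quality_and_score_ordering(self, default_fit):
        model, design = default_fit["model"], default_fit["design"]
        assert model.r2y >= 0.7
        by_organ = {o: model.t_pred[(design["organ"] == o).to_numpy()].mean()
                    for o in ("stem_bark", "leaf", "fruit")}
        assert by_organ["stem_bark"] > by_organ["leaf"] > by_organ["fruit"]

    def test_no_planted_orthogonal_structure_gives_tiny_ortho_variance(self):
        # blocks made of active ions only, low noise, moderate effect sizes
        # (large log-scale effects would add real curvature variance): the
        # single planted activity axis leaves almost nothing orthogonal
        res = run_scenario(21, n_ions_neg=5, n_ions_pos=5, n_active=10,
                           n_clones_neg=0, n_clones_pos=0,
                           n_subthreshold_neg=0, n_subthreshold_pos=0,
                           noise_sd_log_intensity=0.05,
                           effect_size_range=(1.0, 1.0))
        ev = res["model"].explained_variance
        assert ev["orthogonal"][0] < 0.02

    def test_planted_actives_rank_in_top_decile_of_loadings(self, default_fit):
        lo = default_fit["loadings"].sort_values("predictive", ascending=False)
        ranks = {ion: i + 1 for i, ion in enumerate(lo["ion_id"])}
        active = [i for i in default_fit["gt"].active_ion_ids if i in ranks]
        assert active
        mean_rank = np.mean([ranks[i] for i in active])
        assert mean_rank <= 0.1 * len(lo)


class TestCrossValidation:
    def test_pure_noise_mean_q2_not_positive(self):
        rng = np.random.default_rng(1)
        q2s = []
        for seed in range(40):
            X1 = rng.normal(size=(30, 20))
            X2 = rng.normal(size=(30, 15))
            y = rng.normal(size=30)
            q2s.append(m.cross_validated_q2([X1, X2], y, 1, 5, seed=seed))
        assert np.mean(q2s) <= 0

    def test_strong_signal_q2_high(self, default_fit):
        design = default_fit["design"]
        strata = (design["organ"] + "/" + design["site"]).to_numpy()
        q2 = m.cross_validated_q2([default_fit["neg_f"], default_fit["pos_f"]],
                                  default_fit["y"], 1, 7, seed=1, strata=strata)
        assert q2 > 0.6

    def test_leave_one_out_runs(self, noise_data):
        X, y = noise_data
        q2 = m.cross_validated_q2([X], y, 1, k_folds=len(y), seed=0)
        assert np.isfinite(q2)

    def test_k_folds_out_of_range_rejected(self, noise_data):
        X, y = noise_data
        with pytest.raises(OplsError):
            m.cross_validated_q2([X], y, 1, k_folds=1)


class TestPermutationTest:
    def test_strong_signal_hits_minimum_p(self, default_fit):
        res = m.permutation_test([default_fit["neg_f"], default_fit["pos_f"]],
                                 default_fit["y"], 1, n_permutations=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)

    def test_same_seed_identical_null(self, noise_data):
        X, y = noise_data
        a = m.permutation_test([X], y, 1, 19, seed=5, k_folds=5)
        b = m.permutation_test([X], y, 1, 19, seed=5, k_folds=5)
        assert a.null_q2 == b.null_q2 and a.p_value == b.p_value

    def test_minimum_permutation_count_enforced(self, noise_data):
        X, y = noise_data
        with pytest.raises(OplsError):
            m.permutation_test([X], y, 1, 10)


class TestLoadings:
    def test_ion_equal_to_score_attains_max_loading(self, noise_data):
        X, y = noise_data
        model = m.fit_consensus_opls([X], y, n_ortho=1)
        # append a synthetic ion proportional to the predictive score
        X2 = np.column_stack([X, model.t_pred * 3.0 + 50.0])
        model2 = m.fit_consensus_opls([X2], y, n_ortho=1)
        lo = m.back_project_loadings(model2, [X2])
        assert lo["predictive"].idxmax() == len(lo) - 1

    def test_orthogonal_ion_has_zero_predictive_loading(self, noise_data):
        X, y = noise_data
        model = m.fit_consensus_opls([X], y, n_ortho=0)
        t = model.t_pred
        rng = np.random.default_rng(2)
        v = rng.normal(size=len(t))
        v -= v.mean()
        v -= (v @ t) / (t @ t) * t  # exactly orthogonal to the score
        lo_val = (v / v.std(ddof=1)) @ (t / np.linalg.norm(t))
        assert abs(lo_val) < 1e-10

    def test_unfitted_model_state_error(self, noise_data):
        X, y = noise_data
        model = m.fit_consensus_opls([X], y, n_ortho=0)
        model.t_pred = None
        with pytest.raises(NotFittedError):
            m.back_project_loadings(model, [X])
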
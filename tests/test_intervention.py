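"""Covariance eigenanalysis, candidate selection and simulated intervention."""

import warnings

import numpy as np
import pytest

import dnbkit as dk
from dnbkit.errors import (
    InsufficientSamplesError,
    InvalidConfigurationError,
    InvalidInputError,
)
from dnbkit.intervention import (
    InterventionRanker,
    _spectrum_svd,
    select_largest_gap,
)

from conftest import make_matrix


def power_iteration(cov, n_iter=10_000):
    """Independent oracle for the leading eigenpair."""
    v = np.ones(cov.shape[0]) / np.sqrt(cov.shape[0])
    for _ in range(n_iter):
        w = cov @ v
        v = w / np.linalg.norm(w)
    return float(v @ cov @ v), v


class TestSampleCovariance:
    def test_identical_samples_give_zero_matrix(self):
        m = make_matrix([[1.0, 1.0], [2.0, 2.0]])
        assert np.all(dk.sample_covariance(m) == 0)

    def test_matches_direct_formula(self):
        values = np.array([[1.0, 2.0, 4.0], [0.0, 1.0, -1.0]])
        cov = dk.sample_covariance(make_matrix(values))
        expected = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                mi, mj = values[i].mean(), values[j].mean()
                expected[i, j] = sum(
                    (values[i][k] - mi) * (values[j][k] - mj) for k in range(3)
                ) / 2
        np.testing.assert_allclose(cov, expected, atol=1e-12)

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(0)
        cov = dk.sample_covariance(make_matrix(rng.normal(size=(6, 4))))
        assert np.array_equal(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_single_sample_rejected(self):
        with pytest.raises(InsufficientSamplesError):
            dk.sample_covariance(make_matrix([[1.0], [2.0]]))


class TestDominantEigen:
    def test_diagonal_matrix(self):
        lam, v = dk.dominant_eigen(np.diag([2.0, 1.0]))
        assert lam == pytest.approx(2.0)
        np.testing.assert_allclose(v, [1.0, 0.0], atol=1e-12)

    def test_symmetric_two_by_two_closed_form(self):
        lam, v = dk.dominant_eigen(np.array([[2.0, 1.0], [1.0, 2.0]]))
        assert lam == pytest.approx(3.0)
        np.testing.assert_allclose(np.abs(v), np.ones(2) / np.sqrt(2), atol=1e-12)
        assert v[0] > 0  # sign convention

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(17)
        B = rng.normal(size=(8, 8))
        cov = B @ B.T
        lam, v = dk.dominant_eigen(cov)
        lam_o, v_o = power_iteration(cov)
        assert lam == pytest.approx(lam_o, abs=1e-8)
        assert abs(v @ v_o) >= 1 - 1e-8

    def test_non_symmetric_rejected(self):
        with pytest.raises(InvalidInputError):
            dk.dominant_eigen(np.array([[1.0, 2.0], [0.0, 1.0]]))

    @pytest.mark.parametrize("shape", [(50, 8), (8, 50)])
    def test_hdlss_svd_path_agrees_with_dense_path(self, shape):
        rng = np.random.default_rng(shape[0])
        values = rng.normal(size=shape)
        evals_svd, v_svd = _spectrum_svd(values)
        cov = np.atleast_2d(np.cov(values, ddof=1))
        evals_dense, vecs_dense = np.linalg.eigh(cov)
        assert evals_svd[0] == pytest.approx(evals_dense[-1], abs=1e-8)
        assert abs(v_svd @ vecs_dense[:, -1]) >= 1 - 1e-8


class TestInterventionIndex:
    def test_isotropic_covariance_flags_degenerate_spectrum(self):
        with pytest.warns(RuntimeWarning):
            ranking = dk.intervention_index(np.eye(3), ["a", "b", "c"])
        assert ranking.eigengap_warning

    def test_index_is_absolute_eigenvector_loading(self):
        v = np.array([0.8, -0.6])
        cov = 2.0 * np.outer(v, v) + 0.5 * (np.eye(2) - np.outer(v, v))
        ranking = dk.intervention_index(cov, ["gene1", "gene2"])
        np.testing.assert_allclose(ranking.index, [0.8, 0.6], atol=1e-12)
        assert ranking.ranking == ("gene1", "gene2")

    def test_unit_norm_invariant(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(12, 12))
        ranking = dk.intervention_index(B @ B.T, [f"g{i}" for i in range(12)])
        assert np.sum(ranking.index**2) == pytest.approx(1.0, abs=1e-10)
        assert sorted(ranking.ranking) == sorted(ranking.gene_ids)

    def test_top_ranked_genes_match_planted_module_on_analytic_covariance(
        self, demo_model
    ):
        sigma = dk.stationary_covariance(demo_model, 0.95)
        ranking = dk.intervention_index(sigma, [f"g{i:04d}" for i in range(500)])
        planted = {f"g{i:04d}" for i in demo_model.dnb_genes}
        assert set(ranking.ranking[:10]) == planted


class TestSelectTop:
    def _ranking(self, index, ids):
        n = len(ids)
        return dk.InterventionRanking(
            stage_label="t",
            gene_ids=tuple(ids),
            eigenvalues=np.linspace(2, 1, n),
            dominant_eigenvector=np.asarray(index),
            index=np.asarray(index),
            ranking=tuple(
                ids[i]
                for i in sorted(range(n), key=lambda i: (-index[i], ids[i]))
            ),
            eigengap_warning=False,
        )

    def test_full_selection_threshold_is_min_index(self):
        r = dk.select_top(self._ranking([0.9, 0.3, 0.1], ["a", "b", "c"]), k=3)
        assert r.selected == ("a", "b", "c")
        assert r.threshold == pytest.approx(0.1)

    def test_ties_resolved_lexicographically(self):
        r = dk.select_top(
            self._ranking([0.9, 0.5, 0.5, 0.1], ["d", "c", "b", "a"]), k=2
        )
        assert r.selected == ("d", "b")

    def test_k_out_of_range_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            dk.select_top(self._ranking([0.9, 0.1], ["a", "b"]), k=3)

    def test_selection_deterministic_under_rerun(self, demo_model):
        sel = []
        for _ in range(2):
            x = dk.sample_stage(demo_model, 0.95, 8, 0.1, seed=42, stage_label="pre")
            sel.append(dk.select_top(dk.ranking_from_expression(x), k=10).selected)
        assert sel[0] == sel[1]

    def test_largest_gap_heuristic_finds_block_edge(self):
        idx = [0.55, 0.54, 0.53, 0.52, 0.05, 0.04, 0.03, 0.02]
        r = select_largest_gap(self._ranking(idx, [f"g{i}" for i in range(8)]))
        assert len(r.selected) == 4


class TestBiotypeFilter:
    def test_published_candidate_list_filters_to_eight(self):
        from dnbkit.io import load_candidate_annotation

        annotation = load_candidate_annotation()
        top10 = [
            "Cst9", "Cox8c", "Ddx4", "Tuba3b", "Rbakdn", "4930449C09Rik",
            "Pttg1ip2", "Capza3", "Prr27", "Piwil1",
        ]
        kept = dk.filter_by_biotype(top10, annotation)
        assert len(kept) == 8
        assert set(top10) - set(kept) == {"Rbakdn", "4930449C09Rik"}
        assert kept == [g for g in top10 if g in kept]  # order preserved

    def test_empty_exclusion_set_is_identity(self):
        assert dk.filter_by_biotype(["a", "b"], {"a": "lncRNA", "b": "x"}, set()) == [
            "a",
            "b",
        ]

    def test_all_excluded_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = dk.filter_by_biotype(["a"], {"a": "lncRNA"})
        assert out == []

    def test_missing_annotation_warns_and_retains(self):
        with pytest.warns(UserWarning):
            out = dk.filter_by_biotype(["a", "b"], {"a": "protein_coding"})
        assert out == ["a", "b"]


class TestSimulateIntervention:
    def test_zero_strength_is_exact_noop(self, small_model):
        out = dk.simulate_intervention(small_model, 0.7, [0, 1], 0.0)
        assert out.leading_eig_after == out.leading_eig_before
        assert out.total_var_after == out.total_var_before
        assert out.dnb_var_after == out.dnb_var_before

    def test_scalar_ou_variance_halves(self):
        m = dk.NetworkModel(
            n_genes=1,
            dnb_genes=np.array([0]),
            drift_base=np.array([[-0.5]]),
            coupling=np.zeros((1, 1)),
            noise_cov=np.array([[1.0]]),
            control_schedule=(0.0,),
            critical_stage=0,
            baseline_expression=np.zeros(1),
        )
        out = dk.simulate_intervention(m, 0.0, [0], 0.5)
        assert out.total_var_before == pytest.approx(1.0, abs=1e-12)
        assert out.total_var_after == pytest.approx(0.5, abs=1e-12)

    def test_stabilization_never_raises_leading_eigenvalue(self, small_model):
        out = dk.simulate_intervention(small_model, 0.9, [0, 1, 2, 3], 0.5)
        assert out.leading_eig_after <= out.leading_eig_before
        assert out.total_var_after < out.total_var_before

    def test_variance_nonincreasing_in_strength(self, demo_model):
        sigma = dk.stationary_covariance(demo_model, 0.95)
        ranking = dk.intervention_index(
            sigma, [f"g{i:04d}" for i in range(500)]
        )
        targets = ranking.ranking[:10]
        variances = [
            dk.simulate_intervention(demo_model, 0.95, targets, s).total_var_after
            for s in (0.0, 0.25, 0.5, 1.0)
        ]
        assert np.all(np.diff(variances) <= 0)

    def test_matches_trajectory_simulation_oracle(self):
        # scaled-down system: targeted stabilization checked against a long
        # Euler-Maruyama run of the modified drift
        m = dk.build_network(5, 2, intra_coupling=2.0, seed=0,
                             control_schedule=(0.8,))
        out = dk.simulate_intervention(m, 0.8, [0, 1], 0.5)
        A2 = m.drift(0.8).copy()
        A2[[0, 1], [0, 1]] -= 0.5
        from dnbkit.model import simulate_trajectory

        traj = simulate_trajectory(m, 0.8, n_steps=40_000, dt=0.005, seed=3,
                                   burn_in=4_000, drift=A2, n_chains=50)
        assert np.trace(np.cov(traj.T, ddof=1)) == pytest.approx(
            out.total_var_after, rel=0.05
        )


class TestCompareToRandom:
    def test_degenerate_full_selection_returns_half_with_warning(self, small_model):
        sigma = dk.stationary_covariance(small_model, 0.5)
        ranking = dk.intervention_index(sigma, [f"g{i:04d}" for i in range(20)])
        with pytest.warns(UserWarning):
            frac = dk.compare_to_random(small_model, 0.5, ranking, 20, 0.5, 10, 0)
        assert frac == 0.5

    def test_informed_targets_beat_random_in_planted_model(self):
        m = dk.build_network(60, 6, seed=1, control_schedule=(0.95,))
        sigma = dk.stationary_covariance(m, 0.95)
        ranking = dk.intervention_index(sigma, [f"g{i:04d}" for i in range(60)])
        frac = dk.compare_to_random(m, 0.95, ranking, 6, 0.5, n_draws=50, seed=7)
        assert frac >= 0.95

    def test_exchangeable_null_model_shows_no_advantage(self):
        m = dk.build_network(60, 6, intra_coupling=0.0, seed=1,
                             control_schedule=(0.95,), destabilize="global")
        x = dk.sample_stage(m, 0.95, 8, 0.1, seed=1, stage_label="pre")
        ranking = dk.ranking_from_expression(x)
        frac = dk.compare_to_random(m, 0.95, ranking, 6, 0.5, n_draws=50, seed=7)
        assert 0.3 <= frac <= 0.7


class TestInterventionRankerEstimator:
    def test_selector_transform_keeps_selected_genes(self, demo_model):
        x = dk.sample_stage(demo_model, 0.95, 8, 0.1, seed=42, stage_label="pre")
        X = x.values.T  # samples x genes
        ranker = InterventionRanker(k=10).fit(X)
        Xt = ranker.transform(X)
        assert Xt.shape == (8, 10)
        assert np.sum(ranker.index_**2) == pytest.approx(1.0, abs=1e-10)

    def test_works_inside_sklearn_pipeline(self):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 30))
        pipe = Pipeline([("rank", InterventionRanker(k=5)), ("scale", StandardScaler())])
        assert pipe.fit_transform(X).shape == (12, 5)

    def test_feature_names_from_dataframe(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        ranker = InterventionRanker(k=2).fit(X)
        assert set(ranker.selected_) <= set("abcd")
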
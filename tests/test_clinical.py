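"""Clinical statistics: hypoxia scores, Cox fits, ROC, ER ANOVA, tightness,
sub-cluster discovery and correlation matrices."""

import numpy as np
import pandas as pd
import pytest

from uncles.clinical import (
    ClinicalCohort,
    cluster_profile_correlation,
    cox_hr,
    er_anova,
    hypoxia_score,
    roc_auc,
    select_clinical_probeset,
    signature_correlations,
    signature_er_test,
    subcluster_discovery,
    tightness_test,
)
from uncles.errors import FitError, InputError


def _cohort(expr: pd.DataFrame, time=None, event=None, er=None):
    n = expr.shape[1]
    idx = expr.columns
    return ClinicalCohort(
        expression=expr,
        os_time=pd.Series(time if time is not None else np.ones(n), index=idx),
        os_event=pd.Series(event if event is not None else np.ones(n, dtype=int), index=idx),
        er_status=pd.Series(er if er is not None else ["positive"] * n, index=idx),
    )


class TestSelectClinicalProbeset:
    def test_single_probeset(self):
        assert select_clinical_probeset(np.array([[1.0, 2.0]]), q25=0.0) == 0

    def test_most_variable_qualifier_wins(self):
        lo = np.array([10.0, 11.0, 9.0, 10.0])    # variance ~ 0.5
        hi = np.array([10.0, 13.0, 7.0, 10.0])    # variance ~ 4.5
        assert select_clinical_probeset(np.vstack([lo, hi]), q25=0.0) == 1

    def test_fallback_global_max_variance(self):
        lo = np.array([0.1, 0.2, 0.1, 0.2])
        hi = np.array([0.1, 0.9, 0.1, 0.9])
        # neither exceeds q25 in >= 25% of samples
        assert select_clinical_probeset(np.vstack([lo, hi]), q25=5.0) == 1


class TestHypoxiaScore:
    def test_rank_arithmetic(self):
        expr = pd.DataFrame([[5.0, 1.0, 3.0, 9.0]], index=["g"],
                            columns=list("abcd"))
        hs = hypoxia_score(["g"], _cohort(expr))
        np.testing.assert_allclose(hs.scores.to_numpy(), [2 / 3, 0.0, 1 / 3, 1.0])

    def test_all_tied_medians_give_half(self):
        expr = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=list("abc"))
        hs = hypoxia_score(["g"], _cohort(expr))
        np.testing.assert_allclose(hs.scores.to_numpy(), 0.5)

    def test_invariant_under_monotone_transform(self, clinical_cohort):
        # exact for an odd gene count, where the median is an order statistic
        # (an even count interpolates, which does not commute with x -> x^3)
        cohort, _, sigs = clinical_cohort
        sig = sigs["hyp"][:29]
        hs1 = hypoxia_score(sig, cohort).scores
        cubed = _cohort(cohort.expression ** 3, cohort.os_time.to_numpy(),
                        cohort.os_event.to_numpy(), cohort.er_status.to_numpy())
        hs2 = hypoxia_score(sig, cubed).scores
        np.testing.assert_allclose(hs1.to_numpy(), hs2.to_numpy())

    def test_range_and_extremes(self, clinical_cohort):
        cohort, _, sigs = clinical_cohort
        s = hypoxia_score(sigs["hyp"], cohort).scores.to_numpy()
        assert s.min() == 0.0 and s.max() == 1.0
        assert ((0 <= s) & (s <= 1)).all()

    def test_no_gene_present_rejected(self, clinical_cohort):
        cohort, _, _ = clinical_cohort
        with pytest.raises(InputError):
            hypoxia_score(["ABSENT"], cohort)


class TestCoxHR:
    def test_planted_beta_recovered(self, clinical_cohort):
        cohort, truth, sigs = clinical_cohort
        hs = hypoxia_score(sigs["hyp"], cohort)
        res = cox_hr(hs, cohort)
        assert res.coefficient == pytest.approx(1.5, abs=0.3)
        assert res.hazard_ratio == pytest.approx(np.exp(res.coefficient))
        assert res.p_value < 0.01

    def test_null_signature_ci_covers_zero(self):
        """beta = 0: the 95% CI should cover 0 in >= 90% of seeded replicates."""
        from uncles.simulate import ClinicalDesign, generate_clinical

        sigs = {"s": [f"X{i}" for i in range(15)]}
        covered = 0
        n_rep = 100
        for seed in range(n_rep):
            design = ClinicalDesign(n_samples=120, signature_effects={"s": 0.0},
                                    n_background_genes=0, seed=seed)
            cohort, _ = generate_clinical(design, sigs)
            res = cox_hr(hypoxia_score(sigs["s"], cohort), cohort)
            lo, hi = res.coefficient - 1.96 * res.se, res.coefficient + 1.96 * res.se
            covered += lo <= 0.0 <= hi
        assert covered >= 0.90 * n_rep

    def test_no_events_is_fit_error(self, clinical_cohort):
        cohort, _, sigs = clinical_cohort
        dead = _cohort(cohort.expression, cohort.os_time.to_numpy(),
                       np.zeros(cohort.n_samples, dtype=int),
                       cohort.er_status.to_numpy())
        with pytest.raises(FitError):
            cox_hr(hypoxia_score(sigs["hyp"], cohort), dead)

    def test_constant_score_is_fit_error(self, clinical_cohort):
        cohort, _, _ = clinical_cohort
        from uncles.clinical import HypoxiaScore

        flat = HypoxiaScore("flat", pd.Series(0.5, index=cohort.expression.columns))
        with pytest.raises(FitError):
            cox_hr(flat, cohort)


class TestRocAuc:
    def test_perfect_score(self):
        n = 40
        time = np.r_[np.full(20, 2.0), np.full(20, 20.0)]
        event = np.r_[np.ones(20, int), np.zeros(20, int)]
        expr = pd.DataFrame(np.r_[np.full(20, 9.0), np.full(20, 1.0)][None, :],
                            index=["g"], columns=[f"s{i}" for i in range(n)])
        cohort = _cohort(expr, time, event)
        hs = hypoxia_score(["g"], cohort)
        auc, p = roc_auc(hs, cohort, horizon_years=10)
        assert auc == 1.0
        assert p < 1e-4

    def test_null_score_auc_half(self, clinical_cohort):
        cohort, _, sigs = clinical_cohort
        hs = hypoxia_score(sigs["null"], cohort)
        auc, _ = roc_auc(hs, cohort, horizon_years=10)
        assert auc == pytest.approx(0.5, abs=0.07)

    def test_combined_signature_not_worse(self, clinical_cohort):
        cohort, _, sigs = clinical_cohort
        from uncles.clinical import HypoxiaScore
        from uncles.simulate import ClinicalDesign, generate_clinical

        design = ClinicalDesign(n_samples=400,
                                signature_effects={"a": 1.2, "b": 1.2},
                                n_background_genes=50, seed=21)
        two = {"a": [f"A{i}" for i in range(20)], "b": [f"B{i}" for i in range(20)]}
        co, _ = generate_clinical(design, two)
        hs_a = hypoxia_score(two["a"], co, "a")
        hs_b = hypoxia_score(two["b"], co, "b")
        combined = HypoxiaScore("a+b", (hs_a.scores + hs_b.scores) / 2)
        auc_a, _ = roc_auc(hs_a, co, 10)
        auc_b, _ = roc_auc(hs_b, co, 10)
        auc_c, _ = roc_auc(combined, co, 10)
        assert auc_c >= max(auc_a, auc_b) - 0.02

    def test_single_class_rejected(self, clinical_cohort):
        cohort, _, sigs = clinical_cohort
        hs = hypoxia_score(sigs["hyp"], cohort)
        with pytest.raises(InputError):
            roc_auc(hs, cohort, horizon_years=1e9)  # nobody survives past horizon


class TestErAnova:
    def test_equal_group_means_null(self):
        rng = np.random.default_rng(3)
        x = 5 + rng.normal(0, 1, 200)
        expr = pd.DataFrame(x[None, :], index=["g"],
                            columns=[f"s{i}" for i in range(200)])
        er = ["positive"] * 100 + ["negative"] * 100
        fc, p = er_anova(_cohort(expr, er=er), "g")
        assert fc == pytest.approx(1.0, abs=0.1)
        assert p > 0.05

    def test_f_equals_squared_t(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 60)
        er = ["positive"] * 30 + ["negative"] * 30
        expr = pd.DataFrame(x[None, :], index=["g"],
                            columns=[f"s{i}" for i in range(60)])
        _, p = er_anova(_cohort(expr, er=er), "g")
        z = (x - x.mean()) / x.std()
        t = stats.ttest_ind(z[:30], z[30:], equal_var=True)
        assert p == pytest.approx(t.pvalue, rel=1e-10)

    def test_planted_two_fold_change_recovered(self, clinical_cohort):
        cohort, _, sigs = clinical_cohort
        fcs = [er_anova(cohort, g)[0] for g in sigs["hyp"][:10]]
        assert np.exp(np.mean(np.log(fcs))) == pytest.approx(2.0, abs=0.3)

    def test_missing_er_rejected(self, clinical_cohort):
        cohort, _, _ = clinical_cohort
        allpos = _cohort(cohort.expression, cohort.os_time.to_numpy(),
                         cohort.os_event.to_numpy(), ["positive"] * cohort.n_samples)
        with pytest.raises(InputError):
            er_anova(allpos, cohort.expression.index[0])


class TestSignatureErTest:
    def test_planted_fold_change_signature_level(self, clinical_cohort):
        cohort, _, sigs = clinical_cohort
        res = signature_er_test(sigs["hyp"], cohort)
        assert res.fold_change == pytest.approx(2.0, abs=0.4)
        assert res.p_value < 1e-4

    def test_random_signature_near_null(self, clinical_cohort):
        cohort, _, _ = clinical_cohort
        rng = np.random.default_rng(5)
        background = [g for g in cohort.expression.index if g.startswith("BG")]
        ps = []
        for _ in range(40):
            sig = list(rng.choice(background, 15, replace=False))
            res = signature_er_test(sig, cohort)
            ps.append(res.p_value)
        # null p-values should not pile up near zero
        assert np.mean(np.array(ps) < 0.05) < 0.25

    def test_too_small_signature_rejected(self, clinical_cohort):
        cohort, _, sigs = clinical_cohort
        with pytest.raises(InputError):
            signature_er_test([sigs["hyp"][0]], cohort)


class TestTightnessTest:
    def test_duplicated_rows_maximally_tight(self):
        rng = np.random.default_rng(6)
        base = rng.normal(5, 1, 50)
        rows = np.vstack([base] * 10 + [rng.normal(5, 1, 50) for _ in range(90)])
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(100)],
                            columns=[f"s{i}" for i in range(50)])
        mse, p = tightness_test([f"g{i}" for i in range(10)], _cohort(expr),
                                n_random=200, seed=0)
        assert mse == pytest.approx(0.0, abs=1e-12)
        assert p < 1e-10

    def test_random_set_null_p_centred(self, clinical_cohort):
        cohort, _, _ = clinical_cohort
        rng = np.random.default_rng(7)
        background = [g for g in cohort.expression.index if g.startswith("BG")]
        ps = [tightness_test(list(rng.choice(background, 12, replace=False)),
                             cohort, n_random=150, seed=s)[1]
              for s in range(30)]
        assert 0.2 < np.median(ps) < 0.8

    def test_tiny_set_rejected(self, clinical_cohort):
        cohort, _, _ = clinical_cohort
        with pytest.raises(InputError):
            tightness_test([cohort.expression.index[0]], cohort)


class TestSubclusterDiscovery:
    @staticmethod
    def _blocked_cohort(sizes, seed=8, n=150):
        """Genes in independent correlated blocks (one latent factor each)."""
        rng = np.random.default_rng(seed)
        rows, names, truth = [], [], []
        for b, size in enumerate(sizes):
            latent = rng.normal(0, 1, n)
            block = []
            for i in range(size):
                g = f"B{b}_{i}"
                rows.append(5 + latent + rng.normal(0, 0.4, n))
                names.append(g)
                block.append(g)
            truth.append(set(block))
        expr = pd.DataFrame(np.exp(np.vstack(rows)), index=names,
                            columns=[f"s{i}" for i in range(n)])
        return _cohort(expr), truth

    def test_anticorrelated_halves_split(self):
        rng = np.random.default_rng(9)
        latent = rng.normal(0, 1, 100)
        up = [5 + latent + rng.normal(0, 0.2, 100) for _ in range(10)]
        down = [5 - latent + rng.normal(0, 0.2, 100) for _ in range(10)]
        expr = pd.DataFrame(np.vstack(up + down),
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(100)])
        res = subcluster_discovery(expr.index, _cohort(expr), min_size=3)
        assert len(res.subclusters) == 2
        assert {frozenset(s) for s in res.subclusters} == {
            frozenset(f"g{i}" for i in range(10)),
            frozenset(f"g{i}" for i in range(10, 20)),
        }

    def test_fully_correlated_single_subcluster(self):
        cohort, truth = self._blocked_cohort([12])
        res = subcluster_discovery(truth[0], cohort, min_size=3)
        assert len(res.subclusters) == 1
        assert set(res.subclusters[0]) == truth[0]

    def test_three_planted_blocks_recovered(self):
        cohort, truth = self._blocked_cohort([40, 20, 30], seed=10)
        all_genes = sorted(set().union(*truth))
        res = subcluster_discovery(all_genes, cohort, min_size=5)
        assert len(res.subclusters) == 3
        for want in truth:
            best = max(len(want & set(s)) / len(want | set(s)) for s in res.subclusters)
            assert best >= 0.9

    def test_correlation_matrix_shape_and_symmetry(self):
        cohort, truth = self._blocked_cohort([8])
        res = subcluster_discovery(truth[0], cohort, min_size=3)
        C = res.correlation.to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C), 1.0)


class TestCorrelations:
    def test_signature_self_correlation_unity(self, clinical_cohort):
        cohort, _, sigs = clinical_cohort
        M = signature_correlations(sigs, cohort)
        np.testing.assert_allclose(np.diag(M.to_numpy()), 1.0)
        np.testing.assert_allclose(M.to_numpy(), M.to_numpy().T, atol=1e-12)

    def test_matches_independent_rank_oracle(self, clinical_cohort):
        from scipy import stats

        cohort, _, sigs = clinical_cohort
        M = signature_correlations(sigs, cohort)
        a = hypoxia_score(sigs["hyp"], cohort).scores
        b = hypoxia_score(sigs["null"], cohort).scores
        rho = stats.spearmanr(a, b).statistic
        assert M.loc["hyp", "null"] == pytest.approx(rho, abs=1e-12)

    def test_profile_correlation_identity_and_negation(self, normalised_collection):
        collection, truth = normalised_collection
        ds = collection.datasets[0]
        genes = [g for g in truth["clusters"]["0"] if g in ds][:10]
        assert cluster_profile_correlation(genes, genes, ds) == pytest.approx(1.0)

    def test_planted_anticorrelated_pair_strongly_negative(self, normalised_collection):
        collection, truth = normalised_collection
        a = truth["clusters"]["0"]
        b = truth["clusters"]["1"]
        for ds in collection.datasets:
            rho = cluster_profile_correlation(a, b, ds)
            assert rho < -0.85

    def test_constant_profile_reported_as_nan(self):
        from uncles.datasets import ExpressionDataset

        ds = ExpressionDataset("d", ["a", "b"], ["c1", "c2"],
                               np.array([[1.0, 1.0], [0.0, 2.0]]))
        with pytest.warns(UserWarning):
            assert np.isnan(cluster_profile_correlation(["a"], ["b"], ds))
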
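import numpy as np
import pytest

from ctimpute import (
    attenuation_slope,
    baseline_correlations,
    classify_recovery,
    per_gene_metrics,
    per_subject_metrics,
    recovery_curve,
    run_paired_dge,
    simulate_phenotypes,
)
from ctimpute.dge import ModeratedResult


def make_result(gene_ids, logfc, fdr, p=None):
    logfc = np.asarray(logfc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    p = fdr if p is None else np.asarray(p, dtype=float)
    return ModeratedResult(
        gene_ids=list(gene_ids), logfc=logfc, sigma2=np.ones_like(logfc),
        df_resid=10.0, t=logfc, p=p, fdr=fdr, d0=4.0, s02=1.0,
    )


@pytest.fixture
def signal_arms():
    """Observed arm with genuine signal; imputed arm sharing directions but
    with independently shuffled significance."""
    rng = np.random.default_rng(31)
    g = 2000
    genes = [f"g{i}" for i in range(g)]
    obs_fdr = rng.random(g) ** 2  # enriched near 0
    logfc = rng.standard_normal(g)
    imp_fdr = obs_fdr[rng.permutation(g)]
    obs = make_result(genes, logfc, obs_fdr)
    imp = make_result(genes, logfc, imp_fdr)
    return obs, imp


class TestPhenotypes:
    def _expr(self, seed=0, g=50, n=30):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((g, n)) + np.linspace(0, 3, n)

    def test_binary_is_positive_score_indicator(self):
        expr = self._expr()
        ps = simulate_phenotypes(expr, [f"s{i}" for i in range(30)],
                                 n_phenotypes=5, seed=1)
        assert np.array_equal(ps.binary, (ps.scores > 0).astype(int))

    def test_zero_score_is_control(self):
        # exact-zero scores must map to 0, not 1
        assert ((np.zeros(3) > 0).astype(int) == 0).all()
        expr = self._expr(seed=2)
        ps = simulate_phenotypes(expr, [f"s{i}" for i in range(30)],
                                 n_phenotypes=3, seed=1)
        assert set(np.unique(ps.binary)) <= {0, 1}

    def test_fixed_seed_reproducible(self):
        expr = self._expr(seed=3)
        a = simulate_phenotypes(expr, [f"s{i}" for i in range(30)], seed=9)
        b = simulate_phenotypes(expr, [f"s{i}" for i in range(30)], seed=9)
        assert np.array_equal(a.continuous, b.continuous)

    def test_continuous_is_score_plus_unit_noise(self):
        expr = self._expr(seed=4)
        ps = simulate_phenotypes(expr, [f"s{i}" for i in range(30)],
                                 n_phenotypes=10, seed=5)
        resid = ps.continuous - ps.scores
        assert abs(resid.std() - 1.0) < 0.15

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotypes(np.ones((10, 12)), [f"s{i}" for i in range(12)],
                                n_phenotypes=2, seed=0)


class TestPairedDGE:
    def _setup(self, seed=0, g=40, n_train=12, n_test=12):
        rng = np.random.default_rng(seed)
        n = n_train + n_test
        samples = [f"s{i}" for i in range(n)]
        pheno = rng.standard_normal(n)
        beta = np.where(rng.random(g) < 0.4, rng.standard_normal(g) * 2, 0.0)
        obs = beta[:, None] * pheno[None, :] + rng.standard_normal((g, n))
        genes = [f"g{i}" for i in range(g)]
        return genes, obs, samples, samples[:n_train], samples[n_train:], pheno

    def test_identical_imputation_gives_identical_arms(self):
        genes, obs, samples, tr, te, pheno = self._setup()
        imp = obs[:, len(tr):]
        o, i = run_paired_dge(obs, genes, imp, genes, samples, tr, te, pheno)
        assert np.allclose(o.t, i.t)
        assert np.allclose(o.fdr, i.fdr)

    def test_gene_intersection_rule(self):
        genes, obs, samples, tr, te, pheno = self._setup()
        imp = obs[: len(genes) - 5, len(tr):]
        o, i = run_paired_dge(obs, genes, imp, genes[:-5], samples, tr, te,
                              pheno)
        assert o.gene_ids == i.gene_ids == genes[:-5]

    def test_permuted_imputation_decorrelates_logfc(self):
        genes, obs, samples, tr, te, pheno = self._setup(seed=1, g=600)
        rng = np.random.default_rng(2)
        imp = obs[:, len(tr):][rng.permutation(len(genes))]
        o, i = run_paired_dge(obs, genes, imp, genes, samples, tr, te, pheno)
        # arm-2 logFC reflects train-half signal, so compare the test-half
        # contribution: correlation should collapse towards the train-only part
        r_full = np.corrcoef(o.logfc, i.logfc)[0, 1]
        assert r_full < 0.9

    def test_empty_intersection_rejected(self):
        genes, obs, samples, tr, te, pheno = self._setup()
        with pytest.raises(ValueError):
            run_paired_dge(obs, genes, obs[:, len(tr):], ["zz"], samples,
                           tr, te, pheno)


class TestClassification:
    def test_identical_results_perfect_recovery(self):
        res = make_result(list("abcd"), [1, -1, 2, -2], [0.01, 0.2, 0.5, 0.04])
        cls = classify_recovery(res, res)
        assert cls.sensitivity == 1.0
        assert cls.specificity == 1.0
        assert cls.err == 0.0

    def test_flipped_sign_is_error(self):
        obs = make_result(["a"], [1.0], [0.01])
        imp = make_result(["a"], [-1.0], [0.01])
        cls = classify_recovery(obs, imp)
        assert cls.status[0] == "No"

    def test_six_gene_brute_force_oracle(self):
        obs_fdr = [0.01, 0.01, 0.01, 0.50, 0.50, 0.04]
        imp_fdr = [0.02, 0.90, 0.03, 0.70, 0.01, 0.04]
        obs_lfc = [1.0, 2.0, -1.0, 0.5, 0.3, -0.2]
        imp_lfc = [0.5, 1.0, 1.0, 0.2, 0.1, -0.1]
        obs = make_result(list("abcdef"), obs_lfc, obs_fdr)
        imp = make_result(list("abcdef"), imp_lfc, imp_fdr)
        cls = classify_recovery(obs, imp, fdr_obs=0.05, fdr_imp=0.05)
        # brute-force rule application
        expect = []
        for of, if_, ol, il in zip(obs_fdr, imp_fdr, obs_lfc, imp_lfc):
            if of < 0.05 and if_ < 0.05 and np.sign(ol) == np.sign(il):
                expect.append("Yes-Sig")
            elif of >= 0.05 and if_ >= 0.05:
                expect.append("Yes-NS")
            else:
                expect.append("No")
        assert list(cls.status) == expect
        # a: Yes-Sig, b: No (imp ns), c: No (sign flip), d: Yes-NS,
        # e: No (imp sig), f: Yes-Sig
        assert cls.sensitivity == pytest.approx(2 / 4)
        assert cls.specificity == pytest.approx(1 / 2)
        assert cls.err == pytest.approx(3 / 6)

    def test_no_observed_significant_reports_missing(self):
        obs = make_result(list("ab"), [1, 1], [0.5, 0.9])
        cls = classify_recovery(obs, obs)
        assert cls.sensitivity is None


class TestRecoveryCurve:
    def test_identical_arms_auc_one(self, signal_arms):
        obs, _ = signal_arms
        curve = recovery_curve(obs, obs)
        assert curve.auc == pytest.approx(1.0)

    def test_independent_imputed_significance_auc_half(self, signal_arms):
        obs, imp = signal_arms
        curve = recovery_curve(obs, imp)
        assert curve.auc == pytest.approx(0.5, abs=0.05)

    def test_degenerate_two_point_curve(self):
        obs = make_result(list("ab"), [1, 1], [0.01, 0.5])
        imp = make_result(list("ab"), [1, 1], [1.0, 1.0])
        curve = recovery_curve(obs, imp, grid=np.array([0.0, 1.01]))
        assert curve.auc == pytest.approx(0.5, abs=0.01)

    def test_sensitivity_monotone_specificity_antitone(self, signal_arms):
        obs, imp = signal_arms
        curve = recovery_curve(obs, imp)
        assert np.all(np.diff(curve.sensitivity) >= -1e-12)
        assert np.all(np.diff(curve.specificity) <= 1e-12)

    def test_auc_invariant_under_monotone_fdr_transform(self, signal_arms):
        """Transforming both the imputed FDRs and the grid by the same
        strictly increasing map leaves the curve and AUC unchanged."""
        obs, imp = signal_arms
        f = lambda x: np.asarray(x) ** 1.5
        imp2 = make_result(imp.gene_ids, imp.logfc, f(imp.fdr))
        base = recovery_curve(obs, imp)
        trans = recovery_curve(obs, imp2, grid=f(base.grid[1:]))
        assert trans.auc == pytest.approx(base.auc, abs=1e-9)

    def test_unsorted_grid_rejected(self, signal_arms):
        obs, imp = signal_arms
        with pytest.raises(ValueError):
            recovery_curve(obs, imp, grid=np.array([0.5, 0.1]))


class TestMetrics:
    def _slabs(self, seed=0, g=20, n=8):
        rng = np.random.default_rng(seed)
        obs = rng.standard_normal((g, n)) + 5
        genes = [f"g{i}" for i in range(g)]
        samples = [f"s{i}" for i in range(n)]
        return obs, genes, samples

    def test_perfect_imputation(self):
        obs, genes, samples = self._slabs()
        df = per_gene_metrics(obs, genes, samples, obs, genes, samples, samples)
        assert np.allclose(df["r"], 1.0)
        assert np.allclose(df["rmse_std"], 0.0)
        dfs = per_subject_metrics(obs, genes, samples, obs, genes, samples,
                                  samples)
        assert np.allclose(dfs["r"], 1.0)

    def test_constant_offset_closed_form(self):
        obs, genes, samples = self._slabs(seed=1)
        c = 0.7
        df = per_gene_metrics(obs, genes, samples, obs + c, genes, samples,
                              samples)
        assert np.allclose(df["r"], 1.0)
        assert np.allclose(df["rmse_std"], c / obs.mean(axis=1))

    def test_negated_centred_imputation_r_minus_one(self):
        obs, genes, samples = self._slabs(seed=2)
        imp = 2 * obs.mean(axis=1, keepdims=True) - obs
        df = per_gene_metrics(obs, genes, samples, imp, genes, samples, samples)
        assert np.allclose(df["r"], -1.0)

    def test_zero_variance_gene_r_missing(self):
        obs, genes, samples = self._slabs(seed=3)
        obs[0] = 4.2
        df = per_gene_metrics(obs, genes, samples, obs + 0.1, genes, samples,
                              samples)
        assert np.isnan(df["r"].iloc[0])

    def test_per_subject_hand_computed(self):
        obs = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0], [4.0, 0.0]])
        imp = np.array([[2.0, 0.0], [4.0, 0.0], [6.0, 0.0], [8.0, 0.0]])
        df = per_subject_metrics(obs, list("abcd"), ["s1", "s2"],
                                 imp, list("abcd"), ["s1", "s2"], ["s1"])
        assert df["r"].iloc[0] == pytest.approx(1.0)
        assert df["rmse"].iloc[0] == pytest.approx(
            np.sqrt(((obs[:, 0] - imp[:, 0]) ** 2).mean()))

    def test_too_few_samples_rejected(self):
        obs, genes, samples = self._slabs()
        with pytest.raises(ValueError):
            per_gene_metrics(obs, genes, samples, obs, genes, samples,
                             samples[:2])


class TestBaselineCorrelations:
    def test_derangement_never_pairs_self(self):
        obs, genes, samples = TestMetrics()._slabs(seed=4, n=9)
        df = baseline_correlations(obs, genes, samples, obs, genes, samples,
                                   samples, seed=3)
        assert all(a != b for a, b in zip(df["sample"], df["mismatched_sample"]))

    def test_identical_profiles_match_baseline(self):
        g, n = 15, 5
        rng = np.random.default_rng(5)
        profile = rng.standard_normal(g)
        obs = np.tile(profile[:, None], (1, n))
        genes = [f"g{i}" for i in range(g)]
        samples = [f"s{i}" for i in range(n)]
        df = baseline_correlations(obs, genes, samples, obs + 0.0, genes,
                                   samples, samples, seed=1)
        # every subject shares one profile: mismatched obs-vs-obs r is 1
        assert np.allclose(df["r_obs_vs_obs_mismatched"], 1.0)

    def test_single_subject_rejected(self):
        obs, genes, samples = TestMetrics()._slabs(seed=6, n=1)
        with pytest.raises(ValueError):
            baseline_correlations(obs, genes, samples, obs, genes, samples,
                                  samples, seed=0)


class TestAttenuation:
    def test_identity_slope_one(self):
        rng = np.random.default_rng(7)
        lfc = rng.standard_normal(50)
        slope, r2 = attenuation_slope(lfc, lfc)
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_half_scale(self):
        rng = np.random.default_rng(8)
        lfc = rng.standard_normal(50)
        slope, _ = attenuation_slope(lfc, 0.5 * lfc)
        assert slope == pytest.approx(0.5)

    def test_noisy_regression_recovery(self):
        rng = np.random.default_rng(9)
        lfc = rng.standard_normal(500)
        imp = 0.7 * lfc + rng.standard_normal(500) * 0.05
        slope, r2 = attenuation_slope(lfc, imp)
        assert slope == pytest.approx(0.7, abs=0.02)
        assert r2 > 0.95

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            attenuation_slope(np.ones(5), np.arange(5.0))
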
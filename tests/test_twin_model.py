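"""Unit and property tests for the bivariate-normal twin model core."""

import numpy as np
import pytest
from scipy import stats

from twinherit.errors import ValidationError
from twinherit.twin_model import (MODELS, ModelFit, TwinPairSet,
                                  VarianceComponents, bootstrap_ci,
                                  compare_models, falconer_h2, fit_all_models,
                                  fit_model, heritability_test, pair_negloglik)

from conftest import simulate_pairs

LOG_2PI = np.log(2.0 * np.pi)


def mvn_negloglik_oracle(pairs: TwinPairSet, vc: VarianceComponents) -> float:
    """Generic multivariate-normal density oracle (scipy, per-pair loop)."""
    v = vc.a2 + vc.c2 + vc.e2
    total = 0.0
    for arr, cov in ((pairs.mz, vc.a2 + vc.c2), (pairs.dz, 0.5 * vc.a2 + vc.c2)):
        if arr.size == 0:
            continue
        dist = stats.multivariate_normal(mean=[vc.mu, vc.mu],
                                         cov=[[v, cov], [cov, v]])
        total -= dist.logpdf(arr).sum()
    return total


class TestPairNegloglik:
    def test_single_mz_pair_identity_cov_at_origin(self):
        pairs = TwinPairSet([[0.0, 0.0]], [], strict=False)
        vc = VarianceComponents(0.0, 0.0, 1.0, 0.0)
        assert pair_negloglik(pairs, vc, "E") == pytest.approx(LOG_2PI, abs=1e-12)

    def test_single_mz_pair_identity_cov_at_ones(self):
        pairs = TwinPairSet([[1.0, 1.0]], [], strict=False)
        vc = VarianceComponents(0.0, 0.0, 1.0, 0.0)
        assert pair_negloglik(pairs, vc, "E") == pytest.approx(LOG_2PI + 1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generic_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pairs = TwinPairSet(rng.normal(size=(7, 2)), rng.normal(size=(5, 2)),
                            strict=False)
        a2, c2, e2 = rng.uniform(0.05, 1.0, 3)
        vc = VarianceComponents(a2, c2, e2, rng.normal())
        got = pair_negloglik(pairs, vc, "ACE")
        assert got == pytest.approx(mvn_negloglik_oracle(pairs, vc), abs=1e-10)

    def test_additive_over_pairs(self):
        rng = np.random.default_rng(3)
        mz = rng.normal(size=(4, 2))
        vc = VarianceComponents(0.3, 0.2, 0.5, 0.1)
        whole = pair_negloglik(TwinPairSet(mz, [], strict=False), vc)
        parts = sum(pair_negloglik(TwinPairSet(mz[i:i + 1], [], strict=False), vc)
                    for i in range(4))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_singular_covariance_is_inf_not_crash(self):
        pairs = TwinPairSet([[0.0, 1.0]], [], strict=False)
        vc = VarianceComponents(1.0, 0.0, 0.0, 0.0)  # e2 = 0 -> singular
        assert pair_negloglik(pairs, vc, "AE") == np.inf

    def test_fixed_component_must_be_zero(self):
        pairs = TwinPairSet([[0.0, 1.0]], [], strict=False)
        with pytest.raises(ValidationError):
            pair_negloglik(pairs, VarianceComponents(0.5, 0.1, 0.4), "AE")


def grid_search_oracle(pairs: TwinPairSet):
    """Zooming vectorized grid over path coefficients (a, c, e) and mu.

    Independent of the package optimizer; reaches ~1e-3 parameter resolution,
    ample for a 1e-4 log-likelihood tolerance on small instances.
    """
    y = pairs.pooled_values()
    sd = np.std(y)

    def nll(a, c, e, mu):
        a2, c2, e2 = a * a, c * c, e * e
        v = a2 + c2 + e2
        out = np.zeros(np.broadcast(a, mu).shape)
        for arr, cov in ((pairs.mz, a2 + c2), (pairs.dz, 0.5 * a2 + c2)):
            if arr.size == 0:
                continue
            det = v * v - cov * cov
            d1 = arr[:, 0][:, None] - mu[None]
            d2 = arr[:, 1][:, None] - mu[None]
            quad = ((v * (d1 * d1 + d2 * d2) - 2 * cov * d1 * d2) / det).sum(axis=0)
            n = arr.shape[0]
            out = out + np.where(det > 0, n * LOG_2PI + 0.5 * n * np.log(
                np.where(det > 0, det, 1.0)) + 0.5 * quad, np.inf)
        return out

    lo = np.array([0.0, 0.0, 1e-3, float(np.min(y))])
    hi = np.array([2 * sd, 2 * sd, 2 * sd, float(np.max(y))])
    best = None
    for _ in range(5):
        axes = [np.linspace(lo[i], hi[i], 13) for i in range(4)]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = [g.ravel() for g in grids]
        vals = nll(*flat)
        k = int(np.argmin(vals))
        best = np.array([f[k] for f in flat]), float(vals[k])
        steps = (hi - lo) / 12
        lo = np.maximum(lo, best[0] - 1.5 * steps)
        hi = best[0] + 1.5 * steps
        hi[2] = max(hi[2], 2e-3)
    return -best[1]


class TestFitModel:
    def test_e_model_closed_form(self):
        pairs = TwinPairSet([[1.0, 2.0]], [[3.0, 4.0]], strict=False)
        pairs_ok = TwinPairSet([[1.0, 2.0], [3.0, 4.0]], [[1.0, 3.0], [2.0, 4.0]])
        fit = fit_model(pairs_ok, "E")
        y = pairs_ok.pooled_values()
        assert fit.components.mu == pytest.approx(np.mean(y), abs=1e-12)
        assert fit.components.e2 == pytest.approx(np.var(y), abs=1e-12)
        n = y.size
        ll = -0.5 * n * (LOG_2PI + np.log(np.var(y)) + 1)
        assert fit.loglik == pytest.approx(ll, abs=1e-10)
        del pairs

    def test_ae_parameter_recovery_large_sample(self, pair_factory):
        rng = np.random.default_rng(42)
        pairs = pair_factory(2000, 2000, 0.6, 0.0, rng)
        fit = fit_model(pairs, "AE")
        assert fit.components.h2 == pytest.approx(0.6, abs=0.05)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_grid_search_oracle_small_instances(self, seed, pair_factory):
        rng = np.random.default_rng(seed)
        pairs = pair_factory(4, 4, 0.5, 0.1, rng)
        fit = fit_model(pairs, "ACE")
        assert fit.loglik >= grid_search_oracle(pairs) - 1e-4

    def test_profile_and_paths_methods_agree(self, pair_factory):
        rng = np.random.default_rng(10)
        pairs = pair_factory(40, 30, 0.5, 0.1, rng)
        for model in MODELS:
            a = fit_model(pairs, model, method="profile")
            b = fit_model(pairs, model, method="paths",
                          rng=np.random.default_rng(0))
            assert a.loglik == pytest.approx(b.loglik, abs=1e-5)

    def test_requires_two_pairs_per_zygosity(self):
        pairs = TwinPairSet([[0.0, 1.0]], [[0.0, 1.0]], strict=False)
        with pytest.raises(ValidationError):
            fit_model(pairs, "AE")

    def test_unknown_model_rejected(self, pair_factory):
        pairs = pair_factory(5, 5, 0.3, 0.0, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            fit_model(pairs, "ADE")


class TestInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_likelihood_nesting(self, seed, pair_factory):
        rng = np.random.default_rng(seed)
        pairs = pair_factory(71, 52, rng.uniform(0, 0.8), rng.uniform(0, 0.15), rng)
        ll = {m: f.loglik for m, f in fit_all_models(pairs).items()}
        assert ll["ACE"] >= max(ll["AE"], ll["CE"]) - 1e-6
        assert min(ll["AE"], ll["CE"]) >= ll["E"] - 1e-6

    def test_location_scale_invariance(self, pair_factory):
        rng = np.random.default_rng(9)
        pairs = pair_factory(50, 40, 0.5, 0.1, rng)
        h2_ref = fit_model(pairs, "AE").components.h2
        shifted = TwinPairSet(3.0 + 2.5 * pairs.mz, 3.0 + 2.5 * pairs.dz)
        assert fit_model(shifted, "AE").components.h2 == pytest.approx(h2_ref, abs=1e-6)

    def test_twin_order_exchangeability(self, pair_factory):
        rng = np.random.default_rng(13)
        pairs = pair_factory(30, 30, 0.4, 0.1, rng)
        swapped = TwinPairSet(pairs.mz[:, ::-1], pairs.dz[:, ::-1])
        for model in MODELS:
            a, b = fit_model(pairs, model), fit_model(swapped, model)
            assert a.loglik == pytest.approx(b.loglik, abs=1e-8)
            assert a.components.h2 == pytest.approx(b.components.h2, abs=1e-6)

    def test_agrees_with_falconer_at_scale(self, pair_factory):
        rng = np.random.default_rng(21)
        pairs = pair_factory(4000, 4000, 0.6, 0.1, rng)
        h2 = fit_model(pairs, "ACE").components.h2
        assert h2 == pytest.approx(falconer_h2(pairs), abs=0.05)


class TestCompareModels:
    @staticmethod
    def _fits(logliks):
        nf = {"ACE": 4, "AE": 3, "CE": 3, "E": 2}
        return {m: ModelFit(m, VarianceComponents(0.1, 0.1, 0.8), ll, nf[m],
                            True, "fp") for m, ll in logliks.items()}

    def test_equal_ace_ae_prefers_ae(self):
        fits = self._fits({"ACE": -100.0, "AE": -100.0, "CE": -105.0, "E": -110.0})
        cmp = compare_models(fits)
        assert cmp.aic["AE"] == cmp.aic["ACE"] - 2
        lrt = {(r["full"], r["reduced"]): r for r in cmp.lrt}
        assert lrt[("ACE", "AE")]["lambda"] == 0.0
        assert lrt[("ACE", "AE")]["pvalue"] == 1.0
        assert cmp.best_model == "AE"

    def test_hand_set_aic_arithmetic(self):
        fits = self._fits({"ACE": -100.0, "AE": -101.0, "CE": -103.0, "E": -110.0})
        cmp = compare_models(fits)
        assert cmp.aic == {"ACE": 208.0, "AE": 208.0, "CE": 212.0, "E": 224.0}
        assert cmp.best_model == "AE"  # tie at 208 resolves to fewer parameters

    def test_lrt_pairs_and_dfs(self):
        fits = self._fits({"ACE": -100.0, "AE": -101.0, "CE": -103.0, "E": -110.0})
        cmp = compare_models(fits)
        pairs = {(r["full"], r["reduced"]): r["df"] for r in cmp.lrt}
        assert pairs == {("ACE", "AE"): 1, ("ACE", "CE"): 1, ("AE", "E"): 1,
                         ("CE", "E"): 1, ("ACE", "E"): 2}
        lam = [r for r in cmp.lrt if (r["full"], r["reduced"]) == ("ACE", "E")][0]
        assert lam["lambda"] == pytest.approx(20.0)
        assert lam["pvalue"] == pytest.approx(stats.chi2.sf(20.0, 2))

    def test_mismatched_fingerprints_rejected(self):
        fits = self._fits({"ACE": -100.0, "AE": -101.0, "CE": -103.0, "E": -110.0})
        fits["E"].fingerprint = "other"
        with pytest.raises(ValidationError):
            compare_models(fits)


class TestHeritabilityTest:
    def test_null_data_rarely_significant(self, pair_factory):
        rng = np.random.default_rng(77)
        not_sig = sum(
            heritability_test(pair_factory(71, 52, 0.0, 0.0, rng)).pvalue >= 0.05
            for _ in range(60))
        assert not_sig >= 54  # >= 90% of replicates

    def test_perfect_mz_duplication_drives_h2_to_one(self):
        rng = np.random.default_rng(5)
        y_mz = rng.standard_normal(80)
        mz = np.column_stack([y_mz, y_mz])
        a = rng.standard_normal(60)
        dz = np.column_stack([a, 0.5 * a + np.sqrt(0.75) * rng.standard_normal(60)])
        ht = heritability_test(TwinPairSet(mz, dz))
        assert ht.h2 > 0.97
        assert ht.pvalue < 1e-10

    def test_ci_brackets_estimate_and_is_clipped(self, pair_factory):
        rng = np.random.default_rng(8)
        ht = heritability_test(pair_factory(71, 52, 0.6, 0.0, rng))
        assert 0.0 <= ht.ci_lo <= ht.h2 <= ht.ci_hi <= 1.0
        assert ht.lam >= 0.0
        assert 0.0 < ht.pvalue <= 1.0

    def test_recovery_at_paper_design_size(self, pair_factory):
        # ERAP2-scale signal: a2 = 0.87 with 71 MZ + 52 DZ pairs
        rng = np.random.default_rng(123)
        h2s = [heritability_test(pair_factory(71, 52, 0.87, 0.0, rng)).h2
               for _ in range(50)]
        assert np.mean(h2s) == pytest.approx(0.87, abs=0.05)


class TestBootstrapCI:
    def test_deterministic_given_seed(self, pair_factory):
        rng = np.random.default_rng(3)
        pairs = pair_factory(71, 52, 0.5, 0.0, rng)
        assert bootstrap_ci(pairs, B=200, seed=11) == bootstrap_ci(pairs, B=200, seed=11)

    def test_requires_minimum_replicates(self, pair_factory):
        pairs = pair_factory(10, 10, 0.5, 0.0, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            bootstrap_ci(pairs, B=50, seed=1)

    def test_median_inside_interval(self, pair_factory):
        rng = np.random.default_rng(4)
        pairs = pair_factory(71, 52, 0.6, 0.0, rng)
        lo, hi, samples = bootstrap_ci(pairs, B=300, seed=2, return_samples=True)
        assert lo <= np.median(samples) <= hi

    def test_near_perfect_mz_duplication_concentrates_near_one(self):
        rng = np.random.default_rng(6)
        y_mz = rng.standard_normal(100)
        mz = np.column_stack([y_mz, y_mz + rng.normal(0, 0.01, 100)])
        a = rng.standard_normal(80)
        dz = np.column_stack([a, 0.5 * a + np.sqrt(0.75) * rng.standard_normal(80)])
        lo, hi = bootstrap_ci(TwinPairSet(mz, dz), B=200, seed=9)
        assert lo > 0.9
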
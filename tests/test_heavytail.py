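"""Discrete heavy-tailed model fitting and Vuong-style comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, special

import neurodegree as nd
from neurodegree.heavytail import PARAM_BOUNDS, upper_incomplete_gamma


class TestCcdf:
    def test_direct_count(self):
        cc = nd.ccdf([1, 1, 2, 3])
        assert dict(zip(cc["value"], cc["proportion"])) == {1: 1.0, 2: 0.5, 3: 0.25}

    def test_constant_sample(self):
        cc = nd.ccdf([4, 4, 4])
        assert len(cc) == 1 and cc["proportion"].iloc[0] == 1.0

    def test_matches_sort_and_count_oracle(self, rng):
        x = rng.integers(1, 50, size=500)
        cc = nd.ccdf(x)
        for v, p in zip(cc["value"], cc["proportion"]):
            assert p == pytest.approx(np.mean(x >= v))
        assert np.all(np.diff(cc["proportion"]) <= 0)
        assert cc["proportion"].iloc[0] == 1.0

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            nd.ccdf([])


class TestDiscretePmf:
    def test_weibull_beta1_is_geometric(self):
        """At shape 1 the Weibull reduces to an exponential law, whose
        discretization has constant ratio exp(lam) between consecutive
        masses."""
        lam = 0.3
        k = np.arange(1, 30)
        p = nd.discrete_pmf("weibull", {"beta": 1.0, "lam": lam}, k, 1)
        np.testing.assert_allclose(p[:-1] / p[1:], np.exp(lam), rtol=1e-10)

    @pytest.mark.parametrize("model,params", [
        ("powerlaw", {"alpha": 2.5}),
        ("truncated_powerlaw", {"alpha": 2.0, "lam": 0.1}),
        ("weibull", {"beta": 0.5, "lam": 0.1}),
    ])
    def test_normalization_with_analytic_tail(self, model, params):
        kcap = 3000
        k = np.arange(1, kcap + 1)
        total = nd.discrete_pmf(model, params, k, 1).sum()
        tail = nd.model_survival(model, params, np.array([kcap + 1]), 1)[0]
        assert total + tail == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.sampled_from(["powerlaw", "truncated_powerlaw", "weibull"]),
           st.floats(1.2, 4.0), st.floats(0.01, 1.0), st.integers(1, 4))
    def test_normalization_property_random_params(self, model, a, lam, xmin):
        params = ({"alpha": a} if model == "powerlaw"
                  else {"alpha": a, "lam": lam} if model == "truncated_powerlaw"
                  else {"beta": min(a / 2, 2.9), "lam": lam})
        k = np.arange(xmin, xmin + 5000)
        total = nd.discrete_pmf(model, params, k, xmin).sum()
        tail = nd.model_survival(model, params, np.array([xmin + 5000]), xmin)[0]
        assert total + tail == pytest.approx(1.0, abs=1e-6)

    def test_truncated_powerlaw_matches_quadrature(self):
        alpha, lam = 2.0, 0.1
        dens = lambda t: t**-alpha * np.exp(-lam * t)
        norm = integrate.quad(dens, 0.5, np.inf)[0]
        k = np.arange(1, 51)
        p = nd.discrete_pmf("truncated_powerlaw", {"alpha": alpha, "lam": lam}, k, 1)
        q = [integrate.quad(dens, kk - 0.5, kk + 0.5)[0] / norm for kk in k]
        np.testing.assert_allclose(p, q, atol=1e-12)

    def test_upper_incomplete_gamma_negative_order(self):
        for a in (-0.5, -1.0, -2.3, -4.0, 0.7):
            for x in (0.05, 0.5, 2.0, 20.0):
                num = integrate.quad(lambda t, a=a: t ** (a - 1) * math.exp(-t),
                                     x, np.inf)[0]
                assert upper_incomplete_gamma(a, np.array([x]))[0] == pytest.approx(
                    num, rel=1e-8)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            nd.discrete_pmf("powerlaw", {"alpha": 0.9}, np.array([1]), 1)
        with pytest.raises(ValueError):
            nd.discrete_pmf("weibull", {"beta": -1, "lam": 0.1}, np.array([1]), 1)
        with pytest.raises(ValueError):
            nd.discrete_pmf("nope", {}, np.array([1]), 1)


class TestPowerlawFit:
    def test_all_ones_closed_form(self):
        x = np.ones(25, dtype=int)
        assert nd.powerlaw_alpha_closed_form(x, 1) == pytest.approx(
            1 + 1 / math.log(2), abs=1e-12)

    def test_hand_evaluated_formula(self):
        x = np.array([1, 2, 4, 8])
        expect = 1 + 4 / sum(math.log(v / 0.5) for v in x)
        assert nd.powerlaw_alpha_closed_form(x, 1) == pytest.approx(expect, abs=1e-12)

    def test_exact_mle_recovers_alpha_at_xmin1(self):
        x = nd.sample_discrete_powerlaw(2.5, 10_000, xmin=1, seed=0)
        fr = nd.fit_discrete_mle(x, "powerlaw")
        assert fr.params["alpha"] == pytest.approx(2.5, abs=0.1)

    def test_closed_form_matches_exact_mle_at_large_xmin(self):
        """The printed approximation agrees with the exact zeta MLE once
        xmin is not tiny (here xmin=20)."""
        x = nd.sample_discrete_powerlaw(2.5, 10_000, xmin=20, seed=1)
        fr = nd.fit_powerlaw_discrete(x, xmin=20)
        assert fr.params["alpha"] == pytest.approx(fr.extras["alpha_exact"], abs=0.01)

    def test_below_xmin_rejected(self):
        with pytest.raises(ValueError):
            nd.fit_powerlaw_discrete(np.array([1, 2, 3]), xmin=2)


class TestXminSelection:
    def test_pure_powerlaw_selects_small_xmin(self):
        hits = 0
        for seed in range(20):
            x = nd.sample_discrete_powerlaw(2.5, 2000, xmin=1, seed=seed)
            xmin, _ = nd.select_xmin_ks(x)
            hits += xmin <= 3
        assert hits >= 18

    def test_equals_exhaustive_scan(self, rng):
        x = rng.integers(1, 40, size=300)
        xmin, ks = nd.select_xmin_ks(x)
        best = None
        for cand in np.unique(x)[:-1]:
            tail = x[x >= cand]
            a = nd.powerlaw_alpha_exact(tail, int(cand))
            d = nd.heavytail.ks_distance(tail, "powerlaw", {"alpha": a}, int(cand))
            if best is None or d < best[1] - 1e-15:
                best = (int(cand), d)
        assert (xmin, ks) == pytest.approx(best)

    def test_candidates_start_at_observed_minimum(self):
        x = np.arange(5, 40)
        xmin, _ = nd.select_xmin_ks(x)
        assert xmin >= 5

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            nd.select_xmin_ks(np.ones(20, dtype=int))


class TestDiscreteMle:
    def test_weibull_recovery_at_exponential_boundary(self):
        """Data with shape 1 (an exponential law) is recovered with the
        shape estimate inside [0.9, 1.1]."""
        x = nd.sample_discrete_weibull(1.0, 0.2, 10_000, seed=2)
        fr = nd.fit_discrete_mle(x, "weibull")
        assert 0.9 <= fr.params["beta"] <= 1.1

    @pytest.mark.parametrize("model,params,sampler", [
        ("weibull", {"beta": 0.5, "lam": 0.1},
         lambda s: nd.sample_discrete_weibull(0.5, 0.1, 4000, seed=s)),
        ("truncated_powerlaw", {"alpha": 2.0, "lam": 0.1},
         lambda s: nd.sample_discrete_truncated_powerlaw(2.0, 0.1, 4000, seed=s)),
    ])
    def test_optimum_beats_parameter_grid(self, model, params, sampler):
        """The optimizer's loglikelihood is never beaten by a 50x50 grid
        over the parameter box (by more than 1e-3)."""
        names = tuple(params)
        for seed in (0, 1):
            x = sampler(seed)
            fr = nd.fit_discrete_mle(x, model)
            (lo1, hi1), (lo2, hi2) = (PARAM_BOUNDS[model][n] for n in names)
            g1 = np.linspace(max(lo1, 0.05), min(hi1, 3.0), 50)
            g2 = np.geomspace(max(lo2, 1e-4), min(hi2, 2.0), 50)
            best = max(nd.loglikelihood(x, model, dict(zip(names, (a, b))))
                       for a in g1 for b in g2)
            assert fr.loglik >= best - 1e-3

    def test_weibull_parameter_recovery(self):
        errs_b, errs_l = [], []
        for seed in range(5):
            x = nd.sample_discrete_weibull(0.5, 0.1, 10_000, seed=seed)
            fr = nd.fit_discrete_mle(x, "weibull")
            errs_b.append(abs(fr.params["beta"] - 0.5))
            errs_l.append(abs(fr.params["lam"] - 0.1))
        assert np.mean(errs_b) < 0.05 and np.mean(errs_l) < 0.03

    def test_rejects_data_below_xmin(self):
        with pytest.raises(ValueError):
            nd.fit_discrete_mle(np.array([0, 1, 2]), "weibull")


class TestCompareModels:
    def test_self_comparison_is_degenerate(self):
        x = nd.sample_discrete_weibull(0.5, 0.1, 500, seed=0)
        fr = nd.fit_discrete_mle(x, "weibull")
        c = nd.compare_models(x, fr, fr)
        assert c.R == 0.0 and c.p == 1.0 and c.degenerate

    def test_antisymmetry(self):
        x = nd.sample_discrete_weibull(0.5, 0.1, 2000, seed=1)
        fa = nd.fit_discrete_mle(x, "weibull")
        fb = nd.fit_discrete_mle(x, "powerlaw")
        cab = nd.compare_models(x, fa, fb)
        cba = nd.compare_models(x, fb, fa)
        assert cab.R == pytest.approx(-cba.R, rel=1e-12)
        assert cab.p == pytest.approx(cba.p, rel=1e-12)
        assert 0.0 <= cab.p <= 1.0

    def test_true_model_never_significantly_beaten(self):
        """Consistency: the generating model is not significantly rejected
        in favor of a rival, and wins outright against non-nested rivals.
        (The power-law / truncated-power-law pair is nested at lam->0, so
        on power-law data that comparison is degenerate by construction and
        its p stays large.)"""
        for seed in range(5):
            x = nd.sample_discrete_weibull(0.5, 0.1, 5000, seed=seed)
            fw = nd.fit_discrete_mle(x, "weibull")
            for rival in ("powerlaw", "truncated_powerlaw"):
                c = nd.compare_models(x, fw, nd.fit_discrete_mle(x, rival))
                assert c.R > 0 and c.p < 0.05
        for seed in range(5):
            x = nd.sample_discrete_powerlaw(2.5, 5000, seed=seed)
            fl = nd.fit_discrete_mle(x, "powerlaw")
            for rival in ("weibull", "truncated_powerlaw"):
                c = nd.compare_models(x, fl, nd.fit_discrete_mle(x, rival))
                assert not (c.R < 0 and c.p < 0.05)
        for seed in range(5):
            x = nd.sample_discrete_truncated_powerlaw(2.0, 0.1, 5000, seed=seed)
            ft = nd.fit_discrete_mle(x, "truncated_powerlaw")
            c = nd.compare_models(x, ft, nd.fit_discrete_mle(x, "powerlaw"))
            assert c.R > 0 and c.p < 0.05
            c = nd.compare_models(x, ft, nd.fit_discrete_mle(x, "weibull"))
            assert not (c.R < 0 and c.p < 0.05)

    def test_weibull_ccdf_lies_between_powerlaw_and_exponential(self):
        """A Weibull with shape in (0,1) interpolates: at large degree its
        CCDF sits above the matched-mean exponential and below the
        matched-mean power law."""
        beta, lam = 0.5, 0.1
        ks = np.arange(1, 30001)
        pmf = nd.discrete_pmf("weibull", {"beta": beta, "lam": lam}, ks, 1)
        mean = float((ks * pmf).sum())
        lam_e = -math.log(1 - 1 / mean)  # geometric-law mean matching
        alpha = optimize.brentq(
            lambda a: special.zeta(a - 1) / special.zeta(a) - mean, 2.0001, 3.5)
        # the three curves cross below ~2e4; "large k" is beyond that
        kk = np.array([20_000, 40_000, 80_000])
        s_w = nd.model_survival("weibull", {"beta": beta, "lam": lam}, kk, 1)
        s_e = nd.model_survival("weibull", {"beta": 1.0, "lam": lam_e}, kk, 1)
        s_p = nd.model_survival("powerlaw", {"alpha": alpha}, kk, 1)
        assert np.all(s_e <= s_w) and np.all(s_w <= s_p)

    def test_mismatched_xmin_rejected(self):
        x = nd.sample_discrete_weibull(0.5, 0.1, 100, xmin=2, seed=0)
        fa = nd.fit_discrete_mle(x, "weibull", xmin=2)
        fb = nd.fit_discrete_mle(x, "weibull", xmin=1)
        with pytest.raises(ValueError):
            nd.compare_models(x, fa, fb)


class TestFitAllSubjects:
    def test_single_significant_subject_defines_group_mean(self):
        import pandas as pd
        comps = pd.DataFrame([{"subject": "s1", "network": "V", "model_a": "weibull",
                               "model_b": "powerlaw", "R": 2.0, "sigma": 1.0,
                               "p": 0.01, "n": 100}])
        out = nd.group_mean_R(comps)
        assert out["mean_R"].iloc[0] == 2.0 and out["n_significant"].iloc[0] == 1

    def test_no_significant_subjects_reported_missing(self):
        import pandas as pd
        comps = pd.DataFrame([{"subject": s, "network": "V", "model_a": "weibull",
                               "model_b": "powerlaw", "R": 0.5, "sigma": 1.0,
                               "p": 0.5, "n": 100} for s in ("a", "b")])
        out = nd.group_mean_R(comps)
        assert np.isnan(out["mean_R"].iloc[0]) and out["n_significant"].iloc[0] == 0

    def test_mixed_cohort_equals_filter_then_average(self, small_cohort):
        rec, payload, _ = small_cohort
        seqs = {sid: {"whole_brain": payload[sid]["whole_brain"]}
                for sid in rec["subject_id"][:6]}
        fits, comps = nd.fit_all_subjects(seqs)
        out = nd.group_mean_R(comps)
        for _, row in out.iterrows():
            sel = comps[(comps["model_a"] == row["model_a"])
                        & (comps["model_b"] == row["model_b"])
                        & (comps["p"] < 0.05)]
            if len(sel):
                assert row["mean_R"] == pytest.approx(sel["R"].mean())
            else:
                assert np.isnan(row["mean_R"])
        # every subject/network fitted with all three models
        assert len(fits) == 6 * 3
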
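"""Posterior summaries, pooling, ML confirmation and strain-mean
statistics of the choice model."""

import numpy as np
import pandas as pd
import pytest

import matechoice as mc
from matechoice.choice_model import R_PAIRS
from conftest import make_competitive_vials


def binary_table(successes, strains=None, context="V+C+", color="black"):
    n = len(successes)
    if strains is None:
        strains = [f"s{(i % 2) + 1:02d}" for i in range(n)]
    return pd.DataFrame(
        {
            "block": "b1",
            "context": context,
            "male_strain": strains,
            "female_strain": "",
            "color": color,
            "success": np.asarray(successes, dtype=int),
            "source_vial": [f"v{i}" for i in range(n)],
        }
    )


@pytest.fixture(scope="module")
def small_fit(small_study):
    """One short but converged-enough fit of the joint model."""
    nc = mc.binarize_latency(small_study.noncompetitive)
    comp = mc.resample_competitive(
        mc.mated_competitive(small_study.competitive), seed=1
    )
    data = mc.combine_contexts(nc, comp)
    spec = mc.ChoiceModelSpec(chains=2, iterations=1000, thin=4, seed=2)
    with pytest.warns(RuntimeWarning):
        # tiny per-strain samples make some separation warnings expected
        return mc.fit_choice_model(data, spec)
    return mc.fit_choice_model(data, spec)


class TestModeHdci:
    def test_constant_sample(self):
        s = mc.mode_hdci(np.full(500, 2.5))
        assert (s.mode, s.lower, s.upper) == (2.5, 2.5, 2.5)

    def test_standard_normal_closed_form(self):
        # true mode 0 and 95% HDI (-1.96, 1.96); HDI endpoints from sorted
        # draws are precise at n = 1e6, the KDE mode carries ~0.017 MC SD
        x = np.random.default_rng(42).normal(size=1_000_000)
        s = mc.mode_hdci(x)
        assert abs(s.mode) < 0.05
        assert s.lower == pytest.approx(-1.96, abs=0.02)
        assert s.upper == pytest.approx(1.96, abs=0.02)

    def test_right_skewed_mode_below_mean(self):
        x = np.exp(np.random.default_rng(3).normal(size=20_000))
        s = mc.mode_hdci(x)
        assert s.mode < x.mean()

    def test_nonnegative_reflection_keeps_boundary_mode(self):
        # half-normal: true mode is exactly 0
        x = np.abs(np.random.default_rng(4).normal(size=50_000))
        s = mc.mode_hdci(x, nonnegative=True)
        assert s.mode == pytest.approx(0.0, abs=0.02)

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            mc.mode_hdci(np.ones(200), mass=1.2)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100 draws"):
            mc.mode_hdci(np.arange(50.0))

    def test_hdci_is_shortest_mass_window(self):
        x = np.random.default_rng(5).exponential(size=10_000)
        s = mc.mode_hdci(x, mass=0.9)
        assert s.lower == pytest.approx(0.0, abs=0.01)  # HDI hugs zero
        inside = (x >= s.lower) & (x <= s.upper)
        assert inside.mean() >= 0.9


class TestCorrelationTest:
    @pytest.mark.parametrize(
        "lower,upper,expected",
        [(0.17, 0.99, True), (-0.63, 0.93, False), (0.0, 0.5, False)],
    )
    def test_interval_versus_zero(self, lower, upper, expected):
        s = mc.SummaryRow("cor", 0.5, lower, upper)
        assert mc.test_correlation_vs_zero(s) is expected


class TestStrainMeans:
    def test_identical_tables_correlate_perfectly(self):
        t = binary_table([1, 0, 1, 0, 0, 1, 1, 0, 0, 0, 1, 1],
                         strains=list("AABBCCAABBCC"))
        assert mc.strain_mean_correlation(t, t) == pytest.approx(1.0)

    def test_reversed_ranks_correlate_negatively(self):
        a = binary_table([1, 1, 1, 0, 0, 0], strains=list("AABBCC"))
        b = binary_table([0, 0, 1, 0, 1, 1], strains=list("AABBCC"))
        # strain means a: (1, .5, 0); b: (0, .5, 1) -- exact reversal
        assert mc.strain_mean_correlation(a, b) == pytest.approx(-1.0)

    def test_null_correlation_rarely_large(self):
        # 20 strains: |r| < 0.45 in ~95% of independent null replicates
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            strains = np.repeat([f"s{i:02d}" for i in range(20)], 10)
            a = binary_table(rng.integers(0, 2, 200), strains=list(strains))
            b = binary_table(rng.integers(0, 2, 200), strains=list(strains))
            if abs(mc.strain_mean_correlation(a, b)) < 0.45:
                hits += 1
        assert hits / n_rep > 0.90


class TestJackknife:
    def test_constant_strain_means(self):
        succ = [1, 0] * 10
        t = binary_table(succ, strains=list(np.repeat(list("ABCDE"), 4)))
        cov, se = mc.jackknife_strain_covariance(t, t.copy())
        assert cov == pytest.approx(0.0)
        assert se == pytest.approx(0.0)

    def test_two_strain_toy_matches_hand_computation(self):
        # strain means (0.2, 0.8) vs (0.3, 0.7):
        # cov = ((0.2-0.5)(0.3-0.5) + (0.8-0.5)(0.7-0.5)) / (2-1) = 0.12
        a = binary_table([1, 0, 0, 0, 0] + [1, 1, 1, 1, 0],
                         strains=["A"] * 5 + ["B"] * 5)
        b = binary_table(
            [1, 1, 1, 0, 0, 0, 0, 0, 0, 0] + [1, 1, 1, 1, 1, 1, 1, 0, 0, 0],
            strains=["A"] * 10 + ["B"] * 10,
        )
        cov, se = mc.jackknife_strain_covariance(a, b)
        assert cov == pytest.approx(0.12)
        assert np.isnan(se)  # SE undefined below 3 strains

    def test_se_close_to_bootstrap(self):
        # resampling cross-check on a 20-strain simulated table
        rng = np.random.default_rng(8)
        pa = rng.beta(2, 4, 20)
        pb = np.clip(pa + rng.normal(0, 0.08, 20), 0.01, 0.99)
        strains = [f"s{i:02d}" for i in range(20)]
        a = binary_table(
            (rng.random((20, 50)) < pa[:, None]).ravel().astype(int),
            strains=list(np.repeat(strains, 50)),
        )
        b = binary_table(
            (rng.random((20, 50)) < pb[:, None]).ravel().astype(int),
            strains=list(np.repeat(strains, 50)),
        )
        cov, se = mc.jackknife_strain_covariance(a, b)
        ma = a.groupby("male_strain")["success"].mean().to_numpy()
        mb = b.groupby("male_strain")["success"].mean().to_numpy()
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, 20, 20)
            boots.append(np.cov(ma[idx], mb[idx], ddof=1)[0, 1])
        boot_se = np.std(boots, ddof=1)
        assert se == pytest.approx(boot_se, rel=0.25)


class TestLrt:
    def test_boundary_zero_statistic(self):
        stat, df, p = mc.lrt_random_effect(-100.0, -100.0)
        assert (stat, df, p) == (0.0, 1, 1.0)

    def test_negative_difference_clamped(self):
        stat, _, p = mc.lrt_random_effect(-101.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_upper_tail(self):
        # chi2(1) upper tail at 7.76 is 0.0053
        stat, df, p = mc.lrt_random_effect(-96.12, -100.0)
        assert stat == pytest.approx(7.76)
        assert p == pytest.approx(0.0053, abs=0.0001)


class TestFitChoiceModel:
    def test_rejects_single_strain_context(self):
        t = binary_table([0, 1, 0, 1], strains=["A"] * 4)
        with pytest.raises(ValueError, match="single male strain"):
            mc.fit_choice_model(t, mc.ChoiceModelSpec(chains=1, iterations=50))

    def test_rejects_nonbinary_response(self):
        t = binary_table([0, 1, 2, 1])
        with pytest.raises(ValueError, match="binary"):
            mc.fit_choice_model(t, mc.ChoiceModelSpec(chains=1, iterations=50))

    def test_draw_bookkeeping_and_determinism(self):
        t = binary_table(np.random.default_rng(1).integers(0, 2, 60))
        spec = mc.ChoiceModelSpec(chains=3, iterations=200, thin=4, seed=9)
        fit = mc.fit_choice_model(t, spec)
        assert len(fit.draws) == spec.retained_draws == 3 * 25
        fit2 = mc.fit_choice_model(t, spec)
        pd.testing.assert_frame_equal(fit.draws, fit2.draws)

    def test_retained_correlation_draws_positive_definite(self, small_fit):
        cols = [f"cor[{mc.CONTEXTS[i]},{mc.CONTEXTS[j]}]" for i, j in R_PAIRS]
        rv = small_fit.draws[cols].to_numpy()
        R = np.tile(np.eye(4), (len(rv), 1, 1))
        for e, (i, j) in enumerate(R_PAIRS):
            R[:, i, j] = rv[:, e]
            R[:, j, i] = rv[:, e]
        evs = np.linalg.eigvalsh(R)
        assert evs.min() > 0.0

    def test_sd_draws_nonnegative(self, small_fit):
        for k in mc.CONTEXTS:
            assert (small_fit.draws[f"sd[{k}]"] > 0).all()

    def test_summarize_refuses_unconverged(self, small_fit):
        bad = small_fit.rhat.copy()
        bad.iloc[0] = 1.5
        unconverged = mc.PosteriorDraws(
            draws=small_fit.draws, strains=small_fit.strains,
            rhat=bad, spec=small_fit.spec,
        )
        with pytest.raises(RuntimeError, match="R-hat"):
            unconverged.summarize()
        assert len(unconverged.summarize(force=True)) > 0

    def test_map_matches_ml_mode_at_scale(self):
        # Laplace-ML and Bayesian posterior mode agree asymptotically
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.8, 20)
        rows = []
        for i in range(20):
            p = 1 / (1 + np.exp(1.0 - a[i]))
            for y in rng.random(120) < p:
                rows.append((f"s{i:02d}", int(y)))
        d = binary_table(
            [y for _, y in rows], strains=[s for s, _ in rows]
        )
        ml = mc.ml_fit_context(d, "V+C+")
        fit = mc.fit_choice_model(
            d, mc.ChoiceModelSpec(chains=2, iterations=3000, thin=5, seed=2)
        )
        bayes_mode = mc.mode_hdci(
            fit.draws["sd[V+C+]"].to_numpy(), nonnegative=True
        ).mode
        assert bayes_mode == pytest.approx(ml.sigma["m_strain"], abs=0.15)


class TestModelInvariants:
    def test_context_label_equivariance(self, small_study):
        # swapping the two noncompetitive context labels in the data must
        # swap the corresponding SD posteriors (up to MC error)
        nc = mc.binarize_latency(small_study.noncompetitive)
        swapped = nc.copy()
        swapped["context"] = swapped["context"].map(
            {"V+C-": "V-C-", "V-C-": "V+C-"}
        )
        spec = mc.ChoiceModelSpec(chains=2, iterations=1500, thin=5, seed=4)
        f1 = mc.fit_choice_model(nc, spec)
        f2 = mc.fit_choice_model(swapped, spec)
        m1 = {
            k: mc.mode_hdci(f1.draws[f"sd[{k}]"].to_numpy(), nonnegative=True).mode
            for k in mc.NONCOMP_CONTEXTS
        }
        m2 = {
            k: mc.mode_hdci(f2.draws[f"sd[{k}]"].to_numpy(), nonnegative=True).mode
            for k in mc.NONCOMP_CONTEXTS
        }
        assert m1["V+C-"] == pytest.approx(m2["V-C-"], abs=0.12)
        assert m1["V-C-"] == pytest.approx(m2["V+C-"], abs=0.12)

    def test_pooled_noncompetitive_summaries_stable_in_resamples(
        self, small_study
    ):
        # resampling only touches competitive rows, so noncompetitive SD
        # summaries must not drift as more resamples are pooled
        nc = mc.binarize_latency(small_study.noncompetitive)
        mated = mc.mated_competitive(small_study.competitive)
        sets = mc.build_resample_sets(mated, 6, seed=3)
        spec = mc.ChoiceModelSpec(chains=2, iterations=1500, thin=5, seed=5)
        pooled2 = mc.fit_resampled(nc, sets[:2], spec)
        pooled6 = mc.fit_resampled(nc, sets, spec)
        for col in ("sd[V+C-]", "sd[V-C-]"):
            m2 = float(pooled2.draws[col].median())
            m6 = float(pooled6.draws[col].median())
            assert m6 == pytest.approx(m2, abs=0.1)


class TestPooling:
    def test_concatenation_count_and_provenance(self, small_fit):
        pooled = mc.pool_posteriors([small_fit] * 5)
        assert len(pooled.draws) == 5 * len(small_fit.draws)
        assert set(pooled.draws["resample"]) == {0}

    def test_pooling_copies_preserves_summaries(self, small_fit):
        # replicating the same draws must not move the summaries (the KDE
        # bandwidth shrinks slightly with the tripled draw count, so the
        # mode matches to a small tolerance rather than bit-exactly)
        pooled = mc.pool_posteriors([small_fit, small_fit, small_fit])
        a = small_fit.summarize(["sd[V+C-]"], force=True)
        b = pooled.summarize(["sd[V+C-]"], force=True)
        assert np.allclose(
            a[["mode", "lower", "upper"]], b[["mode", "lower", "upper"]],
            atol=0.02,
        )

    def test_pooling_order_invariant(self, small_fit):
        half = mc.PosteriorDraws(
            draws=small_fit.draws.iloc[: len(small_fit.draws) // 2].reset_index(
                drop=True
            ),
            strains=small_fit.strains,
            rhat=small_fit.rhat,
            spec=small_fit.spec,
        )
        p1 = mc.pool_posteriors([small_fit, half])
        p2 = mc.pool_posteriors([half, small_fit])
        s1 = p1.summarize(["cor[V+C-,V-C-]"], force=True)
        s2 = p2.summarize(["cor[V+C-,V-C-]"], force=True)
        pd.testing.assert_frame_equal(s1, s2)

    def test_mismatched_fits_rejected(self, small_fit):
        other = mc.PosteriorDraws(
            draws=small_fit.draws.rename(columns={"sd[V+C+]": "weird"}),
            strains=small_fit.strains,
            rhat=small_fit.rhat,
            spec=small_fit.spec,
        )
        with pytest.raises(ValueError, match="differing parameter"):
            mc.pool_posteriors([small_fit, other])


class TestMlFit:
    def test_null_variance_near_boundary(self):
        rng = np.random.default_rng(11)
        strains = list(np.repeat([f"s{i}" for i in range(10)], 80))
        d = binary_table(rng.integers(0, 2, 800), strains=strains)
        fit = mc.ml_fit_context(d, "V+C+")
        assert fit.sigma["m_strain"] < 0.15

    def test_strong_signal_recovered(self):
        # sigma = 1.5, 20 strains, 50 trials/strain: estimates land in a
        # simulation-derived band around the truth
        for rep in range(3):
            rng = np.random.default_rng(50 + rep)
            a = rng.normal(0, 1.5, 20)
            strains, ys = [], []
            for i in range(20):
                p = 1 / (1 + np.exp(1.0 - a[i]))
                strains += [f"s{i:02d}"] * 50
                ys += list((rng.random(50) < p).astype(int))
            d = binary_table(ys, strains=strains)
            fit = mc.ml_fit_context(d, "V+C+")
            assert 0.9 <= fit.sigma["m_strain"] <= 2.1

    def test_noncompetitive_context_gets_female_term(self, small_study):
        nc = mc.binarize_latency(small_study.noncompetitive)
        fit = mc.ml_fit_context(nc, "V+C-")
        assert set(fit.sigma) == {"m_strain", "f_strain"}
        red = mc.ml_fit_context(nc, "V+C-", random_terms=("f_strain",))
        assert red.loglik <= fit.loglik + 1e-6

    def test_unknown_context_or_term_rejected(self, small_study):
        nc = mc.binarize_latency(small_study.noncompetitive)
        with pytest.raises(ValueError, match="unknown context"):
            mc.ml_fit_context(nc, "X")
        with pytest.raises(ValueError, match="unknown random term"):
            mc.ml_fit_context(nc, "V+C-", random_terms=("vial",))
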
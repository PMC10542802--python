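"""Association suite: splines, Cox, Poisson LRT, PR, Fine-Gray, meta, FDR."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from hetburden.assoc import (
    EffectEstimate,
    build_design,
    cause_specific_events,
    fdr_adjust,
    fit_cox,
    fit_poisson_interaction,
    fit_subdistribution,
    marginal_prevalence_ratio,
    meta_inverse_variance,
    random_heteroplasmy_pick,
    rcs_basis,
)


class TestRcsBasis:
    def test_column_count_equals_df(self):
        x = np.random.default_rng(0).uniform(40, 70, 500)
        for df in (3, 4, 5):
            assert rcs_basis(x, df=df).shape[1] == df

    def test_linear_function_is_in_the_span(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 400)
        basis = rcs_basis(x, df=4).to_numpy()
        X = np.column_stack([np.ones(len(x)), basis])
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        assert np.allclose(X @ beta, x, atol=1e-8)

    def test_linear_beyond_boundary_knots(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 2000)
        basis = rcs_basis(x, df=4)
        knots = basis.attrs["knots"]
        # numerical second derivative of each basis column outside the
        # boundary knots must vanish
        grid = np.concatenate([
            np.linspace(x.min() - 5, knots[0] - 0.2, 30),
            np.linspace(knots[-1] + 0.2, x.max() + 5, 30),
        ])
        gb = rcs_basis(grid, df=4, knots=knots).to_numpy()
        h = grid[1] - grid[0]
        for j in range(gb.shape[1]):
            col = gb[:30, j]
            second = np.diff(col, 2)
            assert np.abs(second).max() < 1e-6 * (1 + np.abs(col).max())

    def test_too_few_distinct_values_is_an_error(self):
        with pytest.raises(ValueError, match="age"):
            rcs_basis(np.array([1.0, 1.0, 1.0, 2.0]), df=4, name="age")


def _exponential_cohort(rng, n, loghr, p_exposed=0.5, censor=None):
    x = (rng.random(n) < p_exposed).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(loghr * x)))
    if censor is None:
        time, event = t, np.ones(n, dtype=int)
    else:
        time = np.minimum(t, censor)
        event = (t <= censor).astype(int)
    return pd.DataFrame({"x": x, "followup_time": time, "event": event})


class TestFitCox:
    def test_matches_closed_form_rate_ratio_without_censoring(self):
        """Two-group exponential data, no censoring: the partial-likelihood
        estimate approaches the events/person-time rate ratio."""
        rng = np.random.default_rng(3)
        df = _exponential_cohort(rng, 4000, np.log(2.0))
        est, _ = fit_cox(df, "x")
        g1 = df[df.x == 1]
        g0 = df[df.x == 0]
        rate_ratio = (len(g1) / g1.followup_time.sum()) / (
            len(g0) / g0.followup_time.sum()
        )
        assert abs(np.log(est["x"].estimate) - np.log(rate_ratio)) < 0.1
        assert abs(np.log(est["x"].estimate) - np.log(2.0)) < 3 * est["x"].se_log

    def test_null_exposure_ci_covers_one(self):
        rng = np.random.default_rng(4)
        covered = 0
        reps = 200
        for _ in range(reps):
            df = _exponential_cohort(rng, 250, 0.0, censor=6.0)
            est, _ = fit_cox(df, "x")
            if est["x"].ci_low <= 1.0 <= est["x"].ci_high:
                covered += 1
        # binomial 3-sigma band around nominal 95% coverage
        assert abs(covered / reps - 0.95) < 3 * np.sqrt(0.95 * 0.05 / reps)

    def test_strata_give_separate_baselines(self):
        rng = np.random.default_rng(5)
        n = 3000
        stratum = rng.integers(2, size=n)
        x = rng.normal(size=n)
        base = np.where(stratum == 1, 0.5, 0.05)  # very different baselines
        t = rng.exponential(1.0 / (base * np.exp(0.4 * x)))
        df = pd.DataFrame({"x": x, "followup_time": t,
                           "event": 1, "center": stratum})
        est, _ = fit_cox(df, "x", strata="center")
        assert abs(np.log(est["x"].estimate) - 0.4) < 3 * est["x"].se_log

    def test_late_entry_is_honoured(self):
        rng = np.random.default_rng(6)
        df = _exponential_cohort(rng, 1500, np.log(1.5))
        df["entry"] = df["followup_time"] * rng.uniform(0, 0.5, len(df))
        est, _ = fit_cox(df, "x", entry_col="entry")
        assert abs(np.log(est["x"].estimate) - np.log(1.5)) < 3 * est["x"].se_log

    def test_nonpositive_time_without_entry_is_an_error(self):
        df = pd.DataFrame({"x": [0.0, 1.0], "followup_time": [0.0, 1.0],
                           "event": [1, 1]})
        with pytest.raises(ValueError):
            fit_cox(df, "x")

    def test_cause_specific_event_conservation(self, sim_bundle):
        cohort = sim_bundle["cohort"]
        causes = [c for c in cohort["cause"].unique() if c]
        total = sum(cause_specific_events(cohort, c).sum() for c in causes)
        assert total == cohort["event"].sum()
        assert total + (cohort["event"] == 0).sum() == len(cohort)


class TestPoissonInteraction:
    @staticmethod
    def _cohort(rng, n, interaction):
        age = rng.uniform(40, 69, n)
        smoking = rng.choice(["never", "former", "current"], n, p=[.5, .3, .2])
        mu = np.exp(-1.0 + 0.02 * (age - 55) + 0.1 * (smoking == "current")
                    + interaction * (age - 55) * (smoking == "current"))
        return pd.DataFrame({
            "heteroplasmy_count": rng.poisson(mu), "age": age, "smoking": smoking,
        })

    def test_null_interaction_type_one_error(self):
        rng = np.random.default_rng(7)
        reps, alpha, rejections = 200, 0.05, 0
        for _ in range(reps):
            df = self._cohort(rng, 400, 0.0)
            *_, p = fit_poisson_interaction(df)
            rejections += p < alpha
        rate = rejections / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_power_against_a_current_smoker_age_slope(self):
        rng = np.random.default_rng(8)
        reps, rejections = 40, 0
        for _ in range(reps):
            df = self._cohort(rng, 4000, 0.05)
            *_, p = fit_poisson_interaction(df)
            rejections += p < 0.05
        assert rejections / reps > 0.8

    def test_degenerate_smoking_category_flagged(self):
        rng = np.random.default_rng(9)
        df = self._cohort(rng, 200, 0.0)
        df["smoking"] = "never"
        with pytest.raises(ValueError, match="smoking"):
            fit_poisson_interaction(df)


class TestMarginalPrevalenceRatio:
    def test_exposure_only_model_reduces_to_model_curve(self):
        rng = np.random.default_rng(10)
        n = 2000
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.5 * x)))).astype(int)
        df = pd.DataFrame({"mss": x, "disease": y})
        est = marginal_prevalence_ratio(df, "disease", "mss")
        import statsmodels.api as sm

        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        p1 = fit.predict(sm.add_constant(x + 1)).mean()
        p0 = fit.predict(sm.add_constant(x)).mean()
        assert est.estimate == pytest.approx(p1 / p0, rel=1e-10)

    def test_zero_coefficient_gives_pr_exactly_one(self):
        # perfectly balanced 2x2 data force the exposure coefficient to 0
        df = pd.DataFrame({
            "mss": [0, 0, 1, 1] * 10,
            "disease": [0, 1, 0, 1] * 10,
        })
        est = marginal_prevalence_ratio(df, "disease", "mss")
        assert est.estimate == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_prevalence_is_an_error(self):
        df = pd.DataFrame({"mss": [0.1, 0.2], "disease": [1, 1]})
        with pytest.raises(ValueError):
            marginal_prevalence_ratio(df, "disease", "mss")


class TestFineGray:
    def test_equals_cox_without_competing_events(self):
        rng = np.random.default_rng(11)
        df = _exponential_cohort(rng, 600, np.log(1.8), censor=5.0)
        df["event_type"] = df["event"]
        cox, _ = fit_cox(df, "x")
        fg, _ = fit_subdistribution(df, "x")
        assert np.isclose(np.log(fg["x"].estimate), np.log(cox["x"].estimate),
                          rtol=1e-6, atol=1e-8)

    def test_exposure_on_competing_cause_pushes_subhazard_below_one(self):
        """If the exposure only accelerates the competing cause, the
        event-of-interest subdistribution hazard ratio must fall below 1
        (fewer subjects remain able to experience the event)."""
        rng = np.random.default_rng(12)
        n = 4000
        x = (rng.random(n) < 0.5).astype(float)
        t1 = rng.exponential(1.0 / 0.05, n)                   # interest
        t2 = rng.exponential(1.0 / (0.10 * np.exp(1.5 * x)))  # competing
        t = np.minimum(t1, t2)
        etype = np.where(t1 <= t2, 1, 2)
        cens = 8.0
        df = pd.DataFrame({
            "x": x,
            "followup_time": np.minimum(t, cens),
            "event_type": np.where(t <= cens, etype, 0),
        })
        fg, _ = fit_subdistribution(df, "x")
        assert fg["x"].ci_high < 1.0

    def test_recovers_known_subdistribution_effect(self):
        """Data drawn from the subdistribution model itself (unit
        exponential subdistribution, known coefficient) are recovered."""
        rng = np.random.default_rng(13)
        beta, p_mix = 0.5, 0.35
        logs, ses = [], []
        for _ in range(10):
            n = 1200
            x = (rng.random(n) < 0.5).astype(float)
            # P(cause 1) under the Fine-Gray mixture model
            p1 = 1 - (1 - p_mix) ** np.exp(beta * x)
            is1 = rng.random(n) < p1
            u = rng.random(n)
            # inverse-CIF sampling: F1(t|x) = 1-(1-p(1-e^{-t}))^{exp(bx)}
            eb = np.exp(beta * x)
            t1 = -np.log(1 - (1 - (1 - u * p1) ** (1 / eb)) / p_mix)
            t2 = rng.exponential(1.0, n)
            time = np.where(is1, t1, t2)
            cens = rng.uniform(1.0, 6.0, n)
            df = pd.DataFrame({
                "x": x,
                "followup_time": np.minimum(time, cens),
                "event_type": np.where(time <= cens, np.where(is1, 1, 2), 0),
            })
            fg, _ = fit_subdistribution(df, "x")
            logs.append(np.log(fg["x"].estimate))
            ses.append(fg["x"].se_log)
        mc_se = np.std(logs, ddof=1) / np.sqrt(len(logs))
        assert abs(np.mean(logs) - beta) < 2.5 * mc_se + 0.02

    def test_agrees_with_external_crr_routine(self, tmp_path):
        """Cross-check the IPCW fit against the reference competing-risks
        regression implementation (cmprsk::crr) on one dataset."""
        rng = np.random.default_rng(14)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.2 * np.exp(0.4 * x)))
        etype = np.where(rng.random(n) < 0.7, 1, 2)
        cens = rng.uniform(0.5, 6.0, n)
        df = pd.DataFrame({
            "x": x,
            "followup_time": np.minimum(t, cens),
            "event_type": np.where(t <= cens, etype, 0),
        })
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(cmprsk))
            d <- read.csv("{csv}")
            f <- crr(d$followup_time, d$event_type, d$x, failcode=1, cencode=0)
            cat(f$coef)
        """)
        out = subprocess.run(["Rscript", "-e", rscript],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        r_coef = float(out.stdout.strip().split()[-1])
        fg, _ = fit_subdistribution(df, "x")
        assert abs(np.log(fg["x"].estimate) - r_coef) < 0.05


class TestMetaAndFdr:
    @staticmethod
    def _est(hr, se, term="t"):
        z = np.log(hr) / se
        from scipy.stats import norm

        return EffectEstimate(
            term, hr, float(np.exp(np.log(hr) - 1.96 * se)),
            float(np.exp(np.log(hr) + 1.96 * se)), se,
            float(2 * norm.sf(abs(z))), 100, 10,
        )

    def test_single_study_is_identity(self):
        e = self._est(1.3, 0.1)
        pooled = meta_inverse_variance([e]).pooled
        assert pooled.estimate == pytest.approx(1.3)
        assert pooled.se_log == pytest.approx(0.1)

    def test_two_identical_studies_halve_the_variance(self):
        e = self._est(1.5, 0.2)
        pooled = meta_inverse_variance([e, e]).pooled
        assert pooled.estimate == pytest.approx(1.5)
        assert pooled.se_log == pytest.approx(0.2 / np.sqrt(2))

    def test_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            hrs = rng.uniform(0.5, 3.0, 4)
            ses = rng.uniform(0.05, 0.5, 4)
            ests = [self._est(h, s) for h, s in zip(hrs, ses)]
            res = meta_inverse_variance(ests)
            w = 1 / ses**2
            want = np.sum(w * np.log(hrs)) / np.sum(w)
            assert np.isclose(np.log(res.pooled.estimate), want)
            assert np.isclose(res.pooled.se_log, np.sqrt(1 / np.sum(w)))

    def test_random_effects_widen_under_heterogeneity(self):
        ests = [self._est(0.8, 0.05), self._est(2.5, 0.05)]
        fixed = meta_inverse_variance(ests)
        random = meta_inverse_variance(ests, random_effects=True)
        assert random.pooled.se_log > fixed.pooled.se_log
        assert random.tau_squared > 0

    def test_degenerate_se_rejected(self):
        bad = EffectEstimate("t", 1.0, 1.0, 1.0, 0.0, 1.0, 10, 1)
        with pytest.raises(ValueError):
            meta_inverse_variance([bad])

    def test_fdr_examples_and_oracle(self):
        assert np.allclose(fdr_adjust([0.02, 0.02, 0.02]), 0.02)
        assert fdr_adjust([0.03]) == pytest.approx([0.03])
        rng = np.random.default_rng(16)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 25))
            got = fdr_adjust(p)
            # brute-force BH step-up
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            assert np.allclose(got, adj)

    def test_fdr_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestRandomPick:
    def test_single_call_and_determinism(self):
        calls = pd.DataFrame({
            "sample_id": ["a", "b", "b", "b"],
            "pos": [5, 1, 2, 3], "ref": "A", "alt": "G",
        })
        p1 = random_heteroplasmy_pick(calls, seed=42)
        p2 = random_heteroplasmy_pick(calls, seed=42)
        pd.testing.assert_frame_equal(p1, p2)
        assert p1[p1.sample_id == "a"]["pos"].item() == 5

    def test_selection_is_uniform(self):
        n = 6000
        calls = pd.DataFrame({
            "sample_id": np.repeat([f"s{i}" for i in range(n)], 3),
            "pos": np.tile([1, 2, 3], n), "ref": "A", "alt": "G",
        })
        picks = random_heteroplasmy_pick(calls, seed=0)
        counts = picks["pos"].value_counts().reindex([1, 2, 3]).to_numpy()
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 0.001
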
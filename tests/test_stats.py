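"""t-tests, Spearman correlation, mixed models, AIC comparison."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prosocontrast import simulate
from prosocontrast.boundary import classify_dataset, filter_tokens
from prosocontrast.errors import ComparisonError, SeparationError, UndefinedStatisticError
from prosocontrast.pipeline import _model_frame
from prosocontrast.stats import (
    ModelFit,
    compare_aic,
    fit_lmm_log,
    fit_mixed_logit,
    spearman,
    t_test_from_summary,
    t_test_raw,
)


def model_frame(config):
    dataset = simulate.generate_dataset(config)
    retained, _ = filter_tokens(dataset)
    return _model_frame(retained, classify_dataset(retained))


class TestTTests:
    def test_hinting_group_summaries(self):
        """Theory-of-mind summaries 14.9 +/- 2.1 vs 17.9 +/- 1.5 (n=10
        each) give t(18) ~= -3.68."""
        res = t_test_from_summary(14.9, 2.1, 10, 17.9, 1.5, 10)
        assert res.df == 18
        assert res.t == pytest.approx(-3.68, abs=0.01)
        assert res.p_value < 0.005

    def test_total_time_group_summaries(self):
        res = t_test_from_summary(169.10, 41.01, 10, 208.8, 63.46, 10)
        assert res.df == 18
        assert res.t == pytest.approx(-1.66, abs=0.01)

    def test_identical_summaries_give_zero(self):
        res = t_test_from_summary(5.0, 1.0, 8, 5.0, 1.0, 8)
        assert res.t == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            t_test_from_summary(5.0, 0.0, 8, 5.0, 0.0, 8)
        with pytest.raises(UndefinedStatisticError):
            t_test_raw([1.0], [2.0, 3.0])

    def test_raw_small_example(self):
        res = t_test_raw([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.224744871, abs=1e-8)
        assert res.df == 4

    def test_raw_identity_and_antisymmetry(self):
        x = [1.0, 2.5, 3.5, 4.0]
        assert t_test_raw(x, x).t == 0.0
        y = [2.0, 2.2, 5.1, 0.3]
        assert t_test_raw(x, y).t == pytest.approx(-t_test_raw(y, x).t)

    @given(
        x=st.lists(st.floats(-50, 50), min_size=2, max_size=20),
        y=st.lists(st.floats(-50, 50), min_size=2, max_size=20),
    )
    @settings(derandomize=True, max_examples=100)
    def test_raw_equals_summary(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        if (x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean()):
            return
        raw = t_test_raw(x, y)
        summ = t_test_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert raw.t == pytest.approx(summ.t, rel=1e-12, abs=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, rel=1e-12, abs=1e-12)


def naive_spearman(x, y):
    """Independent oracle: explicit average ranks + textbook Pearson."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            r[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return r

    rx, ry = ranks(x), ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 5], [2, 4, 9, 11])
        assert res.rho == pytest.approx(1.0)

    def test_tied_example(self):
        res = spearman([1, 2, 2, 4], [10, 20, 30, 40])
        assert res.rho == pytest.approx(0.9486832980505138)

    def test_antitone(self):
        res = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_permutation_p_for_monotone_small_n(self):
        res = spearman([1, 2, 3, 4, 5], [1, 3, 4, 7, 9], method="permutation")
        assert res.rho == pytest.approx(1.0)
        # exact enumeration: 2 of 120 permutations reach |rho| = 1
        assert res.p_value == pytest.approx(2 / 120)

    def test_oracle_agreement_randomized_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 25))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.all(x == x[0]):
                continue
            assert spearman(x, y).rho == pytest.approx(naive_spearman(x, y), abs=1e-12)


class TestMixedLogit:
    def test_matches_lme4_reference(self, tmp_path):
        """Laplace ML agrees with R lme4::glmer on one synthetic dataset
        (estimates, SEs, variance components, AIC)."""
        frame = model_frame(simulate.default_config(seed=42))
        fit = fit_mixed_logit(frame)
        data_path = tmp_path / "glmm.csv"
        frame[["outcome", "condition", "group", "participant_id", "item_id"]].to_csv(
            data_path, index=False
        )
        script = tmp_path / "ref.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{data_path}")\n'
            'd$condition <- relevel(factor(d$condition), ref="given")\n'
            'd$group <- relevel(factor(d$group), ref="HC")\n'
            'm <- glmer(outcome ~ condition*group + (1|participant_id) + (1|item_id),'
            ' data=d, family=binomial)\n'
            'co <- summary(m)$coefficients\n'
            'vc <- as.data.frame(VarCorr(m))\n'
            'cat(co[,1], co[,2], vc$vcov, AIC(m), sep="\\n")\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        values = [float(v) for v in proc.stdout.split()]
        ref_beta, ref_se, ref_vc, ref_aic = (
            values[0:4], values[4:8], values[8:10], values[10]
        )
        est = [fe.estimate for fe in fit.fixed_effects]
        se = [fe.std_error for fe in fit.fixed_effects]
        assert est == pytest.approx(ref_beta, abs=0.02)
        assert se == pytest.approx(ref_se, abs=0.02)
        assert fit.variance_components["participant"] == pytest.approx(ref_vc[0], abs=0.05)
        assert fit.variance_components["item"] == pytest.approx(ref_vc[1], abs=0.05)
        assert fit.aic == pytest.approx(ref_aic, abs=0.1)

    def test_wald_statistic_and_aic_invariants(self):
        fit = fit_mixed_logit(model_frame(simulate.default_config(seed=5)))
        for fe in fit.fixed_effects:
            assert fe.statistic == pytest.approx(fe.estimate / fe.std_error, rel=1e-9)
            assert 0.0 <= fe.p_value <= 1.0
        assert fit.aic == pytest.approx(
            -2.0 * fit.log_likelihood + 2.0 * fit.n_params, rel=1e-12
        )
        assert all(v >= 0 for v in fit.variance_components.values())

    def test_constant_outcome_is_separation_error(self):
        frame = model_frame(simulate.default_config(seed=5))
        frame["outcome"] = 1
        with pytest.raises(SeparationError):
            fit_mixed_logit(frame)

    def test_single_group_drops_group_terms(self):
        frame = model_frame(simulate.default_config(seed=5))
        fit = fit_mixed_logit(frame[frame["group"] == "HC"])
        assert [fe.name for fe in fit.fixed_effects] == [
            "(Intercept)",
            "condition[contrastive]",
        ]

    def test_null_model_calibration(self):
        """With all true effects 0 and no random variation, the condition
        effect's |z| stays below 1.96 in >= 90% of 50 seeded replicates."""
        null = simulate.TrueCoefficients(
            intercept=0.0, condition_effect=0.0, group_effect=0.0, interaction=0.0
        )
        rng = np.random.default_rng(77)
        calm = 0
        for seed in rng.integers(0, 2**31 - 1, size=50):
            config = simulate.default_config(
                true_coefficients=null,
                var_participant=0.0,
                var_item=0.0,
                dropout_prob=0.0,
                seed=int(seed),
            )
            fit = fit_mixed_logit(model_frame(config))
            z = abs(fit.effect("condition[contrastive]").statistic)
            calm += z < 1.96
        assert calm >= 45


def log_uniform_mean(lo, hi):
    """E[log U] for U ~ Uniform(lo, hi)."""
    return (hi * np.log(hi) - lo * np.log(lo)) / (hi - lo) - 1.0


class TestLmmLog:
    def test_duration_condition_effect_recovered(self):
        """The HC condition effect on log S2 duration equals (to 3 SE) the
        generator-implied truth: the marginal shift in P(TWO_AP) times the
        mean log-ratio gap between the two label regimes."""
        config = simulate.default_config(n_participants_per_group=40, seed=9)
        fit = fit_lmm_log(model_frame(config), "duration")
        coef = config.true_coefficients
        var_total = config.var_participant + config.var_item
        nodes, weights = np.polynomial.hermite_e.hermegauss(80)
        weights = weights / np.sqrt(2 * np.pi)

        def marginal_p(eta):
            return float(np.sum(weights / (1 + np.exp(-(eta + nodes * np.sqrt(var_total))))))

        rr = config.ratio_ranges
        delta_logratio = log_uniform_mean(*rr.two_ap_dur) - log_uniform_mean(*rr.one_ap_dur)
        truth = (
            marginal_p(coef.intercept + coef.condition_effect)
            - marginal_p(coef.intercept)
        ) * delta_logratio
        effect = fit.effect("condition[contrastive]")
        assert effect.estimate == pytest.approx(truth, abs=3 * effect.std_error)
        assert effect.statistic > 0

    def test_rescaling_response_shifts_only_intercept(self):
        frame = model_frame(simulate.default_config(seed=13))
        base = fit_lmm_log(frame, "duration")
        scaled = frame.copy()
        scaled["dur_s2"] = scaled["dur_s2"] * 3.7
        shifted = fit_lmm_log(scaled, "duration")
        assert shifted.effect("(Intercept)").estimate == pytest.approx(
            base.effect("(Intercept)").estimate + np.log(3.7), abs=1e-4
        )
        for name in [fe.name for fe in base.fixed_effects][1:]:
            assert shifted.effect(name).estimate == pytest.approx(
                base.effect(name).estimate, abs=1e-4
            )

    def test_null_calibration_f0(self):
        """No true effects and equal acoustic regimes: |t| of the condition
        effect below 2 in >= 90% of 50 seeded replicates."""
        null = simulate.TrueCoefficients(0.0, 0.0, 0.0, 0.0)
        # with null coefficients the label (and hence the f0 regime) is
        # independent of condition, so the condition effect is truly zero
        rng = np.random.default_rng(123)
        calm = 0
        for seed in rng.integers(0, 2**31 - 1, size=50):
            config = simulate.default_config(
                true_coefficients=null, var_participant=0.0, var_item=0.0,
                dropout_prob=0.0, seed=int(seed),
            )
            fit = fit_lmm_log(model_frame(config), "f0")
            calm += abs(fit.effect("condition[contrastive]").statistic) < 2.0
        assert calm >= 45


def _fake_fit(aic, n_obs=323, ll=None, k=4):
    ll = ll if ll is not None else -(aic - 2 * k) / 2
    return ModelFit(
        formula={"response": "outcome", "fixed": [], "random_intercepts": []},
        fixed_effects=[],
        variance_components={},
        log_likelihood=ll,
        aic=aic,
        n_obs=n_obs,
        n_params=k,
        converged=True,
    )


class TestCompareAic:
    def test_retained_vs_maximal_structure(self):
        """AIC 388.1 (intercepts only) beats 404.7 (maximal), delta 16.6."""
        cmp = compare_aic(_fake_fit(388.1), _fake_fit(404.7))
        assert cmp.preferred == "a"
        assert cmp.delta == pytest.approx(16.6)

    def test_tie_prefers_first(self):
        cmp = compare_aic(_fake_fit(100.0), _fake_fit(100.0))
        assert cmp.preferred == "a" and cmp.tie

    def test_aic_formula(self):
        assert _fake_fit(aic=388.1, ll=-190.05, k=4).aic == pytest.approx(
            -2 * -190.05 + 2 * 4
        )

    def test_antisymmetry(self):
        a, b = _fake_fit(388.1), _fake_fit(404.7)
        assert compare_aic(a, b).signed_delta == -compare_aic(b, a).signed_delta

    def test_mismatched_data_rejected(self):
        with pytest.raises(ComparisonError):
            compare_aic(_fake_fit(100.0, n_obs=10), _fake_fit(90.0, n_obs=11))
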
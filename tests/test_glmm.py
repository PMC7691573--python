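import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

import medsurg as ms
from medsurg.glmm import PI2_3, build_design

from _oracles import newton_logistic
from conftest import AMAZE_COVS, make_table


def _flat_trial(n=900, seed=2):
    """Trial generated with no between-surgeon variation in the mediator."""
    cfg = ms.GeneratorConfig(
        n_patients=n, n_clusters=10, alpha0=-0.4, alpha1=1.1,
        alpha_x={"age": 0.5}, sigma_v=0.0, theta_x={"age": 0.3},
        sigma_u=0.0, covariate_spec={"age": ("normal", 0, 1)}, seed=seed,
    )
    return ms.generate_trial(cfg)


def test_sigma_zero_data_matches_plain_logistic_oracle():
    """With no cluster variance the AGQ fit collapses to ordinary logistic
    regression; an independent Newton-Raphson fit must agree to 4 sig figs."""
    trial = _flat_trial()
    fit = ms.fit_glmm(trial.table, ms.GlmmSpec.mediator(("age",)))
    y = trial.table.df["M"].to_numpy(float)
    X = build_design(trial.table.df, ("T", "age"))
    beta_o, vcov_o = newton_logistic(y, X)
    if fit.sigma == 0.0:
        rtol = 5e-5  # 4 significant figures
    else:
        rtol = 2e-2  # tiny estimated sigma perturbs coefficients slightly
    np.testing.assert_allclose(fit.coef_array, beta_o, rtol=rtol, atol=1e-4)
    assert fit.sigma < 0.25
    assert fit.icc == pytest.approx(0.0, abs=0.02)


def test_amaze_mediator_icc_is_large(amaze_fits):
    med, out = amaze_fits
    assert 0.3 < med.icc < 0.8  # strong surgeon preference, order 0.5
    assert out.icc < 0.3


def test_icc_definitional_identity(amaze_fits):
    for fit in amaze_fits:
        assert fit.icc == fit.sigma**2 / (fit.sigma**2 + PI2_3)


def test_quadrature_consistency_7_vs_15(amaze_trial):
    a = ms.fit_glmm(amaze_trial.table, ms.GlmmSpec.mediator(AMAZE_COVS), quad_points=7)
    b = ms.fit_glmm(amaze_trial.table, ms.GlmmSpec.mediator(AMAZE_COVS), quad_points=15)
    # genuine 7-point truncation at mediator-level ICC is a few 1e-3 (lme4
    # shows the same order); far below any reported SE
    np.testing.assert_allclose(a.coef_array, b.coef_array, atol=5e-3)
    assert abs(a.sigma - b.sigma) < 5e-3


def test_likelihood_at_estimate_beats_generating_values():
    for seed in range(8):
        cfg = ms.GeneratorConfig(
            n_patients=300, n_clusters=10, alpha0=-0.3, alpha1=0.8, alpha_x={},
            sigma_v=0.9, theta_x={}, sigma_u=0.4, covariate_spec={}, seed=seed,
        )
        trial = ms.generate_trial(cfg)
        spec = ms.GlmmSpec.mediator(())
        fit = ms.fit_glmm(trial.table, spec)
        ll_true = ms.glmm.loglik_at(
            trial.table, spec, [cfg.alpha0, cfg.alpha1], cfg.sigma_v
        )
        assert fit.loglik >= ll_true - 1e-6


def test_agrees_with_lme4_glmer():
    """Independent cross-check against R lme4 at the same quadrature order."""
    cfg = ms.GeneratorConfig(
        n_patients=400, n_clusters=12, alpha0=-0.5, alpha1=1.2,
        alpha_x={"age": 0.4}, sigma_v=1.2, theta_x={},
        covariate_spec={"age": ("normal", 0, 1)}, seed=42,
    )
    trial = ms.generate_trial(cfg)
    fit = ms.fit_glmm(trial.table, ms.GlmmSpec.mediator(("age",)), quad_points=9)
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as td:
        csv = pathlib.Path(td) / "d.csv"
        ms.write_trial_table(trial.table, csv)
        rcode = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(M ~ T + age + (1|cluster), data=d, family=binomial, nAGQ=9);"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))[1]), sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
        )
    assert out.returncode == 0, out.stderr
    vals = np.array([float(v) for v in out.stdout.strip().split(",")])
    np.testing.assert_allclose(fit.coef_array, vals[:3], atol=2e-3)
    assert fit.sigma == pytest.approx(vals[3], abs=5e-3)


def test_rank_deficiency_names_aliased_column():
    t = make_table(covs=("age",))
    df = t.df.copy()
    df["age2"] = df["age"]  # exact copy -> aliased
    tt = ms.TrialTable(df=df, covariates={"age": "continuous", "age2": "continuous"})
    with pytest.raises(ms.RankDeficiencyError, match="age2"):
        ms.fit_glmm(tt, ms.GlmmSpec.mediator(("age", "age2")))


def test_complete_separation_raises():
    df = make_table(n0=30, n1=30, m0=0, m1=30, y0=10, y1=20).df
    tt = ms.TrialTable(df=df, covariates={})
    with pytest.raises(ms.SeparationError):
        ms.fit_glmm(tt, ms.GlmmSpec.mediator(()))


# ---- odds ratios ----------------------------------------------------------


def test_odds_ratio_zero_coef_is_one(amaze_fits):
    from conftest import make_covfree_fit

    fit = make_covfree_fit("mediator", [0.0, 0.0], sigma=0.5)
    fit.vcov = np.diag([0.04, 0.09])
    tab = ms.odds_ratio_table(fit, level=0.95)
    assert tab.loc["T", "odds_ratio"] == pytest.approx(1.0)
    # CI symmetric around 1 on the log scale
    assert tab.loc["T", "ci_low"] * tab.loc["T", "ci_high"] == pytest.approx(1.0)


def test_odds_ratio_zero_se_zero_width():
    from conftest import make_covfree_fit

    fit = make_covfree_fit("mediator", [0.0, np.log(2.0)], sigma=0.0)
    fit.vcov = np.zeros((2, 2))
    tab = ms.odds_ratio_table(fit)
    assert tab.loc["T", "odds_ratio"] == pytest.approx(2.0)
    assert tab.loc["T", "ci_low"] == pytest.approx(2.0)
    assert tab.loc["T", "ci_high"] == pytest.approx(2.0)


def test_odds_ratios_match_oracle_logistic_fit():
    trial = _flat_trial(n=700, seed=5)
    fit = ms.fit_glmm(trial.table, ms.GlmmSpec.mediator(("age",)))
    tab = ms.odds_ratio_table(fit)
    y = trial.table.df["M"].to_numpy(float)
    X = build_design(trial.table.df, ("T", "age"))
    beta_o, _ = newton_logistic(y, X)
    np.testing.assert_allclose(
        tab["odds_ratio"].to_numpy(), np.exp(beta_o), rtol=5e-3
    )


# ---- prediction -----------------------------------------------------------


def test_predict_prob_all_zero_coefficients_is_half():
    from conftest import make_covfree_fit

    fit = make_covfree_fit("outcome", [0.0] * 4, sigma=0.7)
    t = make_table()
    p = ms.predict_prob(fit, t, random_intercept="zero")
    assert np.allclose(p, 0.5)


def test_predict_prob_hand_computed_record():
    from scipy.special import expit

    from conftest import make_covfree_fit

    fit = make_covfree_fit("outcome", [0.2, 0.5, -0.3, 0.8], sigma=0.0)
    t = make_table(n0=2, n1=2, m0=1, m1=1, y0=1, y1=1)
    p = ms.predict_prob(fit, t, t=1.0, m=1.0, random_intercept="zero")
    assert p[0] == pytest.approx(expit(0.2 + 0.5 - 0.3 + 0.8))


def test_predict_prob_draw_with_sigma_zero_equals_zero_rule():
    from conftest import make_covfree_fit

    fit = make_covfree_fit("outcome", [0.3, 0.1, 0.2, 0.0], sigma=0.0)
    t = make_table()
    a = ms.predict_prob(fit, t, random_intercept="zero")
    b = ms.predict_prob(fit, t, random_intercept="draw", seed=1)
    np.testing.assert_array_equal(a, b)


def test_predict_prob_unknown_cluster_mode_rule_errors(amaze_fits):
    med, _ = amaze_fits
    # clusters c1..c4, unseen by the amaze fit
    t = make_table(covs=("age", "baseline_sr"))
    with pytest.raises(ms.ModelError, match="draw"):
        ms.predict_prob(med, t, random_intercept="mode")


# ---- recovery (scaled-down version of the full study in acceptance) -------


def test_parameter_recovery_short():
    true = np.array([-0.3, 1.0, 0.5])
    ests, covered = [], []
    for seed in range(40):
        cfg = ms.GeneratorConfig(
            n_patients=1000, n_clusters=20, alpha0=true[0], alpha1=true[1],
            alpha_x={"age": true[2]}, sigma_v=1.0, theta_x={},
            covariate_spec={"age": ("normal", 0, 1)}, seed=seed,
        )
        fit = ms.fit_glmm(ms.generate_trial(cfg).table, ms.GlmmSpec.mediator(("age",)))
        se = np.sqrt(np.diag(fit.vcov))
        ests.append(fit.coef_array)
        covered.append(np.abs(fit.coef_array - true) < 1.96 * se)
    ests = np.asarray(ests)
    mcse = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
    assert np.all(np.abs(ests.mean(axis=0) - true) < 3 * mcse + 0.02)
    assert np.asarray(covered).mean() > 0.85


def test_fit_serialization_round_trips_through_engine(amaze_trial, amaze_fits):
    med, out = amaze_fits
    med2 = ms.GlmmFit.from_dict(med.to_dict())
    out2 = ms.GlmmFit.from_dict(out.to_dict())
    a = ms.estimate_natural_effects(amaze_trial.table, med, out, n_sims=300, seed=41)
    b = ms.estimate_natural_effects(amaze_trial.table, med2, out2, n_sims=300, seed=41)
    assert a.tau == b.tau and a.zeta_avg == b.zeta_avg and a.delta_avg == b.delta_avg
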
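import numpy as np
import pytest

import medsurg as ms

from _oracles import covfree_effects
from conftest import make_covfree_fit, make_table

MED = dict(a0=-0.6, a1=1.3, sv=0.9)
OUT = dict(t0=-0.2, t1=0.5, t2=0.4, t3=0.3, su=0.5)


def _fits(med=MED, out=OUT):
    mf = make_covfree_fit("mediator", [med["a0"], med["a1"]], med["sv"])
    of = make_covfree_fit("outcome", [out["t0"], out["t1"], out["t2"], out["t3"]], out["su"])
    return mf, of


def test_composition_identity_exact():
    mf, of = _fits()
    t = make_table(n0=40, n1=40)
    est = ms.estimate_natural_effects(t, mf, of, n_sims=400, seed=1)
    assert abs(est.tau - (est.delta1 + est.zeta0)) < 1e-12
    assert abs(est.tau - (est.delta0 + est.zeta1)) < 1e-12
    assert est.delta_avg == (est.delta0 + est.delta1) / 2
    assert est.zeta_avg == (est.zeta0 + est.zeta1) / 2


def test_no_mediator_effect_gives_exactly_zero_indirect():
    """theta2 = theta3 = 0: common random numbers make the NIE exactly 0."""
    mf, of = _fits(out=dict(t0=-0.2, t1=0.5, t2=0.0, t3=0.0, su=0.5))
    t = make_table()
    est = ms.estimate_natural_effects(t, mf, of, n_sims=300, seed=2)
    assert est.delta0 == 0.0
    assert est.delta1 == 0.0


def test_mediator_unresponsive_to_treatment_gives_zero_indirect():
    """alpha1 = 0 and sigma_v = 0: M(0) and M(1) are the same draw."""
    mf, of = _fits(med=dict(a0=-0.3, a1=0.0, sv=0.0))
    t = make_table()
    est = ms.estimate_natural_effects(t, mf, of, n_sims=300, seed=3)
    assert est.delta0 == 0.0 and est.delta1 == 0.0


def test_engine_matches_quadrature_oracle():
    """All seven natural-effect quantities within 3 MC-SEs of the closed form."""
    mf, of = _fits()
    t = make_table(n0=60, n1=60)
    est = ms.estimate_natural_effects(t, mf, of, n_sims=2000, seed=7)
    oracle = covfree_effects(MED["a0"], MED["a1"], MED["sv"], **{
        "t0": OUT["t0"], "t1": OUT["t1"], "t2": OUT["t2"], "t3": OUT["t3"], "su": OUT["su"]})
    for name in ("delta0", "delta1", "delta_avg", "zeta0", "zeta1", "zeta_avg", "tau"):
        se = est.mc_se(name)
        assert abs(est.effect(name) - oracle[name]) < 3 * se + 1e-4, name


def test_controlled_effects_zero_without_treatment_terms():
    mf, of = _fits(out=dict(t0=0.1, t1=0.0, t2=0.6, t3=0.0, su=0.4))
    t = make_table()
    cde = ms.estimate_controlled_effects(t, of, n_sims=400, seed=5)
    assert cde.cde_m0 == 0.0 and cde.cde_m1 == 0.0


def test_controlled_effects_equal_without_interaction():
    mf, of = _fits(out=dict(t0=0.1, t1=0.5, t2=0.6, t3=0.0, su=0.4))
    t = make_table()
    cde = ms.estimate_controlled_effects(t, of, n_sims=4000, seed=6)
    assert cde.cde_m0 == pytest.approx(cde.cde_m1, abs=0.02)


def test_controlled_effects_match_quadrature_oracle():
    _, of = _fits()
    t = make_table(n0=60, n1=60)
    cde = ms.estimate_controlled_effects(t, of, n_sims=2000, seed=8)
    oracle = covfree_effects(MED["a0"], MED["a1"], MED["sv"], OUT["t0"], OUT["t1"], OUT["t2"], OUT["t3"], OUT["su"])
    for name, got in (("cde_m0", cde.cde_m0), ("cde_m1", cde.cde_m1)):
        se = np.std(cde.rep_diffs, axis=0, ddof=1)[0] / np.sqrt(cde.n_sims)
        assert abs(got - oracle[name]) < 3 * se + 1e-3, name


def test_mc_error_shrinks_as_sqrt_nsims():
    mf, of = _fits()
    t = make_table(n0=30, n1=30)

    def spread(n_sims):
        vals = [
            ms.estimate_natural_effects(t, mf, of, n_sims=n_sims, seed=s).tau
            for s in range(18)
        ]
        return np.std(vals, ddof=1)

    s_small, s_big = spread(100), spread(1600)
    # fourfold n_sims increase should shrink SD about fourfold (x4 in sqrt)
    assert s_big < s_small / 2.0


def test_zero_rule_removes_intercept_variation():
    mf, of = _fits()
    t = make_table()
    a = ms.estimate_natural_effects(t, mf, of, n_sims=500, seed=9, re_rule="zero")
    b = ms.estimate_natural_effects(t, mf, of, n_sims=500, seed=9, re_rule="zero")
    assert a.tau == b.tau  # deterministic given seed


def test_small_nsims_warns():
    mf, of = _fits()
    with pytest.warns(UserWarning, match="n_sims"):
        ms.estimate_natural_effects(make_table(), mf, of, n_sims=50, seed=0)


def test_engine_recovers_generator_truth():
    """Fits + engine reproduce the generating-model truth on average."""
    cfg = ms.GeneratorConfig(
        n_patients=400, n_clusters=12, alpha0=-0.6, alpha1=1.3, alpha_x={},
        sigma_v=0.9, theta0=-0.2, theta1=0.5, theta2=0.4, theta3=0.3,
        theta_x={}, sigma_u=0.5, covariate_spec={},
    )
    truth = ms.true_effects(cfg, n_mc=400_000, seed=1)
    errs = {"tau": [], "zeta_avg": [], "delta_avg": []}
    import dataclasses
    for seed in range(100):
        trial = ms.generate_trial(dataclasses.replace(cfg, seed=seed))
        mf = ms.fit_glmm(trial.table, ms.GlmmSpec.mediator(()))
        of = ms.fit_glmm(trial.table, ms.GlmmSpec.outcome(()))
        est = ms.estimate_natural_effects(trial.table, mf, of, n_sims=400, seed=seed)
        for k in errs:
            errs[k].append(est.effect(k) - truth.effect(k))
    for k, v in errs.items():
        v = np.asarray(v)
        mcse = v.std(ddof=1) / np.sqrt(len(v))
        assert abs(v.mean()) < 3 * mcse + 0.01, (k, v.mean(), mcse)


# ---- moderation -----------------------------------------------------------


def _moderated_fits(t_age_out=0.0, t_age_med=0.0, m_age_out=0.0):
    mf = ms.GlmmFit(
        spec=ms.GlmmSpec(response="mediator", terms=("T", "age", "T:age")),
        coefficients={"Intercept": -0.6, "T": 1.3, "age": 0.0, "T:age": t_age_med},
        vcov=np.zeros((4, 4)), sigma=0.9, cluster_modes={}, loglik=0.0,
        converged=True, n_used=0, quad_points=7,
    )
    of = ms.GlmmFit(
        spec=ms.GlmmSpec(
            response="outcome", terms=("T", "M", "T:M", "age", "T:age", "M:age")
        ),
        coefficients={
            "Intercept": -0.2, "T": 0.5, "M": 0.4, "T:M": 0.3,
            "age": 0.0, "T:age": t_age_out, "M:age": m_age_out,
        },
        vcov=np.zeros((7, 7)), sigma=0.5, cluster_modes={}, loglik=0.0,
        converged=True, n_used=0, quad_points=7,
    )
    return mf, of


def test_zero_interactions_give_flat_profile():
    mf, of = _moderated_fits()
    t = make_table(covs=("age",))
    mod = ms.estimate_moderated_effects(
        t, mf, of, "age", grid=[-1.0, 0.0, 1.0], n_sims=800, seed=4
    )
    prof = mod.profile("zeta_avg")
    assert np.ptp(prof) < 3 * mod.estimates[0].mc_se("zeta_avg") + 0.01


def test_negative_treatment_age_interaction_gives_declining_direct_effect():
    mf, of = _moderated_fits(t_age_out=-0.8)
    t = make_table(covs=("age",))
    mod = ms.estimate_moderated_effects(
        t, mf, of, "age", grid=[-1.5, 0.0, 1.5], n_sims=2000, seed=4
    )
    prof = mod.profile("zeta_avg")
    assert prof[0] > prof[1] > prof[2]


def test_single_point_grid_consistent_with_plain_engine():
    mf, of = _moderated_fits()
    t = make_table(covs=("age",))
    mod = ms.estimate_moderated_effects(t, mf, of, "age", grid=[0.0], n_sims=1500, seed=11)
    plain = ms.estimate_natural_effects(t, mf, of, n_sims=1500, seed=11, overrides={"age": 0.0})
    assert mod.estimates[0].tau == plain.tau


def test_missing_interaction_terms_error():
    mf, of = _fits()
    t = make_table(covs=("age",))
    with pytest.raises(ms.ModelError, match="T:age"):
        ms.estimate_moderated_effects(t, mf, of, "age", grid=[0.0], n_sims=100, seed=0)
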
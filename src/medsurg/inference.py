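"""Nonparametric bootstrap confidence intervals for mediation effects.

Each replicate resamples the trial (patients with replacement stratified by
arm, or whole surgeon clusters with replacement), refits both mixed models
and reruns the Monte Carlo engine with a replicate-specific sub-seed.
Intervals are percentile intervals; refits that fail to converge are dropped
and counted, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import glmm as _glmm
from .glmm import GlmmFit, GlmmSpec, ModelError, build_design, fit_glmm
from .mediation import (
    ControlledEffects,
    MediationEstimates,
    _natural_cells,
    estimate_controlled_effects,
    estimate_natural_effects,
)
from .trial_data import TrialTable

EFFECT_NAMES = ("delta0", "delta1", "delta_avg", "zeta0", "zeta1", "zeta_avg", "tau")
CDE_NAMES = ("cde_m0", "cde_m1")


@dataclass
class BootstrapResult:
    n_boot: int
    level: float
    seed: int
    resample_unit: str
    replicates: dict  # effect name -> vector of length n_boot - failures
    ci: dict  # effect name -> (low, high)
    failed: int


def mc_standard_error(replicates) -> float:
    """Sample SD of a replicate vector (>= 2 replicates required)."""
    r = np.asarray(replicates, float)
    if r.size < 2:
        raise ValueError("need at least 2 replicates")
    return float(np.std(r, ddof=1))


def percentile_ci(replicates, level: float) -> tuple:
    r = np.asarray(replicates, float)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(r, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def _resample(rng, unit, arm_idx, cluster_rows, codes, n_clusters):
    if unit == "patient":
        parts = [idx[rng.integers(0, len(idx), len(idx))] for idx in arm_idx]
        idx = np.concatenate(parts)
        return idx, codes[idx], n_clusters
    if unit == "cluster":
        picks = rng.integers(0, n_clusters, n_clusters)
        idx = np.concatenate([cluster_rows[s] for s in picks])
        codes_b = np.concatenate(
            [np.full(len(cluster_rows[s]), j) for j, s in enumerate(picks)]
        )
        return idx, codes_b, n_clusters
    raise ValueError(f"unknown resample unit {unit!r}")


def bootstrap_effects(
    table: TrialTable,
    med_spec: GlmmSpec,
    out_spec: GlmmSpec,
    n_boot: int = 999,
    level: float = 0.95,
    seed: int = 0,
    resample_unit: str = "patient",
    n_sims: int = 2000,
    re_rule: str = "draw",
    quad_points: int = 7,
    max_failed_frac: float = 0.2,
) -> tuple[MediationEstimates, ControlledEffects, BootstrapResult]:
    """Point estimates plus percentile bootstrap CIs for all effects.

    Returns the full-data natural-effect and controlled-effect estimates with
    their ``ci`` fields populated, alongside the raw replicate vectors.
    """
    if n_boot < 199:
        raise ValueError("n_boot must be at least 199")
    med_fit = fit_glmm(table, med_spec, quad_points=quad_points)
    out_fit = fit_glmm(table, out_spec, quad_points=quad_points)
    ss = np.random.SeedSequence(seed)
    point_seed, boot_ss = ss.spawn(2)
    nat = estimate_natural_effects(
        table, med_fit, out_fit, n_sims=n_sims,
        seed=int(point_seed.generate_state(1)[0] % 2**31), re_rule=re_rule,
    )
    cde = estimate_controlled_effects(
        table, out_fit, n_sims=n_sims,
        seed=int(point_seed.generate_state(2)[1] % 2**31), re_rule=re_rule,
    )

    df = table.df
    y_m = df["M"].to_numpy(float)
    y_o = df["Y"].to_numpy(float)
    Xm_fit = build_design(df, med_spec.terms)
    Xo_fit = build_design(df, out_spec.terms)
    Xm_pot = {t: build_design(df, med_spec.terms, {"T": t}) for t in (0, 1)}
    Xo_pot = {
        (t, m): build_design(df, out_spec.terms, {"T": t, "M": m})
        for t in (0, 1)
        for m in (0, 1)
    }
    t_arr = df["T"].to_numpy(float)
    arm_idx = [np.nonzero(t_arr == a)[0] for a in (0, 1)]
    labels, codes = np.unique(df["cluster"].astype(str).to_numpy(), return_inverse=True)
    n_clusters = len(labels)
    cluster_rows = [np.nonzero(codes == s)[0] for s in range(n_clusters)]

    warm_med = np.concatenate([med_fit.coef_array, [np.log(max(med_fit.sigma, 1e-3))]])
    warm_out = np.concatenate([out_fit.coef_array, [np.log(max(out_fit.sigma, 1e-3))]])

    reps = {k: [] for k in EFFECT_NAMES + CDE_NAMES}
    failed = 0
    children = boot_ss.spawn(n_boot)
    for b in range(n_boot):
        rng = np.random.default_rng(children[b])
        idx, codes_b, S_b = _resample(rng, resample_unit, arm_idx, cluster_rows, codes, n_clusters)
        n_b = len(idx)
        try:
            cm = _glmm._fit_core(
                y_m[idx], Xm_fit[idx], codes_b, S_b, quad_points,
                tol=1e-6, start=warm_med.copy(), max_iter=200,
            )
            co = _glmm._fit_core(
                y_o[idx], Xo_fit[idx], codes_b, S_b, quad_points,
                tol=1e-6, start=warm_out.copy(), max_iter=200,
            )
        except (np.linalg.LinAlgError, FloatingPointError, ModelError):
            failed += 1
            continue
        pm, po = cm.params, co.params
        if not (cm.success and co.success) or max(
            np.max(np.abs(pm[:-1])), np.max(np.abs(po[:-1]))
        ) > 25:
            failed += 1
            continue
        beta_m, sv = pm[:-1], float(np.exp(pm[-1]))
        beta_o, su = po[:-1], float(np.exp(po[-1]))
        sv = 0.0 if sv < _glmm._SIGMA_ZERO else sv
        su = 0.0 if su < _glmm._SIGMA_ZERO else su
        lp_m = {t: Xm_pot[t][idx] @ beta_m for t in (0, 1)}
        lp_o = {tm: Xo_pot[tm][idx] @ beta_o for tm in Xo_pot}
        if re_rule == "draw":
            v = rng.normal(0.0, sv, size=n_sims)[:, None]
            u = rng.normal(0.0, su, size=n_sims)[:, None]
        else:  # zero rule inside the bootstrap; modes are not refit here
            v = np.zeros((1, 1))
            u = np.zeros((1, 1))
        cells = _natural_cells(lp_m, lp_o, v, u, n_sims, n_b, rng).mean(axis=0)
        est = MediationEstimates.from_pbar(cells, n_sims=n_sims, seed=b)
        for k in EFFECT_NAMES:
            reps[k].append(est.effect(k))
        w_y = rng.uniform(size=(n_sims, n_b))
        for m in (0, 1):
            p1 = expit(lp_o[(1, m)][None, :] + u)
            p0 = expit(lp_o[(0, m)][None, :] + u)
            d = ((w_y < p1).astype(float) - (w_y < p0).astype(float)).mean()
            reps[CDE_NAMES[m]].append(d)

    if failed > max_failed_frac * n_boot:
        raise ModelError(
            f"{failed}/{n_boot} bootstrap refits failed; consider more data "
            "or a simpler model"
        )
    replicates = {k: np.asarray(v) for k, v in reps.items()}
    ci = {k: percentile_ci(v, level) for k, v in replicates.items()}
    nat.ci = {k: ci[k] for k in EFFECT_NAMES}
    cde.ci = {k: ci[k] for k in CDE_NAMES}
    result = BootstrapResult(
        n_boot=n_boot,
        level=level,
        seed=seed,
        resample_unit=resample_unit,
        replicates=replicates,
        ci=ci,
        failed=failed,
    )
    return nat, cde, result
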
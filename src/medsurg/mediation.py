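"""Monte Carlo estimation of natural, total and controlled effects.

Potential mediators M(0), M(1) are simulated from the fitted mediator model
with treatment forced to each arm; the four potential outcomes Y(t, M(t'))
are then simulated from the fitted outcome model. Averaging over patients
and simulation replicates gives the cell means P(t, t') from which all
effects on the probability-difference scale follow:

    delta(t) = P(t,1) - P(t,0)   natural indirect effect (NIE)
    zeta(t)  = P(1,t) - P(0,t)   natural direct effect (NDE)
    tau      = P(1,1) - P(0,0)   total effect, = delta(1)+zeta(0) = delta(0)+zeta(1)

The estimand is marginal over the trial's empirical covariate distribution
and over the population of surgeons. Common random numbers are shared across
the four (t, t') cells within a replicate, so structural zeroes (e.g. no
mediator effect on outcome) are exact, not just in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .glmm import GlmmFit, ModelError, build_design
from .trial_data import TrialTable

_EFFECTS = ("delta0", "delta1", "delta_avg", "zeta0", "zeta1", "zeta_avg", "tau")


@dataclass
class MediationEstimates:
    delta0: float
    delta1: float
    delta_avg: float
    zeta0: float
    zeta1: float
    zeta_avg: float
    tau: float
    n_sims: int
    seed: int
    pbar: np.ndarray | None = None  # 2x2 cell means, [t_outcome, t_mediator]
    rep_cells: np.ndarray | None = None  # (n_sims, 2, 2) per-replicate cell means
    cde_m0: float | None = None
    cde_m1: float | None = None
    ci: dict = field(default_factory=dict)  # effect name -> (low, high)

    @classmethod
    def from_pbar(cls, pbar: np.ndarray, n_sims: int, seed: int, rep_cells=None):
        pbar = np.asarray(pbar, float)
        d0 = pbar[0, 1] - pbar[0, 0]
        d1 = pbar[1, 1] - pbar[1, 0]
        z0 = pbar[1, 0] - pbar[0, 0]
        z1 = pbar[1, 1] - pbar[0, 1]
        return cls(
            delta0=float(d0),
            delta1=float(d1),
            delta_avg=float((d0 + d1) / 2.0),
            zeta0=float(z0),
            zeta1=float(z1),
            zeta_avg=float((z0 + z1) / 2.0),
            tau=float(pbar[1, 1] - pbar[0, 0]),
            n_sims=n_sims,
            seed=seed,
            pbar=pbar,
            rep_cells=None if rep_cells is None else np.asarray(rep_cells, float),
        )

    def effect(self, name: str) -> float:
        return getattr(self, name)

    def mc_se(self, name: str) -> float:
        """Monte Carlo standard error of an effect from per-replicate cells."""
        if self.rep_cells is None:
            raise ValueError("per-replicate cells were not stored")
        c = self.rep_cells
        reps = {
            "delta0": c[:, 0, 1] - c[:, 0, 0],
            "delta1": c[:, 1, 1] - c[:, 1, 0],
            "zeta0": c[:, 1, 0] - c[:, 0, 0],
            "zeta1": c[:, 1, 1] - c[:, 0, 1],
            "tau": c[:, 1, 1] - c[:, 0, 0],
        }
        reps["delta_avg"] = (reps["delta0"] + reps["delta1"]) / 2.0
        reps["zeta_avg"] = (reps["zeta0"] + reps["zeta1"]) / 2.0
        r = reps[name]
        return float(np.std(r, ddof=1) / np.sqrt(len(r)))

    def to_dict(self) -> dict:
        d = {k: float(self.effect(k)) for k in _EFFECTS}
        d["n_sims"] = int(self.n_sims)
        d["seed"] = int(self.seed)
        if self.pbar is not None:
            d["pbar"] = self.pbar.tolist()
        if self.cde_m0 is not None:
            d["cde_m0"] = float(self.cde_m0)
            d["cde_m1"] = float(self.cde_m1)
        if self.ci:
            d["ci"] = {k: [float(v[0]), float(v[1])] for k, v in self.ci.items()}
        return d


@dataclass
class ControlledEffects:
    cde_m0: float
    cde_m1: float
    n_sims: int
    seed: int
    rep_diffs: np.ndarray | None = None  # (n_sims, 2) per-replicate differences
    ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "cde_m0": float(self.cde_m0),
            "cde_m1": float(self.cde_m1),
            "n_sims": int(self.n_sims),
            "seed": int(self.seed),
        }
        if self.ci:
            d["ci"] = {k: [float(v[0]), float(v[1])] for k, v in self.ci.items()}
        return d


@dataclass
class ModeratedEffects:
    moderator: str
    grid: np.ndarray
    estimates: list  # one MediationEstimates per grid value

    def profile(self, name: str) -> np.ndarray:
        return np.array([e.effect(name) for e in self.estimates])


# ---------------------------------------------------------------------------


def _check_fits(table: TrialTable, *fits: GlmmFit) -> None:
    for fit in fits:
        if not fit.converged:
            raise ModelError(f"{fit.spec.response} model did not converge")
        for term in fit.spec.terms:
            for name in term.split(":"):
                if name not in ("T", "M") and name not in table.df.columns:
                    raise ModelError(
                        f"term {name!r} of the {fit.spec.response} model is "
                        "missing from the trial table"
                    )


def _intercepts(rule, sigma, n_sims, rng, fit=None, table=None):
    """Random-intercept realisations, shape (n_sims, 1) or (1, n)."""
    if rule == "draw":
        return rng.normal(0.0, sigma, size=n_sims)[:, None]
    if rule == "zero":
        return np.zeros((1, 1))
    if rule == "mode":
        labs = table.df["cluster"].astype(str)
        unknown = set(labs.unique()) - set(fit.cluster_modes)
        if unknown:
            raise ModelError(f"clusters {sorted(unknown)} unseen by the fit")
        return labs.map(fit.cluster_modes).to_numpy(float)[None, :]
    raise ValueError(f"unknown random-intercept rule {rule!r}")


def _natural_cells(
    lp_m,  # dict t -> (n,) mediator linear predictor with T forced
    lp_o,  # dict (t, m) -> (n,) outcome linear predictor with T, M forced
    v,  # (n_sims,1) or broadcastable mediator intercepts
    u,  # outcome intercepts
    n_sims: int,
    n: int,
    rng,
):
    w_m = rng.uniform(size=(n_sims, n))
    M = {t: w_m < expit(lp_m[t][None, :] + v) for t in (0, 1)}
    w_y = rng.uniform(size=(n_sims, n))
    rep_cells = np.empty((n_sims, 2, 2))
    for t in (0, 1):
        base = lp_o[(t, 0)][None, :]
        diff = (lp_o[(t, 1)] - lp_o[(t, 0)])[None, :]
        for tp in (0, 1):
            p = expit(base + diff * M[tp] + u)
            rep_cells[:, t, tp] = (w_y < p).mean(axis=1)
    return rep_cells


def estimate_natural_effects(
    table: TrialTable,
    med_fit: GlmmFit,
    out_fit: GlmmFit,
    n_sims: int = 2000,
    seed: int = 0,
    re_rule: str = "draw",
    overrides: dict | None = None,
    outcome_lp_shift: np.ndarray | None = None,
) -> MediationEstimates:
    """Natural direct/indirect and total effects on the probability scale.

    ``re_rule`` chooses the random-intercept realisation for the potential
    draws: ``"draw"`` (fresh N(0, sigma_hat^2) per replicate; the marginal,
    population-of-surgeons estimand and the default), ``"zero"`` or
    ``"mode"``. ``overrides``/``outcome_lp_shift`` are internal hooks used by
    moderation (forcing a covariate to a grid value) and by the sensitivity
    module (additive per-cell shift on the outcome linear predictor).
    """
    _check_fits(table, med_fit, out_fit)
    if n_sims < 100:
        warnings.warn(f"n_sims={n_sims} is small; estimates will be noisy", stacklevel=2)
    df = table.df
    n = len(df)
    extra = overrides or {}
    lp_m = {
        t: build_design(df, med_fit.spec.terms, {"T": t, **extra}) @ med_fit.coef_array
        for t in (0, 1)
    }
    lp_o = {}
    for t in (0, 1):
        for m in (0, 1):
            lp = build_design(df, out_fit.spec.terms, {"T": t, "M": m, **extra}) @ out_fit.coef_array
            if outcome_lp_shift is not None:
                lp = lp + outcome_lp_shift[t, m]
            lp_o[(t, m)] = lp
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    v = _intercepts(re_rule, med_fit.sigma, n_sims, rng, med_fit, table)
    u = _intercepts(re_rule, out_fit.sigma, n_sims, rng, out_fit, table)
    rep_cells = _natural_cells(lp_m, lp_o, v, u, n_sims, n, rng)
    pbar = rep_cells.mean(axis=0)
    return MediationEstimates.from_pbar(pbar, n_sims=n_sims, seed=seed, rep_cells=rep_cells)


def estimate_controlled_effects(
    table: TrialTable,
    out_fit: GlmmFit,
    n_sims: int = 2000,
    seed: int = 0,
    re_rule: str = "draw",
    outcome_lp_shift: np.ndarray | None = None,
) -> ControlledEffects:
    """Controlled direct effects with the mediator mandated (m=1) for all
    patients or prohibited (m=0); the mediator model plays no part."""
    _check_fits(table, out_fit)
    df = table.df
    n = len(df)
    lp_o = {}
    for t in (0, 1):
        for m in (0, 1):
            lp = build_design(df, out_fit.spec.terms, {"T": t, "M": m}) @ out_fit.coef_array
            if outcome_lp_shift is not None:
                lp = lp + outcome_lp_shift[t, m]
            lp_o[(t, m)] = lp
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u = _intercepts(re_rule, out_fit.sigma, n_sims, rng, out_fit, table)
    w_y = rng.uniform(size=(n_sims, n))
    rep = np.empty((n_sims, 2))
    for m in (0, 1):
        y1 = w_y < expit(lp_o[(1, m)][None, :] + u)
        y0 = w_y < expit(lp_o[(0, m)][None, :] + u)
        rep[:, m] = (y1.astype(float) - y0.astype(float)).mean(axis=1)
    return ControlledEffects(
        cde_m0=float(rep[:, 0].mean()),
        cde_m1=float(rep[:, 1].mean()),
        n_sims=n_sims,
        seed=seed,
        rep_diffs=rep,
    )


def estimate_moderated_effects(
    table: TrialTable,
    med_fit: GlmmFit,
    out_fit: GlmmFit,
    moderator: str,
    grid,
    n_sims: int = 2000,
    seed: int = 0,
    re_rule: str = "draw",
) -> ModeratedEffects:
    """Natural-effect profile along a moderator grid.

    At each grid value g every patient's moderator is set to g (all other
    covariates at observed values) and the natural effects are recomputed.
    Both fits must carry the moderator-by-treatment interaction, and the
    outcome fit the moderator-by-mediator interaction.
    """
    tm = f"T:{moderator}"
    mm = f"M:{moderator}"
    if tm not in med_fit.spec.terms and f"{moderator}:T" not in med_fit.spec.terms:
        raise ModelError(f"mediator model lacks the {tm} interaction")
    if tm not in out_fit.spec.terms and f"{moderator}:T" not in out_fit.spec.terms:
        raise ModelError(f"outcome model lacks the {tm} interaction")
    if mm not in out_fit.spec.terms and f"{moderator}:M" not in out_fit.spec.terms:
        raise ModelError(f"outcome model lacks the {mm} interaction")
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")
    estimates = [
        estimate_natural_effects(
            table,
            med_fit,
            out_fit,
            n_sims=n_sims,
            seed=seed,
            re_rule=re_rule,
            overrides={moderator: g},
        )
        for g in grid
    ]
    return ModeratedEffects(moderator=moderator, grid=grid, estimates=estimates)
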
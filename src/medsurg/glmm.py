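"""Mixed-effects logistic regression with a single Gaussian random intercept.

Fits the mediator model logit P(M=1|T,X,v_s) = alpha'x + v_s and the outcome
model logit P(Y=1|T,M,X,u_s) = theta'x + u_s, with v_s, u_s ~ N(0, sigma^2)
per surgeon, by maximum (approximate) likelihood using adaptive Gauss-Hermite
quadrature over the random intercept. One quadrature point recovers the
Laplace approximation. The intra-cluster correlation is reported on the
latent log-odds scale, icc = sigma^2 / (sigma^2 + pi^2/3), the level-1
residual variance of the latent-variable formulation being pi^2/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .trial_data import TrialTable

PI2_3 = np.pi**2 / 3.0
_SIGMA_FLOOR = 1e-6
_SIGMA_ZERO = 1e-4  # below this, report sigma = 0 / icc = 0


class ModelError(RuntimeError):
    pass


class RankDeficiencyError(ModelError):
    pass


class SeparationError(ModelError):
    pass


# ---------------------------------------------------------------------------
# model terms and design matrices


@dataclass(frozen=True)
class GlmmSpec:
    """Which response to model and which fixed-effect terms to include.

    Terms are names resolved against the trial table: ``"T"``, ``"M"``,
    covariate names, and interactions written ``"A:B"`` (e.g. ``"T:M"``,
    ``"T:age"``). An intercept is always included. The outcome model carries
    the treatment-by-mediator interaction unless explicitly disabled.
    """

    response: str  # "mediator" or "outcome"
    terms: tuple = ()
    cluster: str = "cluster"

    def __post_init__(self):
        if self.response not in ("mediator", "outcome"):
            raise ValueError("response must be 'mediator' or 'outcome'")
        object.__setattr__(self, "terms", tuple(self.terms))
        if self.response == "mediator":
            for t in self.terms:
                if t == "M" or t.startswith("M:") or t.endswith(":M"):
                    raise ValueError("mediator model cannot contain M terms")

    @classmethod
    def mediator(cls, covariates=()) -> "GlmmSpec":
        return cls(response="mediator", terms=("T", *covariates))

    @classmethod
    def outcome(cls, covariates=(), interaction: bool = True) -> "GlmmSpec":
        terms = ["T", "M"]
        if interaction:
            terms.append("T:M")
        terms.extend(covariates)
        return cls(response="outcome", terms=tuple(terms))

    @property
    def response_column(self) -> str:
        return "M" if self.response == "mediator" else "Y"

    @property
    def names(self) -> tuple:
        return ("Intercept", *self.terms)


def _resolve(df: pd.DataFrame, name: str, overrides: dict) -> np.ndarray:
    if name in overrides:
        v = overrides[name]
        return np.broadcast_to(np.asarray(v, float), (len(df),)).copy()
    if name not in df.columns:
        raise ModelError(f"term {name!r} not found in trial table")
    return df[name].to_numpy(float)


def build_design(df: pd.DataFrame, terms, overrides: dict | None = None) -> np.ndarray:
    """Design matrix for the given terms (intercept first); ``overrides``
    substitutes columns (e.g. forcing T=1 or M=0 for potential outcomes)."""
    overrides = overrides or {}
    cols = [np.ones(len(df))]
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(_resolve(df, a, overrides) * _resolve(df, b, overrides))
        else:
            cols.append(_resolve(df, term, overrides))
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[j] for j in range(len(diag)) if diag[j] < tol]
    if bad:
        raise RankDeficiencyError(f"design matrix rank-deficient; aliased columns: {bad}")


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite likelihood


class _AGQProblem:
    """Negative log-likelihood and gradient for (beta, log sigma).

    The random intercept is integrated cluster-by-cluster with quadrature
    nodes recentred at the conditional mode and rescaled by the conditional
    curvature; the gradient treats the adapted nodes as fixed (the node
    dependence vanishes as the quadrature becomes exact).
    """

    def __init__(self, y, X, codes, n_clusters, quad_points):
        # rows sorted by cluster so per-cluster sums are contiguous reduceats
        order = np.argsort(codes, kind="stable")
        self.y = np.ascontiguousarray(y[order])
        self.X = np.ascontiguousarray(X[order])
        codes_s = codes[order]
        self.S = n_clusters
        counts = np.bincount(codes_s, minlength=n_clusters)
        self.counts = counts
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.starts = np.minimum(starts, max(len(y) - 1, 0))  # guard empty tail cluster
        self.occupied = counts > 0  # empty clusters contribute nothing
        nodes, weights = np.polynomial.hermite.hermgauss(quad_points)
        self.a = nodes
        self.logw = np.log(weights) + nodes**2
        self.modes = np.zeros(n_clusters)

    def _csum(self, v):
        out = np.add.reduceat(v, self.starts, axis=0)
        if not self.occupied.all():
            out[~self.occupied] = 0.0
        return out

    def adapt(self, params) -> float:
        """Recentre/rescale the nodes at the conditional modes for ``params``.

        Returns the largest mode shift, so the outer loop can detect that the
        adaptation has stabilised. Between calls the nodes stay frozen and
        :meth:`nll_grad` is the exact gradient of the frozen-node objective.
        """
        y = self.y
        beta = params[:-1]
        sigma = np.exp(params[-1])
        xb = self.X @ beta
        z = self.modes.copy()
        for _ in range(50):
            eta = xb + sigma * np.repeat(z, self.counts)
            p = expit(eta)
            g1 = sigma * self._csum(y - p) - z
            g2 = -(sigma**2) * self._csum(p * (1 - p)) - 1.0
            z = z - np.clip(g1 / g2, -4.0, 4.0)
            if np.max(np.abs(g1)) < 1e-10:
                break
        shift = float(np.max(np.abs(z - self.modes))) if self.S else 0.0
        self.modes = z
        eta = xb + sigma * np.repeat(z, self.counts)
        p = expit(eta)
        h = (sigma**2) * self._csum(p * (1 - p)) + 1.0  # curvature at the mode
        tau = 1.0 / np.sqrt(h)
        self.Z = z[:, None] + np.sqrt(2.0) * tau[:, None] * self.a[None, :]  # (S, K)
        self.Zobs = np.repeat(self.Z, self.counts, axis=0)  # (n, K)
        self.log_scale = float(np.sum(np.log(np.sqrt(2.0) * tau)))
        return shift

    def nll_grad_adaptive(self, params):
        """Re-adapt the nodes at ``params``, then evaluate.

        Robust for the global search (the objective cannot run away from its
        adaptation point); its gradient is exact only up to the node
        dependence, so the final convergence is established by the
        self-consistency loop in the fitter.
        """
        self.adapt(params)
        return self.nll_grad(params)

    def nll_grad(self, params):
        """Negative log-likelihood and exact gradient at the current nodes."""
        y = self.y
        beta = params[:-1]
        sigma = np.exp(params[-1])
        xb = self.X @ beta
        eta = xb[:, None] + sigma * self.Zobs
        P = expit(eta)
        resid = y[:, None] - P
        ll = y[:, None] * eta - np.logaddexp(0.0, eta)
        G = self._csum(ll) - 0.5 * self.Z**2
        A = self.logw[None, :] + G
        amax = A.max(axis=1, keepdims=True)
        expA = np.exp(A - amax)
        denom = expA.sum(axis=1)
        loglik = float(
            np.sum(np.log(denom) + amax[:, 0]) + self.log_scale
            - self.S * 0.5 * np.log(2.0 * np.pi)
        )
        q = expA / denom[:, None]  # (S, K) posterior-ish quadrature weights

        wr = (np.repeat(q, self.counts, axis=0) * resid).sum(axis=1)
        grad_beta = self.X.T @ wr
        # d/dlog sigma: sum_s sum_k q_sk * sigma * z_sk * sum_{i in s}(y - p_k)
        grad_ls = float(np.sum(q * sigma * self.Z * self._csum(resid)))
        grad = -np.concatenate([grad_beta, [grad_ls]])
        return -loglik, grad


@dataclass
class GlmmFit:
    """Fitted random-intercept logistic model."""

    spec: GlmmSpec
    coefficients: dict
    vcov: np.ndarray
    sigma: float
    cluster_modes: dict
    loglik: float
    converged: bool
    n_used: int
    quad_points: int
    names: tuple = field(init=False)

    def __post_init__(self):
        self.names = tuple(self.coefficients)

    @property
    def coef_array(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))

    @property
    def icc(self) -> float:
        return self.sigma**2 / (self.sigma**2 + PI2_3)

    def se(self) -> dict:
        s = np.sqrt(np.diag(self.vcov))
        return dict(zip(self.names, s))

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "terms": list(self.spec.terms),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "vcov": self.vcov.tolist(),
            "sigma": float(self.sigma),
            "icc": float(self.icc),
            "cluster_modes": {k: float(v) for k, v in self.cluster_modes.items()},
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_used": int(self.n_used),
            "quad_points": int(self.quad_points),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GlmmFit":
        return cls(
            spec=GlmmSpec(response=d["response"], terms=tuple(d["terms"])),
            coefficients=dict(d["coefficients"]),
            vcov=np.asarray(d["vcov"], float),
            sigma=float(d["sigma"]),
            cluster_modes=dict(d["cluster_modes"]),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n_used=int(d["n_used"]),
            quad_points=int(d["quad_points"]),
        )


def _fit_core(y, X, codes, n_clusters, quad_points, tol, start=None, max_iter=300):
    """Array-level fit; returns (params, nll, problem, success, transform).

    Covariate columns are centred and scaled internally (the optimiser sees a
    well-conditioned problem); returned parameters are on the original scale.
    ``transform`` is the (p+1)x(p+1) matrix mapping internal to external
    parameters, used to map the internal covariance back.
    """
    p = X.shape[1]
    mu = X[:, 1:].mean(axis=0) if p > 1 else np.zeros(0)
    sd = X[:, 1:].std(axis=0) if p > 1 else np.zeros(0)
    sd = np.where(sd > 0, sd, 1.0)
    Xc = X.copy()
    Xc[:, 1:] = (X[:, 1:] - mu) / sd
    # external = A @ internal (logsigma passes through)
    A = np.eye(p + 1)
    A[0, 1:p] = -mu / sd
    A[np.arange(1, p), np.arange(1, p)] = 1.0 / sd

    prob = _AGQProblem(y, Xc, codes, n_clusters, quad_points)
    if start is None:
        beta = np.zeros(p)
        # a few Newton steps of plain logistic for starting values
        for _ in range(8):
            eta = Xc @ beta
            m = expit(eta)
            W = m * (1 - m) + 1e-10
            g = Xc.T @ (y - m)
            H = (Xc * W[:, None]).T @ Xc
            try:
                beta = beta + np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
        beta = np.clip(beta, -15, 15)
        start_c = np.concatenate([beta, [np.log(0.5)]])
    else:
        # map external warm start to the internal scale
        ext = np.asarray(start, float)
        bc = ext[:p].copy()
        bc[1:] = bc[1:] * sd
        bc[0] = ext[0] + float(mu @ ext[1:p])
        start_c = np.concatenate([bc, [ext[p]]])
    lo = np.array([-40.0] * p + [np.log(_SIGMA_FLOOR)])
    hi = np.array([40.0] * p + [np.log(50.0)])
    lo_ls = lo[-1]

    def masked_gmax(xv, gv):
        m = np.abs(gv).max() if xv[-1] > lo_ls + 1e-8 or gv[-1] <= 0 else np.abs(gv[:-1]).max(initial=0.0)
        return float(m)

    # The estimate is defined as the root of the adaptive-quadrature score
    # (gradient with the nodes re-adapted at every evaluation). Damped Newton
    # root-finding on that field, backtracking on the score norm; a large
    # objective increase is rejected as a safeguard against runaway steps.
    def _solve(x0):
        return _newton_root(prob, x0, lo, hi, masked_gmax, tol, max_iter)

    x, nll, grad, converged = _solve(np.clip(start_c, lo, hi))
    if np.exp(x[-1]) < 0.05:
        # the log-sigma score vanishes as sigma -> 0, so a trajectory that
        # dips early can be declared converged at the floor even when a
        # positive-sigma root fits far better; probe and re-solve if so
        best = None
        for s_try in (0.5, 1.0, 2.0):
            xp = x.copy()
            xp[-1] = np.log(s_try)
            nll_p, _ = prob.nll_grad_adaptive(xp)
            if nll_p < nll - 1e-8 and (best is None or nll_p < best[1]):
                best = (xp, nll_p)
        if best is not None:
            x2, nll2, grad2, conv2 = _solve(best[0])
            if nll2 < nll:
                x, nll, grad, converged = x2, nll2, grad2, conv2
    gtol_abs = max(10 * tol, 1e-5) * (1.0 + abs(nll))
    success = converged or masked_gmax(x, grad) < gtol_abs
    params = np.empty(p + 1)
    params[:p] = A[:p, :p] @ x[:p]
    params[p] = x[p]
    return _CoreFit(params, nll, prob, success, A, x)


def _newton_root(prob, x, lo, hi, masked_gmax, tol, max_iter):
    p = len(x) - 1
    nll, grad = prob.nll_grad_adaptive(x)
    gtol_abs = max(10 * tol, 1e-5) * (1.0 + abs(nll))
    converged = False
    for _ in range(max_iter):
        gmax = masked_gmax(x, grad)
        if gmax < gtol_abs:
            converged = True
            break
        # drop the log-sigma direction when sigma sits at its floor and the
        # score there is (near) flat or points below the floor
        free = np.ones(p + 1, bool)
        if x[-1] <= lo[-1] + 1e-8 and grad[-1] > -1e-3:
            free[-1] = False
        idx_free = np.nonzero(free)[0]
        J = np.empty((len(idx_free), p + 1))
        h = 1e-6 * (1.0 + np.abs(x))
        for r, j in enumerate(idx_free):
            xp = x.copy()
            xp[j] += h[j]
            _, gp = prob.nll_grad_adaptive(xp)
            J[r] = (gp - grad) / h[j]
        Jf = J[:, idx_free].T  # d score_i / d x_j on the free block
        step = np.zeros(p + 1)
        try:
            step[idx_free] = np.linalg.solve(Jf, -grad[idx_free])
        except np.linalg.LinAlgError:
            step[idx_free], *_ = np.linalg.lstsq(Jf, -grad[idx_free], rcond=None)
        norm = np.max(np.abs(step))
        if norm > 2.0:
            step *= 2.0 / norm
        moved = False
        for damp in (1.0, 0.5, 0.25, 0.1, 0.03, 0.01):
            xn = np.clip(x + damp * step, lo, hi)
            nll_n, grad_n = prob.nll_grad_adaptive(xn)
            if masked_gmax(xn, grad_n) < gmax and nll_n < nll + 0.5:
                x, nll, grad = xn, nll_n, grad_n
                moved = True
                break
        if not moved:
            # steepest-descent rescue on the objective, then resume Newton
            sd = -grad / max(np.abs(grad).max(), 1.0)
            for damp in (0.5, 0.1, 0.02):
                xn = np.clip(x + damp * sd, lo, hi)
                nll_n, grad_n = prob.nll_grad_adaptive(xn)
                if nll_n < nll - 1e-10:
                    x, nll, grad = xn, nll_n, grad_n
                    moved = True
                    break
        if not moved:
            break
    return x, nll, grad, converged



@dataclass
class _CoreFit:
    params: np.ndarray  # external scale, (beta..., log sigma)
    nll: float
    prob: "_AGQProblem"
    success: bool
    transform: np.ndarray
    params_internal: np.ndarray


def _numerical_vcov(prob, params):
    p = len(params)
    H = np.zeros((p, p))
    h = 1e-5 * (1.0 + np.abs(params))
    for j in range(p):
        up = params.copy()
        dn = params.copy()
        up[j] += h[j]
        dn[j] -= h[j]
        _, gu = prob.nll_grad_adaptive(up)
        _, gd = prob.nll_grad_adaptive(dn)
        H[:, j] = (gu - gd) / (2 * h[j])
    H = 0.5 * (H + H.T)
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.linalg.pinv(H)
    return V


def fit_glmm(
    table: TrialTable,
    spec: GlmmSpec,
    quad_points: int = 7,
    tol: float = 1e-7,
    start: np.ndarray | None = None,
    max_iter: int = 200,
    compute_vcov: bool = True,
) -> GlmmFit:
    """Maximum-likelihood fit by adaptive Gauss-Hermite quadrature.

    ``quad_points=1`` is the Laplace approximation. A non-converged optimiser
    yields ``converged=False``, never an exception; rank deficiency and
    apparent complete separation raise :class:`ModelError`. When the
    random-intercept SD estimate hits its lower floor the fit coincides with
    ordinary logistic regression and is reported with sigma = 0, icc = 0.
    """
    df = table.df
    y = df[spec.response_column].to_numpy(float)
    X = build_design(df, spec.terms)
    names = spec.names
    _check_rank(X, names)
    labels, codes = np.unique(df[spec.cluster].astype(str).to_numpy(), return_inverse=True)

    core = _fit_core(
        y, X, codes, len(labels), quad_points, tol, start=start, max_iter=max_iter
    )
    beta = core.params[:-1]
    sigma = float(np.exp(core.params[-1]))
    nll, success = core.nll, core.success
    if np.max(np.abs(beta)) > 25.0:
        raise SeparationError(
            "coefficient diverged; data look completely separated "
            "(penalised logistic regression is out of scope)"
        )
    if compute_vcov:
        V_int = _numerical_vcov(core.prob, core.params_internal)
        A = core.transform
        V_full = A @ V_int @ A.T
        vcov = V_full[: len(beta), : len(beta)]
    else:
        vcov = np.full((len(beta), len(beta)), np.nan)
    if sigma < _SIGMA_ZERO:
        sigma = 0.0
    modes = sigma * core.prob.modes
    return GlmmFit(
        spec=spec,
        coefficients=dict(zip(names, beta)),
        vcov=vcov,
        sigma=sigma,
        cluster_modes={str(lab): float(m) for lab, m in zip(labels, modes)},
        loglik=-nll,
        converged=success,
        n_used=len(y),
        quad_points=quad_points,
    )


def loglik_at(table: TrialTable, spec: GlmmSpec, beta, sigma, quad_points: int = 7) -> float:
    """Approximate log-likelihood at supplied parameters (diagnostics)."""
    df = table.df
    y = df[spec.response_column].to_numpy(float)
    X = build_design(df, spec.terms)
    labels, codes = np.unique(df[spec.cluster].astype(str).to_numpy(), return_inverse=True)
    prob = _AGQProblem(y, X, codes, len(labels), quad_points)
    params = np.concatenate([np.asarray(beta, float), [np.log(max(sigma, _SIGMA_FLOOR))]])
    prob.adapt(params)
    nll, _ = prob.nll_grad(params)
    return -nll


def odds_ratio_table(fit: GlmmFit, level: float = 0.95) -> pd.DataFrame:
    """Per-term odds ratios with Wald confidence intervals.

    OR = exp(coef); CI = exp(coef +/- z * SE). The ICC is attached as a
    DataFrame attribute for report rendering, not as a table row.
    """
    if not fit.converged:
        raise ModelError("odds ratios requested from a non-converged fit")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    se = fit.se()
    rows = []
    for name, coef in fit.coefficients.items():
        s = se[name]
        rows.append(
            {
                "term": name,
                "odds_ratio": np.exp(coef),
                "ci_low": np.exp(coef - z * s),
                "ci_high": np.exp(coef + z * s),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["icc"] = fit.icc
    out.attrs["level"] = level
    return out


def predict_prob(
    fit: GlmmFit,
    table: TrialTable,
    t: float | np.ndarray | None = None,
    m: float | np.ndarray | None = None,
    random_intercept: str = "zero",
    seed: int | None = None,
) -> np.ndarray:
    """Per-record success probability with T and/or M optionally overridden.

    ``random_intercept``: ``"zero"`` (marginal at v=0), ``"draw"`` (fresh
    N(0, sigma^2) draw per record, needs ``seed``), or ``"mode"`` (each
    record's own cluster posterior mode).
    """
    overrides = {}
    if t is not None:
        overrides["T"] = t
    if m is not None:
        overrides["M"] = m
    X = build_design(table.df, fit.spec.terms, overrides)
    eta = X @ fit.coef_array
    if random_intercept == "zero":
        pass
    elif random_intercept == "draw":
        rng = np.random.default_rng(seed)
        eta = eta + rng.normal(0.0, fit.sigma, size=len(eta))
    elif random_intercept == "mode":
        labs = table.df["cluster"].astype(str)
        unknown = set(labs.unique()) - set(fit.cluster_modes)
        if unknown:
            raise ModelError(
                f"clusters {sorted(unknown)} unseen by the fit; use 'draw' or 'zero'"
            )
        eta = eta + labs.map(fit.cluster_modes).to_numpy(float)
    else:
        raise ValueError(f"unknown random-intercept rule {random_intercept!r}")
    return expit(eta)
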
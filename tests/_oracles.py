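"""Independent oracles the implementation is checked against.

Everything here is deliberately written from scratch against the model
definitions (closed forms, enumeration, plain Newton iterations) and shares
no code with the package internals.
"""

import numpy as np
from scipy.special import expit, logit

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(60)


def gauss_mean_expit(lp, sigma):
    """E[expit(lp + sigma*Z)], Z ~ N(0,1), by 60-point Gauss-Hermite."""
    if sigma == 0:
        return expit(lp)
    z = np.sqrt(2.0) * sigma * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    return float(np.sum(w * expit(lp + z)))


def covfree_cells(a0, a1, sv, t0, t1, t2, t3, su):
    """Exact potential-outcome cell means P(t, t') for covariate-free models.

    The mediator and outcome random intercepts are independent, so
    P(t,t') = P_M(t') * P_Y(t, m=1) + (1 - P_M(t')) * P_Y(t, m=0), each
    factor a logistic-normal mean.
    """
    pm = {t: gauss_mean_expit(a0 + a1 * t, sv) for t in (0, 1)}
    py = {
        (t, m): gauss_mean_expit(t0 + t1 * t + t2 * m + t3 * t * m, su)
        for t in (0, 1)
        for m in (0, 1)
    }
    cells = np.empty((2, 2))
    for t in (0, 1):
        for tp in (0, 1):
            cells[t, tp] = pm[tp] * py[(t, 1)] + (1 - pm[tp]) * py[(t, 0)]
    cde = {m: py[(1, m)] - py[(0, m)] for m in (0, 1)}
    return cells, cde


def covfree_effects(a0, a1, sv, t0, t1, t2, t3, su):
    c, cde = covfree_cells(a0, a1, sv, t0, t1, t2, t3, su)
    d0, d1 = c[0, 1] - c[0, 0], c[1, 1] - c[1, 0]
    z0, z1 = c[1, 0] - c[0, 0], c[1, 1] - c[0, 1]
    return {
        "delta0": d0, "delta1": d1, "delta_avg": (d0 + d1) / 2,
        "zeta0": z0, "zeta1": z1, "zeta_avg": (z0 + z1) / 2,
        "tau": c[1, 1] - c[0, 0], "cde_m0": cde[0], "cde_m1": cde[1],
    }


def newton_logistic(y, X, max_iter=60, tol=1e-12):
    """Plain logistic regression by Newton-Raphson (no random effects)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p) + 1e-12
        g = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(X @ beta)
    vcov = np.linalg.inv((X * (p * (1 - p))[:, None]).T @ X)
    return beta, vcov


def enumerate_discrete_u(a0, a1, g, t0, t1, t2, t3, b):
    """Exact confounded world with U in {-1, +1} (mean 0, variance 1).

    True structural models:
        logit P(M=1 | T, U) = a0 + a1 T + g U
        logit P(Y=1 | T, M, U) = t0 + t1 T + t2 M + t3 T M + b U

    Returns the infinite-data ('observed') marginal model coefficients a
    naive analysis would fit, the implied lambda contrasts, the exact natural
    effects, and the naive (confounded) estimates.
    """
    Us = np.array([-1.0, 1.0])
    pm = {t: {u: expit(a0 + a1 * t + g * u) for u in Us} for t in (0, 1)}
    py = {
        (t, m): {u: expit(t0 + t1 * t + t2 * m + t3 * t * m + b * u) for u in Us}
        for t in (0, 1)
        for m in (0, 1)
    }
    pm_marg = {t: 0.5 * (pm[t][-1.0] + pm[t][1.0]) for t in (0, 1)}
    ah0 = logit(pm_marg[0])
    ah1 = logit(pm_marg[1]) - ah0

    pobs, e_u = {}, {}
    for t in (0, 1):
        for m in (0, 1):
            w = np.array([0.5 * (pm[t][u] if m == 1 else 1 - pm[t][u]) for u in Us])
            w = w / w.sum()
            pobs[(t, m)] = float(sum(w[i] * py[(t, m)][u] for i, u in enumerate(Us)))
            e_u[(t, m)] = float(w @ Us)
    th0 = logit(pobs[(0, 0)])
    th1 = logit(pobs[(1, 0)]) - th0
    th2 = logit(pobs[(0, 1)]) - th0
    th3 = logit(pobs[(1, 1)]) - th0 - th1 - th2
    lam_t = {t: e_u[(t, 1)] - e_u[(t, 0)] for t in (0, 1)}
    lam0 = lam_t[0]
    lam1 = lam_t[1] - lam_t[0]

    cells = np.empty((2, 2))
    for t in (0, 1):
        for tp in (0, 1):
            cells[t, tp] = sum(
                0.5 * (pm[tp][u] * py[(t, 1)][u] + (1 - pm[tp][u]) * py[(t, 0)][u])
                for u in Us
            )
    naive = np.empty((2, 2))
    for t in (0, 1):
        for tp in (0, 1):
            naive[t, tp] = (
                pm_marg[tp] * pobs[(t, 1)] + (1 - pm_marg[tp]) * pobs[(t, 0)]
            )

    def _eff(c):
        return {
            "zeta_avg": ((c[1, 0] - c[0, 0]) + (c[1, 1] - c[0, 1])) / 2,
            "delta_avg": ((c[0, 1] - c[0, 0]) + (c[1, 1] - c[1, 0])) / 2,
            "tau": c[1, 1] - c[0, 0],
        }

    return {
        "observed_med_coefs": (ah0, ah1),
        "observed_out_coefs": (th0, th1, th2, th3),
        "pm_marg": pm_marg,
        "lambda0": lam0,
        "lambda1": lam1,
        "true": _eff(cells),
        "naive": _eff(naive),
    }
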
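import numpy as np
import pytest

import medsurg as ms

AMAZE_COVS = ("age", "baseline_sr")


@pytest.fixture(scope="session")
def amaze_trial():
    """One realisation of the default trial conditions."""
    return ms.generate_trial(ms.amaze_like(seed=3))


@pytest.fixture(scope="session")
def amaze_fits(amaze_trial):
    med = ms.fit_glmm(amaze_trial.table, ms.GlmmSpec.mediator(AMAZE_COVS))
    out = ms.fit_glmm(amaze_trial.table, ms.GlmmSpec.outcome(AMAZE_COVS))
    return med, out


@pytest.fixture(scope="session")
def null_trial():
    """Covariate-free global-null trial (no treatment or mediator effects)."""
    cfg = ms.GeneratorConfig.null(
        n_patients=160, n_clusters=8, sigma_v=0.7, sigma_u=0.5, seed=11
    )
    return ms.generate_trial(cfg)


def make_covfree_fit(response, coefs, sigma, interaction=True):
    """Hand-build a GlmmFit with known coefficients (no fitting involved)."""
    if response == "mediator":
        spec = ms.GlmmSpec.mediator(())
    else:
        spec = ms.GlmmSpec.outcome((), interaction=interaction)
    names = spec.names
    assert len(coefs) == len(names)
    return ms.GlmmFit(
        spec=spec,
        coefficients=dict(zip(names, map(float, coefs))),
        vcov=np.zeros((len(names), len(names))),
        sigma=float(sigma),
        cluster_modes={},
        loglik=0.0,
        converged=True,
        n_used=0,
        quad_points=7,
    )


def make_table(n0=60, n1=60, m0=20, m1=35, y0=25, y1=40, n_clusters=4, covs=None):
    """Deterministic table with exact arm counts of M and Y."""
    import pandas as pd

    rows = []
    for arm, (n, m, y) in enumerate([(n0, m0, y0), (n1, m1, y1)]):
        for i in range(n):
            rows.append(
                {
                    "Y": 1 if i < y else 0,
                    "M": 1 if i < m else 0,
                    "T": arm,
                    "cluster": f"c{i % n_clusters + 1}",
                }
            )
    df = pd.DataFrame(rows)
    covariates = {}
    if covs:
        rng = np.random.default_rng(0)
        for name in covs:
            df[name] = rng.normal(0, 1, len(df))
            covariates[name] = "continuous"
    return ms.TrialTable(df=df, covariates=covariates)
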
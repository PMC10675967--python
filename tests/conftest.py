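"""Shared helpers for the test suite.

The central tool is an *independent* reference solver for the elastic-net
objective: scipy's L-BFGS-B applied to the split-variable formulation
(beta = u - v with u, v >= 0), which turns the non-smooth L1 problem into a
smooth bound-constrained one. The package's coordinate-descent solver is
then checked against this oracle on random instances.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from clusterlasso.data import ClusteredDataset, GAUSSIAN, BINOMIAL


# ---------------------------------------------------------------------------
# dataset construction helpers
# ---------------------------------------------------------------------------

def make_dataset(
    X,
    y,
    cluster=None,
    family: str = GAUSSIAN,
    standardized: bool = True,
    var_names=None,
) -> ClusteredDataset:
    """Build a ClusteredDataset from raw arrays with sensible defaults."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if cluster is None:
        cluster = np.zeros(n, dtype=int)
    if var_names is None:
        var_names = [f"x{j}" for j in range(p)]
    return ClusteredDataset(
        X=X,
        y=np.asarray(y, dtype=float),
        cluster=np.asarray(cluster),
        var_names=list(var_names),
        family=family,
        standardized=standardized,
    )


def random_instance(
    rng: np.random.Generator,
    n: int,
    p: int,
    family: str = GAUSSIAN,
    n_clusters: int = 1,
    signal: float = 1.0,
) -> ClusteredDataset:
    """Small random scaled instance for solver cross-checks."""
    X = rng.standard_normal((n, p))
    X = X / X.std(axis=0)
    beta = np.zeros(p)
    k = max(1, p // 2)
    beta[rng.choice(p, size=k, replace=False)] = signal * rng.standard_normal(k)
    cluster = rng.integers(n_clusters, size=n)
    eta = X @ beta + 0.3 * rng.standard_normal(n)
    if family == GAUSSIAN:
        y = eta
    else:
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        if y.sum() in (0, len(y)):  # force both classes to be present
            y[0] = 1.0 - y[0]
    return make_dataset(X, y, cluster=cluster, family=family)


# ---------------------------------------------------------------------------
# independent elastic-net oracle (scipy L-BFGS-B, split variables)
# ---------------------------------------------------------------------------

def enet_oracle(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    family: str = GAUSSIAN,
    x0: np.ndarray | None = None,
):
    """Minimize nll(b0, X beta) + lam*(alpha*||beta||_1 + (1-alpha)/2*||beta||^2)
    with nll = (1/2n)*RSS (gaussian) or (1/n)*sum[log(1+e^eta) - y*eta]
    (binomial), via the smooth split beta = u - v, u, v >= 0.

    Returns (objective, intercept, beta).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    def unpack(z):
        return z[0], z[1 : 1 + p], z[1 + p :]

    def fun_grad(z):
        b0, u, v = unpack(z)
        beta = u - v
        eta = b0 + X @ beta
        if family == GAUSSIAN:
            r = eta - y
            nll = 0.5 * float(r @ r) / n
            geta = r / n
        else:
            # log(1+e^eta) evaluated stably
            nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
            geta = (1.0 / (1.0 + np.exp(-eta)) - y) / n
        gbeta = X.T @ geta
        ridge = lam * (1.0 - alpha) * beta
        f = nll + lam * (alpha * float(np.sum(u + v)) + 0.5 * (1 - alpha) * float(beta @ beta))
        g = np.concatenate(
            [[float(np.sum(geta))], gbeta + lam * alpha + ridge, -gbeta + lam * alpha - ridge]
        )
        return f, g

    if x0 is None:
        x0 = np.zeros(1 + 2 * p)
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    res = minimize(
        fun_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 20000, "maxfun": 100000, "ftol": 1e-16, "gtol": 1e-12},
    )
    b0, u, v = unpack(res.x)
    beta = u - v
    # objective without the split-variable overshoot min(u, v) > 0
    eta = b0 + X @ beta
    if family == GAUSSIAN:
        nll = 0.5 * float(np.sum((eta - y) ** 2)) / n
    else:
        nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    obj = nll + lam * (
        alpha * float(np.sum(np.abs(beta))) + 0.5 * (1 - alpha) * float(beta @ beta)
    )
    return obj, float(b0), beta


def enet_oracle_polished(X, y, lam, alpha, family=GAUSSIAN) -> float:
    """Two-stage oracle objective: a cold L-BFGS-B run followed by a restart
    from the cleanly re-split solution (u = beta+, v = beta-), which removes
    the residual split-variable drift. Returns the better objective."""
    obj1, b0, beta = enet_oracle(X, y, lam, alpha, family)
    x0 = np.concatenate([[b0], np.maximum(beta, 0.0), np.maximum(-beta, 0.0)])
    obj2, _, _ = enet_oracle(X, y, lam, alpha, family, x0=x0)
    return min(obj1, obj2)


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230913)
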
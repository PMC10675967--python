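"""Fixed-effects penalized regression by cyclic coordinate descent.

Implements the two cluster-ignoring model variants: *no hosps* (predictors
only) and *hosps fixed* (hospital indicator columns appended to the design),
for Gaussian and binomial outcomes, over a descending penalty path with warm
starts. The objective is

    -(1/n) loglik(family)  +  lam * [ alpha * ||beta||_1 + (1-alpha)/2 * ||beta||_2^2 ]

with an unpenalized intercept. ``alpha=1`` is the LASSO; ``alpha=0.99999``
is the near-LASSO elastic net used as a robustness variant. The binomial
family is handled by an IRLS outer loop around the weighted Gaussian
coordinate-descent kernel. *post* estimates refit an unpenalized model on
the selected support (relaxed LASSO).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ClusteredDataset, GAUSSIAN, BINOMIAL

# convergence constants
CD_TOL = 1e-7          # max |coefficient change| between sweeps
CD_MAX_SWEEPS = 100_000
IRLS_TOL = 1e-8        # relative deviance change
IRLS_MAX_ITER = 200
WEIGHT_FLOOR = 1e-5    # working-weight floor near fitted probabilities 0/1
ETA_GUARD = 30.0       # |linear predictor| beyond which lam=0 binomial fits
                       # are declared separated


class SeparationError(RuntimeError):
    """Unpenalized binomial fit is diverging (complete separation)."""


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -ETA_GUARD, ETA_GUARD)))


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@dataclass
class FitResult:
    """One fitted model at one penalty value.

    ``beta`` holds the predictor coefficients (standardized scale).
    Hospital effects, when present, live in ``cluster_effects`` aligned with
    ``cluster_labels``: penalized dummy coefficients for the fixed variant
    (reference hospital = first sorted label, effect 0), predicted random
    intercepts for the mixed variant.
    """

    intercept: float
    beta: np.ndarray
    var_names: list[str]
    family: str
    lam: float
    alpha: float
    cluster_labels: np.ndarray | None = None
    cluster_effects: np.ndarray | None = None
    cluster_kind: str = "none"  # none | dummy | random
    tau: float = 0.0
    phi: float | None = None
    df: int = 0
    loglik: float = math.nan
    aic: float = math.nan
    bic: float = math.nan
    estimator: str = "classic"
    converged: bool = True
    n_iter: int = 0
    notes: str = ""

    @property
    def support(self) -> np.ndarray:
        """Indices of nonzero predictor coefficients."""
        return np.flatnonzero(self.beta)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.beta))


@dataclass
class PathResult:
    """Warm-started fits along a descending penalty grid."""

    lambdas: np.ndarray
    fits: list[FitResult]
    family: str

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": [f.lam for f in self.fits],
                "n_selected": [f.n_selected for f in self.fits],
                "df": [f.df for f in self.fits],
                "loglik": [f.loglik for f in self.fits],
                "aic": [f.aic for f in self.fits],
                "bic": [f.bic for f in self.fits],
                "tau": [f.tau for f in self.fits],
                "converged": [f.converged for f in self.fits],
            }
        )

    def coef_table(self) -> pd.DataFrame:
        """Coefficient paths (penalty x variable), for path plots."""
        rows = {f.lam: f.beta for f in self.fits}
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=self.fits[0].var_names
        ).rename_axis("lambda")


# ---------------------------------------------------------------------------
# coordinate-descent kernel (weighted gaussian working response)
# ---------------------------------------------------------------------------

def _cd_weighted(
    X: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    lam: float,
    alpha: float,
    beta: np.ndarray,
    intercept: float,
    penalized: np.ndarray,
    tol: float = CD_TOL,
    max_sweeps: int = CD_MAX_SWEEPS,
    dummy_start: int | None = None,
    dummy_groups: np.ndarray | None = None,
    block_ridge: float = 0.0,
) -> tuple[np.ndarray, float, bool, int]:
    """Minimize (1/2n) sum w_i (z_i - b0 - x_i beta)^2 + penalty(beta).

    Cyclic coordinate descent with soft-thresholding; the intercept is
    refreshed after every sweep. Sweeps alternate between the full column
    set and the current active set for speed; convergence is declared when a
    full sweep moves no coefficient by more than ``tol``.

    Columns from ``dummy_start`` on may be declared a block of disjoint
    0/1 indicators via ``dummy_groups`` (row -> block column offset, -1 for
    reference rows). Disjoint supports make their coordinate updates
    independent, so the whole block is updated in one vectorized pass.
    """
    n, p = X.shape
    Xw2 = (w[:, None] * X * X).sum(axis=0) / n
    wsum = w.sum()
    r = z - intercept - X @ beta
    thr = lam * alpha
    ridge = lam * (1.0 - alpha)
    if dummy_start is not None:
        grp_rows = np.flatnonzero(dummy_groups >= 0)
        grp_idx = dummy_groups[grp_rows]
        G = p - dummy_start
        blk_pen = bool(penalized[dummy_start]) if G else True
        dense_cols = range(dummy_start)
    else:
        G = 0
        dense_cols = range(p)

    def block_update() -> float:
        # simultaneous soft-threshold update of all indicator coefficients
        bb = beta[dummy_start:]
        s = Xw2[dummy_start:]
        ok = s > 0
        g = np.bincount(grp_idx, weights=(w * r)[grp_rows], minlength=G) / n
        g = g + s * bb
        if blk_pen:
            bnew = np.sign(g) * np.maximum(np.abs(g) - thr, 0.0) / (s + ridge)
        else:
            # unpenalized indicators, or ridge-shrunken random intercepts
            denom = s + block_ridge
            bnew = np.divide(g, denom, out=np.zeros_like(g), where=denom > 0)
            if block_ridge == 0.0:
                bnew[~ok] = 0.0
        d = bnew - bb
        if np.any(d != 0.0):
            r[grp_rows] -= d[grp_idx]
            beta[dummy_start:] = bnew
            return float(np.max(np.abs(d)))
        return 0.0

    def sweep(cols) -> float:
        nonlocal intercept, r
        dmax = 0.0
        for j in cols:
            if Xw2[j] <= 0:
                beta[j] = 0.0  # constant-zero column cannot carry signal
                continue
            xj = X[:, j]
            g = (w * r) @ xj / n + Xw2[j] * beta[j]
            if penalized[j]:
                bj = _soft(g, thr) / (Xw2[j] + ridge)
            else:
                bj = g / Xw2[j]
            d = bj - beta[j]
            if d != 0.0:
                r -= d * xj
                beta[j] = bj
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
        if G:
            dmax = max(dmax, block_update())
        d0 = (w @ r) / wsum
        if d0 != 0.0:
            intercept += d0
            r -= d0
            if abs(d0) > dmax:
                dmax = abs(d0)
        return dmax

    n_sweeps = 0
    converged = False
    while n_sweeps < max_sweeps:
        dmax = sweep(dense_cols)
        n_sweeps += 1
        if dmax < tol:
            converged = True
            break
        active = np.flatnonzero(beta[: len(dense_cols)]).tolist()
        while n_sweeps < max_sweeps:
            dmax = sweep(active)
            n_sweeps += 1
            if dmax < tol:
                break
    return beta, intercept, converged, n_sweeps


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def dummy_matrix(
    cluster: np.ndarray, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-coded hospital indicators (first sorted label dropped)."""
    if labels is None:
        labels = np.unique(cluster)
    D = (cluster[:, None] == labels[None, 1:]).astype(float)
    return D, labels


def _augment(
    data: ClusteredDataset,
    include_cluster_dummies: bool,
    penalize_dummies: bool,
    dummy_labels: np.ndarray | None = None,
):
    if include_cluster_dummies:
        D, labels = dummy_matrix(data.cluster, dummy_labels)
        Xa = np.hstack([data.X, D])
        penalized = np.concatenate(
            [
                np.ones(data.p, dtype=bool),
                np.full(D.shape[1], penalize_dummies, dtype=bool),
            ]
        )
        # row -> dummy-column offset (-1 for the reference hospital)
        pos = np.searchsorted(labels, data.cluster)
        groups = pos - 1
        return Xa, penalized, labels, groups
    return data.X, np.ones(data.p, dtype=bool), None, None


# ---------------------------------------------------------------------------
# likelihood bookkeeping
# ---------------------------------------------------------------------------

def _gaussian_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    n = len(y)
    rss = float(np.sum((y - mu) ** 2))
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _binomial_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _finalize_ic(fit: FitResult, n: int) -> FitResult:
    fit.aic = -2.0 * fit.loglik + 2.0 * fit.df
    fit.bic = -2.0 * fit.loglik + math.log(n) * fit.df
    return fit


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_at_lambda(
    data: ClusteredDataset,
    lam: float,
    alpha: float = 1.0,
    include_cluster_dummies: bool = False,
    penalize_dummies: bool = True,
    init: FitResult | None = None,
    dummy_labels: np.ndarray | None = None,
) -> FitResult:
    """Fit the penalized model at one penalty value.

    ``init`` warm-starts the coordinates (used along a path). The intercept
    is never penalized; hospital dummies are penalized like ordinary
    predictors unless ``penalize_dummies=False``. ``dummy_labels`` fixes the
    hospital-indicator universe (used by cross-validation folds so that the
    dummy space matches the full training data).
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    y = data.y
    n, p = data.n, data.p
    Xa, penalized, labels, groups = _augment(
        data, include_cluster_dummies, penalize_dummies, dummy_labels
    )
    pa = Xa.shape[1]
    dummy_start = p if include_cluster_dummies else None

    beta = np.zeros(pa)
    intercept = float(np.mean(y)) if data.family == GAUSSIAN else 0.0
    if init is not None:
        beta[: len(init.beta)] = init.beta
        if include_cluster_dummies and init.cluster_effects is not None:
            beta[p:] = init.cluster_effects[1:]
        intercept = init.intercept

    if data.family == GAUSSIAN and lam == 0.0:
        # unpenalized least squares has a direct solution
        A = np.column_stack([np.ones(n), Xa])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        intercept, beta = float(coef[0]), coef[1:]
        converged, n_iter = True, 0
        loglik = _gaussian_loglik(y, intercept + Xa @ beta)
    elif data.family == GAUSSIAN:
        beta, intercept, converged, n_iter = _cd_weighted(
            Xa, y, np.ones(n), lam, alpha, beta, intercept, penalized,
            dummy_start=dummy_start, dummy_groups=groups,
        )
        mu = intercept + Xa @ beta
        loglik = _gaussian_loglik(y, mu)
    else:
        if init is None:
            pbar = float(np.clip(np.mean(y), 1e-6, 1 - 1e-6))
            intercept = math.log(pbar / (1 - pbar))
        converged = False
        n_iter = 0
        dev_old = math.inf
        for outer in range(IRLS_MAX_ITER):
            eta = intercept + Xa @ beta
            if lam == 0.0 and np.max(np.abs(eta)) >= ETA_GUARD:
                raise SeparationError(
                    "unpenalized binomial fit is diverging; data are separable"
                )
            prob = _sigmoid(eta)
            w = np.maximum(prob * (1 - prob), WEIGHT_FLOOR)
            z = eta + (y - prob) / w
            beta, intercept, _, sweeps = _cd_weighted(
                Xa, z, w, lam, alpha, beta, intercept, penalized,
                dummy_start=dummy_start, dummy_groups=groups,
            )
            n_iter += sweeps
            mu_new = _sigmoid(intercept + Xa @ beta)
            dev = -2.0 * _binomial_loglik(y, mu_new)
            if abs(dev_old - dev) < IRLS_TOL * (abs(dev) + 1.0):
                converged = True
                break
            dev_old = dev
        loglik = _binomial_loglik(y, _sigmoid(intercept + Xa @ beta))

    fit = FitResult(
        intercept=float(intercept),
        beta=beta[:p].copy(),
        var_names=list(data.var_names),
        family=data.family,
        lam=float(lam),
        alpha=float(alpha),
        df=int(np.count_nonzero(beta)) + 1,
        loglik=loglik,
        converged=bool(converged),
        n_iter=int(n_iter),
    )
    if include_cluster_dummies:
        fit.cluster_kind = "dummy"
        fit.cluster_labels = labels
        fit.cluster_effects = np.concatenate([[0.0], beta[p:]])
    return _finalize_ic(fit, n)


def fit_path(
    data: ClusteredDataset,
    lambdas: np.ndarray,
    alpha: float = 1.0,
    include_cluster_dummies: bool = False,
    penalize_dummies: bool = True,
    dummy_labels: np.ndarray | None = None,
) -> PathResult:
    """Warm-started fits down a descending penalty sequence."""
    lambdas = np.asarray(lambdas, dtype=float)
    fits: list[FitResult] = []
    init = None
    for lam in lambdas:
        fit = fit_at_lambda(
            data,
            lam,
            alpha=alpha,
            include_cluster_dummies=include_cluster_dummies,
            penalize_dummies=penalize_dummies,
            init=init,
            dummy_labels=dummy_labels,
        )
        fits.append(fit)
        init = fit
    return PathResult(lambdas=lambdas, fits=fits, family=data.family)


def post_lasso_refit(data: ClusteredDataset, fit: FitResult) -> FitResult:
    """Relaxed-LASSO step: unpenalized refit on the selected support.

    Coefficients outside the support stay exactly zero; hospital dummies,
    when the variant includes them, are refitted unpenalized alongside the
    active predictors. A separating binomial refit falls back to the
    penalized estimates with a note.
    """
    active = fit.support
    sub = data.subset_cols(active) if len(active) < data.p else data
    include_dummies = fit.cluster_kind == "dummy"
    try:
        refit = fit_at_lambda(
            sub,
            lam=0.0,
            alpha=1.0,
            include_cluster_dummies=include_dummies,
            penalize_dummies=False,
        )
    except SeparationError:
        out = replace(fit, estimator="post", converged=False)
        out.notes = "post refit separated; penalized estimates retained"
        return out
    beta = np.zeros(data.p)
    beta[active] = refit.beta
    out = replace(
        refit,
        beta=beta,
        var_names=list(data.var_names),
        lam=fit.lam,
        alpha=fit.alpha,
        estimator="post",
    )
    return _finalize_ic(out, data.n)


def predict(
    fit: FitResult,
    newX: np.ndarray,
    new_cluster: np.ndarray | None = None,
) -> np.ndarray:
    """Predictions on the model scale: the (log) outcome mean for gaussian,
    event probabilities for binomial. Hospital effects are applied when the
    fit carries them; an unknown hospital is an error because the
    subsampling design guarantees every test hospital was seen in training.
    """
    eta = fit.intercept + np.asarray(newX, dtype=float) @ fit.beta
    if fit.cluster_kind != "none":
        if new_cluster is None:
            raise ValueError("this fit carries hospital effects; pass new_cluster")
        labels = fit.cluster_labels
        pos = np.searchsorted(labels, new_cluster)
        pos_clipped = np.clip(pos, 0, len(labels) - 1)
        bad = labels[pos_clipped] != np.asarray(new_cluster)
        if bad.any():
            unknown = sorted(set(np.asarray(new_cluster)[bad].tolist()))
            raise KeyError(
                f"hospitals {unknown} were not in the training data; the "
                "subsampling constraint requires every test hospital in train"
            )
        eta = eta + fit.cluster_effects[pos_clipped]
    if fit.family == BINOMIAL:
        return _sigmoid(eta)
    return eta


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def penalized_objective(data: ClusteredDataset, fit: FitResult) -> float:
    """-(1/n) loglik + lam * (alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2),
    with the gaussian negative log-likelihood taken as (1/2n)*RSS."""
    eta = predict_linear(data, fit)
    if data.family == GAUSSIAN:
        nll = 0.5 * float(np.mean((data.y - eta) ** 2))
    else:
        nll = -_binomial_loglik(data.y, _sigmoid(eta)) / data.n
    b = full_coef_vector(fit)
    pen = fit.lam * (
        fit.alpha * float(np.abs(b).sum())
        + 0.5 * (1 - fit.alpha) * float(b @ b)
    )
    return nll + pen


def full_coef_vector(fit: FitResult) -> np.ndarray:
    """Predictor coefficients plus penalized dummy coefficients, matching
    the internally augmented design."""
    if fit.cluster_kind == "dummy":
        return np.concatenate([fit.beta, fit.cluster_effects[1:]])
    return fit.beta


def predict_linear(data: ClusteredDataset, fit: FitResult) -> np.ndarray:
    eta = fit.intercept + data.X @ fit.beta
    if fit.cluster_kind != "none":
        pos = np.searchsorted(fit.cluster_labels, data.cluster)
        eta = eta + fit.cluster_effects[pos]
    return eta


def kkt_violation(data: ClusteredDataset, fit: FitResult) -> float:
    """Maximum violation of the subgradient stationarity conditions.

    Zero coefficients require |x_j' r| / n <= lam*alpha; nonzero ones
    require x_j' r / n = lam*alpha*sign(beta_j) + lam*(1-alpha)*beta_j,
    where r is the residual y - mu (gaussian) or y - p (binomial). The
    intercept requires mean(r) = 0.
    """
    eta = predict_linear(data, fit)
    if data.family == GAUSSIAN:
        r = data.y - eta
    else:
        r = data.y - _sigmoid(eta)
    if fit.cluster_kind == "dummy":
        D, _ = dummy_matrix(data.cluster, fit.cluster_labels)
        X = np.hstack([data.X, D])
    else:
        X = data.X
    b = full_coef_vector(fit)
    g = X.T @ r / data.n
    thr = fit.lam * fit.alpha
    ridge = fit.lam * (1 - fit.alpha)
    viol = abs(float(np.mean(r)))
    for j in range(len(b)):
        if b[j] == 0.0:
            viol = max(viol, abs(g[j]) - thr)
        else:
            viol = max(viol, abs(g[j] - thr * np.sign(b[j]) - ridge * b[j]))
    return viol


def lambda_max_fixed(
    data: ClusteredDataset,
    include_cluster_dummies: bool = False,
    alpha: float = 1.0,
) -> float:
    """KKT bound: smallest penalty at which the null (intercept-only) model
    is stationary, max_j |x_j' (y - ybar)| / (n*alpha)."""
    Xa, _, _, _ = _augment(data, include_cluster_dummies, True)
    ybar = float(np.mean(data.y))
    r = data.y - ybar  # gaussian residual; binomial score at the null fit
    return float(np.max(np.abs(Xa.T @ r)) / (data.n * alpha))
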
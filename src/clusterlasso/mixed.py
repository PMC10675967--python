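"""L1-penalized random-intercept (generalized) linear mixed model.

The *hosps random* estimator: fixed effects carry a LASSO penalty, each
hospital gets a normal random intercept b_h ~ N(0, tau^2) whose variance is
estimated and whose predicted values (BLUPs) are shrunken cluster means.

Fitting alternates three steps to a stationary point of the penalized
(approximate) likelihood:

1. **beta step** — coordinate descent with soft-thresholding on the working
   response that absorbs the current predicted intercepts;
2. **b step** — ridge-shrunken cluster means of the working residuals,
   shrinkage n_h / (n_h + phi^2/tau^2) for the gaussian family, the
   weighted analogue under the PQL linearization for binomial;
3. **variance step** — EM-type moment update of tau^2 (and phi^2 for
   gaussian) including the posterior-variance shrinkage correction.

For the gaussian family the reported log-likelihood is the exact marginal
likelihood of the random-intercept model; for binomial it is a Laplace
approximation at the predicted intercepts. tau collapsing to zero is a
valid boundary solution (the model degenerates to the cluster-ignoring
LASSO) and is reported, not raised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import ClusteredDataset, GAUSSIAN, BINOMIAL
from .lasso import (
    FitResult,
    PathResult,
    _cd_weighted,
    _binomial_loglik,
    _sigmoid,
    predict,
)

OUTER_TOL = 1e-6
OUTER_MAX_ITER = 500
TAU2_FLOOR = 1e-12
INNER_VAR_TOL = 1e-10
INNER_VAR_MAX_ITER = 1000


def _variance_fixed_point_gaussian(
    ss_e: float,
    ebar: np.ndarray,
    counts: np.ndarray,
    tau2: float,
    phi2: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """EM fixed point for (tau^2, phi^2) at fixed residual statistics.

    With the per-cluster residual means and total SS held fixed, each EM
    step is O(#clusters), so the variance components are iterated to
    convergence inside every outer step instead of once per step (the slow
    component of the alternation when cluster information is weak).
    """
    H = len(counts)
    for _ in range(INNER_VAR_MAX_ITER):
        if tau2 <= TAU2_FLOOR:
            b = np.zeros(H)
            v = np.zeros(H)
        else:
            denom = counts * tau2 + phi2
            b = counts * tau2 / denom * ebar
            v = tau2 * phi2 / denom
        tau2_new = float(np.mean(b * b + v))
        # sum((e - b)^2) expanded from the per-cluster statistics
        ss_within = ss_e - 2.0 * float(np.sum(counts * ebar * b)) + float(
            np.sum(counts * b * b)
        )
        phi2_new = (ss_within + float(np.sum(counts * v))) / n
        moved = abs(tau2_new - tau2) + abs(phi2_new - phi2)
        tau2, phi2 = tau2_new, phi2_new
        if tau2 < TAU2_FLOOR:
            tau2 = 0.0
        if moved < INNER_VAR_TOL * (tau2 + phi2 + 1e-12):
            break
    if tau2 <= 0:
        b = np.zeros(H)
        v = np.zeros(H)
    else:
        denom = counts * tau2 + phi2
        b = counts * tau2 / denom * ebar
        v = tau2 * phi2 / denom
    return b, v, tau2, phi2


def _variance_fixed_point_binomial(
    sw: np.ndarray, swr: np.ndarray, tau2: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """EM fixed point for tau^2 under the PQL linearization (phi = 1)."""
    H = len(sw)
    for _ in range(INNER_VAR_MAX_ITER):
        if tau2 <= TAU2_FLOOR:
            b = np.zeros(H)
            v = np.zeros(H)
        else:
            b = swr / (sw + 1.0 / tau2)
            v = 1.0 / (sw + 1.0 / tau2)
        tau2_new = float(np.mean(b * b + v))
        moved = abs(tau2_new - tau2)
        tau2 = tau2_new
        if tau2 < TAU2_FLOOR:
            tau2 = 0.0
            break
        if moved < INNER_VAR_TOL * (tau2 + 1e-12):
            break
    if tau2 <= 0:
        b = np.zeros(H)
        v = np.zeros(H)
    else:
        b = swr / (sw + 1.0 / tau2)
        v = 1.0 / (sw + 1.0 / tau2)
    return b, v, tau2


@dataclass
class MixedModelState:
    """Warm-start state carried along a penalty path."""

    beta: np.ndarray
    intercept: float
    b: np.ndarray          # per-cluster intercepts, sorted-label order
    tau2: float
    phi2: float            # residual variance (gaussian; 1.0 for binomial)
    iteration: int = 0
    obj_trace: list = field(default_factory=list)


def _marginal_loglik_gaussian(
    e: np.ndarray, idx: np.ndarray, counts: np.ndarray, tau2: float, phi2: float
) -> float:
    """Exact marginal log-likelihood of e ~ N(0, phi2*I + tau2*J) per cluster."""
    n = len(e)
    ebar = np.bincount(idx, weights=e) / counts
    ss_within = float(np.sum(e * e)) - float(np.sum(counts * ebar * ebar))
    denom = phi2 + counts * tau2
    ll = -0.5 * (
        n * math.log(2 * math.pi)
        + (n - len(counts)) * math.log(phi2)
        + float(np.sum(np.log(denom)))
        + ss_within / phi2
        + float(np.sum(counts * ebar * ebar / denom))
    )
    return ll


def _laplace_loglik_binomial(
    y: np.ndarray, eta: np.ndarray, b: np.ndarray, sw: np.ndarray, tau2: float
) -> float:
    """Laplace-approximate marginal log-likelihood at the predicted b."""
    cond = _binomial_loglik(y, _sigmoid(eta))
    if tau2 <= 0:
        return cond
    return cond - float(np.sum(b * b)) / (2 * tau2) - 0.5 * float(
        np.sum(np.log1p(tau2 * sw))
    )


def penalized_joint_objective(
    data: ClusteredDataset, state: MixedModelState, lam: float
) -> float:
    """Joint penalized objective at fixed variance components (the quantity
    the beta and b steps jointly decrease):

    gaussian: (1/2n*phi2)*||y - eta||^2 + (1/2n*tau2)*||b||^2 + lam*||beta||_1
    binomial: -(1/n)*cond loglik + (1/2n*tau2)*||b||^2 + lam*||beta||_1
    """
    idx = data.cluster_index()
    eta = state.intercept + data.X @ state.beta + state.b[idx]
    n = data.n
    if data.family == GAUSSIAN:
        fit_term = 0.5 * float(np.sum((data.y - eta) ** 2)) / (n * state.phi2)
    else:
        fit_term = -_binomial_loglik(data.y, _sigmoid(eta)) / n
    b_term = (
        0.5 * float(np.sum(state.b**2)) / (n * state.tau2)
        if state.tau2 > 0
        else 0.0
    )
    return fit_term + b_term + lam * float(np.abs(state.beta).sum())


def _fit_mixed(
    data: ClusteredDataset,
    lam: float,
    init: MixedModelState | None,
    tau_zero: bool,
    freeze_variance: bool,
    tol: float,
    max_outer: int,
    track_objective: bool,
) -> tuple[FitResult, MixedModelState]:
    y, X = data.y, data.X
    n, p = data.n, data.p
    labels = data.cluster_labels
    idx = data.cluster_index()
    H = len(labels)
    counts = np.bincount(idx, minlength=H).astype(float)

    single_cluster = H < 2
    if single_cluster and not tau_zero:
        warnings.warn(
            "only one cluster: tau is unidentifiable and fixed to 0",
            RuntimeWarning,
        )
        tau_zero = True

    if init is not None:
        beta = init.beta.copy()
        intercept = init.intercept
        b = init.b.copy()
        tau2 = init.tau2
        phi2 = init.phi2
    else:
        beta = np.zeros(p)
        if data.family == GAUSSIAN:
            intercept = float(np.mean(y))
            phi2 = max(float(np.var(y)), 1e-8)
        else:
            pbar = float(np.clip(np.mean(y), 1e-6, 1 - 1e-6))
            intercept = math.log(pbar / (1 - pbar))
            phi2 = 1.0
        b = np.zeros(H)
        tau2 = 0.0 if tau_zero else 0.1 * phi2
    if tau_zero:
        tau2 = 0.0
        b = np.zeros(H)

    ones = np.ones(n)
    converged = False
    state = MixedModelState(beta, intercept, b, tau2, phi2)
    # augmented design: predictors plus one indicator column per hospital;
    # the indicator block is updated vectorized inside the CD kernel with a
    # ridge phi^2/(n tau^2), which is exactly the BLUP shrinkage, so each
    # outer step solves (beta, b) jointly at the current variances
    D = (idx[:, None] == np.arange(H)[None, :]).astype(float)
    Xa = np.hstack([X, D])
    penal = np.concatenate([np.ones(p, dtype=bool), np.zeros(H, dtype=bool)])
    coef = np.concatenate([beta, b])
    for it in range(1, max_outer + 1):
        beta_old = beta.copy()
        b_old = b.copy()
        int_old, tau2_old, phi2_old = intercept, tau2, phi2

        if data.family == GAUSSIAN:
            if tau2 > 0:
                coef[:p], coef[p:] = beta, b
                coef, intercept, _, _ = _cd_weighted(
                    Xa, y, ones, lam, 1.0, coef, intercept, penal,
                    dummy_start=p, dummy_groups=idx,
                    block_ridge=phi2 / (n * tau2),
                )
                beta, b = coef[:p].copy(), coef[p:].copy()
            else:
                beta, intercept, _, _ = _cd_weighted(
                    X, y, ones, lam, 1.0, beta, intercept,
                    np.ones(p, dtype=bool),
                )
                b = np.zeros(H)
            e = y - intercept - X @ beta
            ebar = np.bincount(idx, weights=e, minlength=H) / counts
            if not (tau_zero or freeze_variance):
                b, _, tau2, phi2 = _variance_fixed_point_gaussian(
                    float(np.sum(e * e)), ebar, counts, tau2, phi2, n
                )
        else:
            eta = intercept + X @ beta + b[idx]
            prob = _sigmoid(eta)
            w = np.maximum(prob * (1 - prob), 1e-5)
            z = eta + (y - prob) / w
            if tau2 > 0:
                coef[:p], coef[p:] = beta, b
                coef, intercept, _, _ = _cd_weighted(
                    Xa, z, w, lam, 1.0, coef, intercept, penal,
                    dummy_start=p, dummy_groups=idx,
                    block_ridge=1.0 / (n * tau2),
                )
                beta, b = coef[:p].copy(), coef[p:].copy()
            else:
                beta, intercept, _, _ = _cd_weighted(
                    X, z, w, lam, 1.0, beta, intercept,
                    np.ones(p, dtype=bool),
                )
                b = np.zeros(H)
            resid = z - intercept - X @ beta
            sw = np.bincount(idx, weights=w, minlength=H)
            swr = np.bincount(idx, weights=w * resid, minlength=H)
            if not (tau_zero or freeze_variance):
                b, _, tau2 = _variance_fixed_point_binomial(sw, swr, tau2)

        state = MixedModelState(beta, intercept, b, tau2, phi2, iteration=it,
                                obj_trace=state.obj_trace)
        if track_objective:
            state.obj_trace.append(penalized_joint_objective(data, state, lam))

        delta = max(
            float(np.max(np.abs(beta - beta_old))) if p else 0.0,
            abs(intercept - int_old),
            float(np.max(np.abs(b - b_old))) if H else 0.0,
            abs(tau2 - tau2_old),
            abs(phi2 - phi2_old),
        )
        if delta < tol:
            converged = True
            break

    # recompute predicted intercepts at the final variance components
    if data.family == GAUSSIAN:
        e = y - intercept - X @ beta
        if tau2 > 0:
            ebar = np.bincount(idx, weights=e, minlength=H) / counts
            b = counts * tau2 / (counts * tau2 + phi2) * ebar
        else:
            b = np.zeros(H)
        loglik = _marginal_loglik_gaussian(e, idx, counts, tau2, max(phi2, 1e-12))
    else:
        eta = intercept + X @ beta + b[idx]
        prob = _sigmoid(eta)
        sw = np.bincount(idx, weights=np.maximum(prob * (1 - prob), 1e-5),
                         minlength=H)
        loglik = _laplace_loglik_binomial(y, eta, b, sw, tau2)

    df = int(np.count_nonzero(beta)) + 2  # intercept + tau
    if data.family == GAUSSIAN:
        df += 1  # residual SD
    fit = FitResult(
        intercept=float(intercept),
        beta=beta.copy(),
        var_names=list(data.var_names),
        family=data.family,
        lam=float(lam),
        alpha=1.0,
        cluster_labels=labels,
        cluster_effects=b.copy(),
        cluster_kind="random",
        tau=math.sqrt(tau2),
        phi=math.sqrt(phi2) if data.family == GAUSSIAN else None,
        df=df,
        loglik=loglik,
        aic=-2 * loglik + 2 * df,
        bic=-2 * loglik + math.log(n) * df,
        converged=converged,
        n_iter=state.iteration,
    )
    state = MixedModelState(
        beta.copy(), float(intercept), b.copy(), tau2, phi2,
        iteration=state.iteration, obj_trace=state.obj_trace,
    )
    return fit, state


def fit_mixed_at_lambda(
    data: ClusteredDataset,
    lam: float,
    init: MixedModelState | None = None,
    tau_zero: bool = False,
    freeze_variance: bool = False,
    tol: float = OUTER_TOL,
    max_outer: int = OUTER_MAX_ITER,
    track_objective: bool = False,
    return_state: bool = False,
):
    """Fit the penalized mixed model at one penalty value.

    ``tau_zero`` pins the random-intercept variance at zero (the model then
    coincides with the cluster-ignoring LASSO); ``freeze_variance`` keeps
    tau^2/phi^2 at their initial values, so only beta and b are updated.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    fit, state = _fit_mixed(
        data, lam, init, tau_zero, freeze_variance, tol, max_outer,
        track_objective,
    )
    return (fit, state) if return_state else fit


def fit_mixed_path(
    data: ClusteredDataset,
    lambdas: np.ndarray,
    final_re: bool = False,
) -> PathResult:
    """Warm-started mixed fits down a descending penalty sequence.

    With ``final_re`` each penalized fit is followed by an unpenalized
    mixed refit on its selected support (the post-LASSO analogue); the
    refit's estimates and information criteria replace the penalized ones
    while the support is preserved.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    fits: list[FitResult] = []
    state: MixedModelState | None = None
    for lam in lambdas:
        fit, state = fit_mixed_at_lambda(data, lam, init=state, return_state=True)
        if final_re:
            fit = mixed_post_refit(data, fit)
        fits.append(fit)
    return PathResult(lambdas=lambdas, fits=fits, family=data.family)


def mixed_post_refit(data: ClusteredDataset, fit: FitResult) -> FitResult:
    """Unpenalized mixed-model refit on the selected support."""
    active = fit.support
    sub = data.subset_cols(active) if len(active) < data.p else data
    refit = fit_mixed_at_lambda(sub, 0.0)
    beta = np.zeros(data.p)
    beta[active] = refit.beta
    out = replace(
        refit,
        beta=beta,
        var_names=list(data.var_names),
        lam=fit.lam,
        estimator="post",
    )
    out.df = int(np.count_nonzero(beta)) + 2 + (1 if data.family == GAUSSIAN else 0)
    out.aic = -2 * out.loglik + 2 * out.df
    out.bic = -2 * out.loglik + math.log(data.n) * out.df
    return out


# conditional prediction: random intercepts applied on the link scale; the
# dispatch in lasso.predict handles cluster_kind == "random" identically.
predict_mixed = predict


def mixed_kkt_violation(data: ClusteredDataset, fit: FitResult) -> float:
    """Stationarity of beta given the final (b, tau, phi).

    gaussian: residual r = y - eta (eta includes b); zero coefficients need
    |x_j' r|/n <= lam, active ones x_j' r/n = lam*sign(beta_j). binomial:
    the weighted analogue with r = y - p.
    """
    idx = data.cluster_index()
    eta = fit.intercept + data.X @ fit.beta + fit.cluster_effects[idx]
    if data.family == GAUSSIAN:
        r = data.y - eta
    else:
        r = data.y - _sigmoid(eta)
    g = data.X.T @ r / data.n
    viol = abs(float(np.mean(r)))
    for j in range(data.p):
        if fit.beta[j] == 0.0:
            viol = max(viol, abs(g[j]) - fit.lam)
        else:
            viol = max(viol, abs(g[j] - fit.lam * np.sign(fit.beta[j])))
    return viol


def lambda_max_mixed(data: ClusteredDataset) -> float:
    """KKT bound at the null mixed model (intercept + random intercepts):
    max_j |x_j' r| / n with r the null model's response residual."""
    null_data = data.subset_cols(np.array([], dtype=int))
    null_fit = fit_mixed_at_lambda(null_data, 0.0)
    idx = data.cluster_index()
    eta = null_fit.intercept + null_fit.cluster_effects[idx]
    if data.family == GAUSSIAN:
        r = data.y - eta
    else:
        r = data.y - _sigmoid(eta)
    return float(np.max(np.abs(data.X.T @ r)) / data.n)
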
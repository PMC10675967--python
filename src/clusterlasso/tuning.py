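"""Penalty-grid construction and model selection.

The grid follows the manual rule used with the random-intercept LASSO:
exactly 100 log-linearly descending penalty values such that (a) the model
at the *largest* value selects no variable at all and (b) within the first
five values at least one variable has entered. Both properties are
certified by actually fitting the model at those grid positions.

Selection criteria over a grid: K-fold cross-validated deviance (the
minimizer ``cv_min``, or the one-standard-error choice ``cv_1se``), AIC,
or BIC. The fixed-effects variants default to 10 CV folds, the mixed
variant to 5 cluster-aware folds (every hospital stays represented in every
training portion, matching the outer subsampling constraint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import ClusteredDataset, GAUSSIAN, BINOMIAL
from .lasso import (
    FitResult,
    PathResult,
    fit_at_lambda,
    fit_path,
    lambda_max_fixed,
    post_lasso_refit,
    predict,
)
from .mixed import (
    fit_mixed_at_lambda,
    fit_mixed_path,
    lambda_max_mixed,
    mixed_post_refit,
)

NO_HOSPS = "no_hosps"
HOSPS_FIXED = "hosps_fixed"
HOSPS_RANDOM = "hosps_random"
VARIANTS = (NO_HOSPS, HOSPS_FIXED, HOSPS_RANDOM)

CV_MIN = "cv_min"
CV_1SE = "cv_1se"
AIC = "aic"
BIC = "bic"
CRITERIA = (CV_MIN, CV_1SE, AIC, BIC)

GRID_SIZE = 100
SAFETY_FACTOR = 1.05   # inflation of the KKT bound so the top of the grid
                       # is a null model even under floating-point slack
INITIAL_RATIO = 1e-3   # lam_min / lam_max before adaptive shrinking
MAX_RATIO_RETRIES = 30


class GridError(RuntimeError):
    """The grid invariants cannot be satisfied on these data."""


@dataclass
class LambdaGrid:
    """Descending 100-value penalty sequence with certified endpoints."""

    values: np.ndarray
    lam_max: float
    ratio: float
    spacing: str = "log-linear"
    certified: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != GRID_SIZE:
            raise GridError(f"grid must have {GRID_SIZE} values")
        if not np.all(np.diff(self.values) < 0) or self.values[-1] <= 0:
            raise GridError("grid must be strictly decreasing and positive")


def _fit_variant_at(
    data: ClusteredDataset,
    lam: float,
    variant: str,
    alpha: float,
) -> FitResult:
    if variant == HOSPS_RANDOM:
        return fit_mixed_at_lambda(data, lam)
    return fit_at_lambda(
        data, lam, alpha=alpha, include_cluster_dummies=(variant == HOSPS_FIXED)
    )


def fit_variant_path(
    data: ClusteredDataset,
    lambdas: np.ndarray,
    variant: str,
    alpha: float = 1.0,
    estimator: str = "classic",
    dummy_labels: np.ndarray | None = None,
) -> PathResult:
    """Dispatch a warm-started path fit for one model variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == HOSPS_RANDOM:
        return fit_mixed_path(data, lambdas, final_re=(estimator == "post"))
    path = fit_path(
        data,
        lambdas,
        alpha=alpha,
        include_cluster_dummies=(variant == HOSPS_FIXED),
        dummy_labels=dummy_labels,
    )
    if estimator == "post":
        path.fits = [post_lasso_refit(data, f) for f in path.fits]
    return path


def build_lambda_grid(
    data: ClusteredDataset,
    variant: str = NO_HOSPS,
    alpha: float = 1.0,
) -> LambdaGrid:
    """Construct and certify the 100-value grid for one variant.

    The top of the grid is the KKT bound at the variant's null model
    (intercept only, or intercept plus random intercepts) inflated by a
    5% safety factor; values descend log-linearly to ``lam_max * ratio``.
    The ratio starts at 1e-3 and is halved until the fit at grid position 5
    selects at least one variable.
    """
    if not data.standardized:
        raise ValueError("standardize predictors before building the grid")
    if variant == HOSPS_RANDOM:
        kkt_bound = lambda_max_mixed(data)
    else:
        kkt_bound = lambda_max_fixed(
            data, include_cluster_dummies=(variant == HOSPS_FIXED), alpha=alpha
        )
    if not np.isfinite(kkt_bound) or kkt_bound <= 0:
        raise GridError(
            "KKT bound is degenerate: no predictor correlates with the outcome"
        )
    lam_max = SAFETY_FACTOR * kkt_bound

    top_fit = _fit_variant_at(data, lam_max, variant, alpha)
    if top_fit.n_selected != 0:
        raise GridError(
            f"null model not achieved at lam_max={lam_max:.6g} "
            f"({top_fit.n_selected} variables selected)"
        )

    ratio = INITIAL_RATIO
    for _ in range(MAX_RATIO_RETRIES):
        values = lam_max * ratio ** (np.arange(GRID_SIZE) / (GRID_SIZE - 1))
        fifth = _fit_variant_at(data, values[4], variant, alpha)
        if fifth.n_selected >= 1:
            return LambdaGrid(
                values=values, lam_max=lam_max, ratio=ratio, certified=True
            )
        ratio *= 0.5
    raise GridError(
        "could not find a grid whose fifth value selects a variable; "
        "predictors may be unrelated to the outcome"
    )


# ---------------------------------------------------------------------------
# deviance and selection
# ---------------------------------------------------------------------------

def deviance(y: np.ndarray, pred: np.ndarray, family: str) -> float:
    """Held-out deviance: MSE on the model scale for gaussian, -2 x mean
    Bernoulli log-likelihood for binomial."""
    if family == GAUSSIAN:
        return float(np.mean((y - pred) ** 2))
    p = np.clip(pred, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


@dataclass
class TuningResult:
    """Chosen penalty and the criterion curve that chose it."""

    criterion: str
    chosen_lambda: float
    chosen_index: int
    lambdas: np.ndarray
    curve: np.ndarray
    curve_se: np.ndarray | None
    chosen_fit: FitResult
    n_selected: int
    variant: str


def _cv_folds(
    data: ClusteredDataset, k: int, rng: np.random.Generator, cluster_aware: bool
) -> list[np.ndarray]:
    n = data.n
    if not cluster_aware:
        perm = rng.permutation(n)
        return [np.sort(part) for part in np.array_split(perm, k)]
    # deal each cluster's shuffled rows round-robin over folds, so every
    # set of k-1 training folds contains every cluster
    folds: list[list[int]] = [[] for _ in range(k)]
    idx = data.cluster_index()
    for c in range(data.n_clusters):
        rows = np.flatnonzero(idx == c)
        if len(rows) < 2:
            raise ValueError(
                f"cluster {data.cluster_labels[c]!r} has fewer than 2 rows; "
                "cluster-aware folding cannot keep it in every training portion"
            )
        rows = rng.permutation(rows)
        start = int(rng.integers(k))
        for i, r in enumerate(rows):
            folds[(start + i) % k].append(int(r))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def default_cv_folds(variant: str) -> int:
    """10 folds for the fixed-effects variants, 5 for the mixed variant."""
    return 5 if variant == HOSPS_RANDOM else 10


def cv_deviance_curve(
    data: ClusteredDataset,
    grid: LambdaGrid,
    variant: str,
    k: int | None = None,
    seed: int = 0,
    alpha: float = 1.0,
    estimator: str = "classic",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-penalty mean held-out deviance and its standard error across
    K folds; computed once and shared by the cv_min / cv_1se choices."""
    if k is None:
        k = default_cv_folds(variant)
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds = _cv_folds(data, k, rng, cluster_aware=(variant == HOSPS_RANDOM))

    n_lam = len(grid.values)
    dev = np.empty((k, n_lam))
    all_rows = np.arange(data.n)
    for f, test_rows in enumerate(folds):
        train_rows = np.setdiff1d(all_rows, test_rows)
        train = data.subset_rows(train_rows)
        test = data.subset_rows(test_rows)
        path = fit_variant_path(
            train,
            grid.values,
            variant,
            alpha=alpha,
            estimator=estimator,
            dummy_labels=data.cluster_labels if variant == HOSPS_FIXED else None,
        )
        for j, fit in enumerate(path.fits):
            pred = predict(fit, test.X, test.cluster)
            dev[f, j] = deviance(test.y, pred, data.family)

    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / math.sqrt(k)
    return mean, se


def tune_cv(
    data: ClusteredDataset,
    grid: LambdaGrid,
    variant: str,
    k: int | None = None,
    criterion: str = CV_MIN,
    seed: int = 0,
    alpha: float = 1.0,
    estimator: str = "classic",
    curve: tuple[np.ndarray, np.ndarray] | None = None,
) -> TuningResult:
    """Internal cross-validation over the grid.

    Per penalty: mean held-out deviance across folds with its standard
    error. ``cv_min`` takes the minimizer; ``cv_1se`` the largest penalty
    whose mean deviance is within one SE of that minimum. Ties go to the
    larger penalty. The returned fit is refitted on the full data at the
    chosen penalty (warm-started down the grid). A precomputed
    (mean, se) deviance curve may be passed to share the CV work between
    the two criteria.
    """
    if criterion not in (CV_MIN, CV_1SE):
        raise ValueError("tune_cv handles cv_min / cv_1se only")
    if curve is None:
        curve = cv_deviance_curve(
            data, grid, variant, k=k, seed=seed, alpha=alpha, estimator=estimator
        )
    mean, se = curve
    idx_min = int(np.argmin(mean))  # first occurrence = largest penalty
    if criterion == CV_MIN:
        idx = idx_min
    else:
        within = mean <= mean[idx_min] + se[idx_min]
        idx = int(np.argmax(within))  # largest penalty within one SE
    chosen_lam = float(grid.values[idx])
    refit_path = fit_variant_path(
        data, grid.values[: idx + 1], variant, alpha=alpha, estimator=estimator
    )
    chosen_fit = refit_path.fits[-1]
    return TuningResult(
        criterion=criterion,
        chosen_lambda=chosen_lam,
        chosen_index=idx,
        lambdas=grid.values,
        curve=mean,
        curve_se=se,
        chosen_fit=chosen_fit,
        n_selected=chosen_fit.n_selected,
        variant=variant,
    )


def tune_ic(
    data: ClusteredDataset,
    grid: LambdaGrid,
    variant: str,
    criterion: str = BIC,
    alpha: float = 1.0,
    estimator: str = "classic",
    path: PathResult | None = None,
) -> TuningResult:
    """Information-criterion tuning: fit the whole path on the full data,
    then pick the penalty minimizing AIC or BIC (largest penalty on ties).
    A pre-computed path may be passed to share work between criteria."""
    if criterion not in (AIC, BIC):
        raise ValueError("tune_ic handles aic / bic only")
    if path is None:
        path = fit_variant_path(
            data, grid.values, variant, alpha=alpha, estimator=estimator
        )
    curve = np.array(
        [f.aic if criterion == AIC else f.bic for f in path.fits]
    )
    idx = int(np.argmin(curve))
    chosen_fit = path.fits[idx]
    return TuningResult(
        criterion=criterion,
        chosen_lambda=float(grid.values[idx]),
        chosen_index=idx,
        lambdas=grid.values,
        curve=curve,
        curve_se=None,
        chosen_fit=chosen_fit,
        n_selected=chosen_fit.n_selected,
        variant=variant,
    )
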
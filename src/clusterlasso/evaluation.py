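"""Outer subsampling experiment, performance measures, variable importance.

The evaluation design follows the hospital-coverage-constrained subsampling
scheme: R (default 20) random splits put 1/20 of the rows in a test set,
subject to every test hospital keeping at least one training row (random
effects and hospital dummies are otherwise unusable on the test fold).
Splits are drawn once and reused by every model variant for comparability;
test sets may overlap across replicates.

Performance is scored per replicate and averaged: RMSE on the log-stay
scale for the gaussian outcome; AUC, area under the precision-recall curve,
Brier score, and the mean predictive Bernoulli likelihood for the binary
outcome. Variable importance is a stability-selection statistic: the share
of replicates in which a variable is among the five largest absolute
coefficients of the CV-selected model.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import ClusteredDataset, GAUSSIAN
from .lasso import FitResult, predict
from .preprocess import scale_unit_variance
from .tuning import (
    AIC,
    BIC,
    CV_1SE,
    CV_MIN,
    HOSPS_RANDOM,
    LambdaGrid,
    TuningResult,
    build_lambda_grid,
    fit_variant_path,
    tune_cv,
    tune_ic,
    VARIANTS,
)

TEST_FRACTION_DENOM = 20  # 1/20 of the rows form each test set
PROB_CLIP = 1e-12


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

@dataclass
class SubsampleSplit:
    """One train/test partition under the hospital-coverage constraint."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    replicate: int

    def checksum(self) -> int:
        return zlib.adler32(np.sort(self.test_idx).astype(np.int64).tobytes())


def make_subsamples(
    data: ClusteredDataset, R: int = 20, seed: int = 0
) -> list[SubsampleSplit]:
    """Draw R random splits with |test| = round(n/20).

    Constraint repair: when a hospital's rows all land in the test set, one
    of them (uniformly chosen) moves back to training and a replacement test
    row is redrawn from hospitals that keep >= 2 training rows.
    Deterministic given the seed; the same splits serve every model variant.
    """
    n = data.n
    n_test = int(round(n / TEST_FRACTION_DENOM))
    if n_test < 1:
        raise ValueError("dataset too small for a 1/20 test split")
    idx = data.cluster_index()
    counts = np.bincount(idx)
    rng = np.random.default_rng(seed)
    splits = []
    for r in range(1, R + 1):
        in_test = np.zeros(n, dtype=bool)
        in_test[rng.choice(n, size=n_test, replace=False)] = True
        guard = 0
        while True:
            test_counts = np.bincount(idx[in_test], minlength=len(counts))
            train_counts = counts - test_counts
            offenders = np.flatnonzero((train_counts == 0) & (counts > 0))
            if len(offenders) == 0:
                break
            guard += 1
            if guard > 10 * n:
                raise RuntimeError(
                    "could not satisfy the hospital-coverage constraint for "
                    f"hospitals {data.cluster_labels[offenders].tolist()}"
                )
            for c in offenders:
                rows_c = np.flatnonzero(in_test & (idx == c))
                back = int(rng.choice(rows_c))
                in_test[back] = False
                train_counts[c] += 1
                candidates = np.flatnonzero(
                    (~in_test) & (train_counts[idx] >= 2)
                )
                candidates = candidates[candidates != back]
                if len(candidates) == 0:
                    raise RuntimeError(
                        "no replacement test row available; offending "
                        f"hospitals: {data.cluster_labels[offenders].tolist()}"
                    )
                repl = int(rng.choice(candidates))
                in_test[repl] = True
                train_counts[idx[repl]] -= 1
        splits.append(
            SubsampleSplit(
                train_idx=np.flatnonzero(~in_test),
                test_idx=np.flatnonzero(in_test),
                seed=seed,
                replicate=r,
            )
        )
    return splits


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """Classification counts at one probability threshold."""

    TP: int
    FP: int
    TN: int
    FN: int

    @classmethod
    def at_threshold(
        cls, y: np.ndarray, p_hat: np.ndarray, threshold: float
    ) -> "ConfusionCounts":
        pos = np.asarray(p_hat) >= threshold
        y = np.asarray(y).astype(bool)
        return cls(
            TP=int(np.sum(pos & y)),
            FP=int(np.sum(pos & ~y)),
            TN=int(np.sum(~pos & ~y)),
            FN=int(np.sum(~pos & y)),
        )


def rmse(y: np.ndarray, mu_hat: np.ndarray) -> float:
    """Root mean squared error on the (log) outcome scale."""
    y = np.asarray(y, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    if len(y) == 0 or len(y) != len(mu_hat):
        raise MetricError("rmse needs equal, nonzero lengths")
    return float(np.sqrt(np.mean((y - mu_hat) ** 2)))


def roc_auc(y: np.ndarray, p_hat: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic:
    the probability a random positive outranks a random negative, ties 1/2."""
    y = np.asarray(y).astype(int)
    p_hat = np.asarray(p_hat, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: both classes must be present")
    ranks = rankdata(p_hat)
    u = float(ranks[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def pr_auc(y: np.ndarray, p_hat: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise interpolation:
    sum over descending distinct thresholds of (recall step) x precision."""
    y = np.asarray(y).astype(int)
    p_hat = np.asarray(p_hat, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise MetricError("AUPRC undefined: no positive cases")
    order = np.argsort(-p_hat, kind="stable")
    y_sorted = y[order]
    p_sorted = p_hat[order]
    # group tied scores into one threshold
    distinct = np.flatnonzero(np.diff(p_sorted)) + 1
    boundaries = np.concatenate([distinct, [len(y_sorted)]])
    tp = np.cumsum(y_sorted)[boundaries - 1]
    fp = boundaries - tp
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def brier(y: np.ndarray, p_hat: np.ndarray) -> float:
    """Mean squared difference between outcomes and predicted probabilities."""
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    if len(y) == 0 or len(y) != len(p_hat):
        raise MetricError("brier needs equal, nonzero lengths")
    return float(np.mean((y - p_hat) ** 2))


def bernoulli_likelihood(y: np.ndarray, p_hat: np.ndarray) -> float:
    """Mean predictive Bernoulli likelihood, probabilities clipped away
    from 0/1 before evaluation."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p_hat, dtype=float), PROB_CLIP, 1 - PROB_CLIP)
    return float(np.mean(np.where(y == 1, p, 1 - p)))


def score_predictions(
    y: np.ndarray, pred: np.ndarray, family: str
) -> dict[str, float]:
    if family == GAUSSIAN:
        return {"rmse": rmse(y, pred)}
    return {
        "auc": roc_auc(y, pred),
        "auprc": pr_auc(y, pred),
        "brier": brier(y, pred),
        "bernoulli_lik": bernoulli_likelihood(y, pred),
    }


# ---------------------------------------------------------------------------
# variable importance (top-5 stability statistic)
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    """Per-variable top-k rate with the mean coefficient where it appears."""

    table: pd.DataFrame       # index: variable; columns: top5_rate, mean_coef
    k: int
    n_replicates: int
    shortfalls: int = 0       # replicates with fewer than k nonzero coefficients

    def formatted(self) -> pd.Series:
        """Rows like '100% (.16)': rate plus bracketed mean coefficient."""
        def fmt(row):
            rate = f"{row.top5_rate * 100:.0f}%"
            if np.isnan(row.mean_coef):
                return f"{rate} (-)"
            coef = f"{row.mean_coef:.2f}".replace("0.", ".").replace("-0.", "-.")
            return f"{rate} ({coef})"

        return self.table.apply(fmt, axis=1)


def variable_importance(
    fits: list[FitResult], var_names: list[str], k: int = 5
) -> ImportanceTable:
    """Top-k-by-|coefficient| rates across replicates.

    Per replicate the variables are ranked by absolute standardized
    coefficient (intercept and hospital effects excluded); the first k
    nonzero ones count, ties broken by variable order. A replicate with
    fewer than k nonzero coefficients contributes all of them and is
    recorded as a shortfall.
    """
    p = len(var_names)
    pos = {name: j for j, name in enumerate(var_names)}
    hits = np.zeros(p)
    coef_sums = np.zeros(p)
    shortfalls = 0
    for fit in fits:
        coef = np.zeros(p)
        for name, b in zip(fit.var_names, fit.beta):
            coef[pos[name]] = b
        order = sorted(range(p), key=lambda j: (-abs(coef[j]), j))
        top = [j for j in order if coef[j] != 0.0][:k]
        if len(top) < k:
            shortfalls += 1
        for j in top:
            hits[j] += 1
            coef_sums[j] += coef[j]
    R = len(fits)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_coef = np.where(hits > 0, coef_sums / np.maximum(hits, 1), np.nan)
    table = pd.DataFrame(
        {"top5_rate": hits / R, "mean_coef": mean_coef}, index=list(var_names)
    )
    return ImportanceTable(
        table=table, k=k, n_replicates=R, shortfalls=shortfalls
    )


# ---------------------------------------------------------------------------
# the experiment loop
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    metrics: pd.DataFrame          # variant, criterion, replicate, metric, value
    aggregate: pd.DataFrame        # variant, criterion, metric, mean, se, sd
    importance: dict[str, ImportanceTable]
    split_checksums: list[int]
    failures: list[str] = field(default_factory=list)


def _criteria_for(variant: str, criteria: list[str], allow_1se_mixed: bool):
    out = []
    for c in criteria:
        if c == CV_1SE and variant == HOSPS_RANDOM and not allow_1se_mixed:
            continue  # the one-SE rule is not offered for the mixed variant
        out.append(c)
    return out


def run_experiment(
    data: ClusteredDataset,
    variants: list[str],
    criteria: list[str],
    splits: list[SubsampleSplit],
    alpha: float = 1.0,
    estimator: str = "classic",
    cv_seed: int = 0,
    importance_k: int = 5,
    allow_1se_mixed: bool = False,
) -> ExperimentResult:
    """Fit, tune, and score every variant x criterion on the fixed splits.

    ``data`` is the globally prepared dataset (outcome transformed,
    collinearity-filtered, unscaled). Per replicate, zero-variance columns
    are dropped from the training fold, scaling factors are computed on the
    training fold and applied to the test fold, each variant builds its
    grid on the training fold, and the tuned model predicts the test fold.
    Importance tables use the cv_min-selected fits.
    """
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    rows = []
    failures: list[str] = []
    cv_fits: dict[str, list[FitResult]] = {v: [] for v in variants}
    for split in splits:
        train = data.subset_rows(split.train_idx)
        test = data.subset_rows(split.test_idx)
        keep = train.X.std(axis=0) > 0
        if not keep.all():
            train = train.subset_cols(keep)
            test = test.subset_cols(keep)
        train, test, _ = scale_unit_variance(train, test)
        for vi, variant in enumerate(variants):
            try:
                grid = build_lambda_grid(train, variant, alpha=alpha)
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(
                    f"replicate {split.replicate} {variant}: grid failed ({exc})"
                )
                continue
            ic_path = None
            cv_curve = None
            for criterion in _criteria_for(variant, criteria, allow_1se_mixed):
                try:
                    if criterion in (CV_MIN, CV_1SE):
                        seed = int(
                            np.random.SeedSequence(
                                (cv_seed, split.replicate, vi)
                            ).generate_state(1)[0]
                            % (2**31)
                        )
                        if cv_curve is None:
                            from .tuning import cv_deviance_curve

                            cv_curve = cv_deviance_curve(
                                train, grid, variant, seed=seed,
                                alpha=alpha, estimator=estimator,
                            )
                        res = tune_cv(
                            train,
                            grid,
                            variant,
                            criterion=criterion,
                            seed=seed,
                            alpha=alpha,
                            estimator=estimator,
                            curve=cv_curve,
                        )
                    else:
                        if ic_path is None:
                            ic_path = fit_variant_path(
                                train,
                                grid.values,
                                variant,
                                alpha=alpha,
                                estimator=estimator,
                            )
                        res = tune_ic(
                            train, grid, variant, criterion=criterion,
                            alpha=alpha, estimator=estimator, path=ic_path,
                        )
                except Exception as exc:
                    failures.append(
                        f"replicate {split.replicate} {variant} {criterion}: {exc}"
                    )
                    continue
                pred = predict(res.chosen_fit, test.X, test.cluster)
                scores = score_predictions(test.y, pred, data.family)
                scores["n_selected"] = float(res.n_selected)
                scores["chosen_lambda"] = res.chosen_lambda
                for metric, value in scores.items():
                    rows.append(
                        {
                            "variant": variant,
                            "criterion": criterion,
                            "replicate": split.replicate,
                            "metric": metric,
                            "value": value,
                        }
                    )
                if criterion == CV_MIN:
                    cv_fits[variant].append(res.chosen_fit)
    if failures:
        warnings.warn(
            f"{len(failures)} variant/criterion fits failed and were excluded",
            RuntimeWarning,
        )
    metrics = pd.DataFrame(rows)
    if len(metrics):
        grouped = metrics.groupby(["variant", "criterion", "metric"])["value"]
        aggregate = grouped.agg(
            mean="mean", sd=lambda s: s.std(ddof=1), n="count"
        ).reset_index()
        aggregate["se"] = aggregate["sd"] / np.sqrt(aggregate["n"])
    else:
        aggregate = pd.DataFrame(
            columns=["variant", "criterion", "metric", "mean", "sd", "n", "se"]
        )
    importance = {
        v: variable_importance(fits, data.var_names, k=importance_k)
        for v, fits in cv_fits.items()
        if fits
    }
    return ExperimentResult(
        metrics=metrics,
        aggregate=aggregate,
        importance=importance,
        split_checksums=[s.checksum() for s in splits],
        failures=failures,
    )
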
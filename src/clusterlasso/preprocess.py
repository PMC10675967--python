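"""Data preparation for the penalized models.

Order of operations is fixed: positive-outcome filter -> log transform of
the stay outcome -> zero-variance removal -> pairwise-collinearity filter ->
unit-variance scaling. The collinearity filter is applied once on the full
dataset before subsampling; zero-variance removal and scaling are applied
per training fold (scaling statistics come from the training rows only and
are reused on the test rows).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import ClusteredDataset, DataError, GAUSSIAN


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessReport:
    """Record of what preprocessing removed or rescaled."""

    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_zero_variance: list[str] = field(default_factory=list)
    scale_factors: dict[str, float] = field(default_factory=dict)
    outcome_transform: str = "none"
    n_excluded_nonpositive: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            dropped_correlated=self.dropped_correlated + other.dropped_correlated,
            dropped_zero_variance=self.dropped_zero_variance
            + other.dropped_zero_variance,
            scale_factors={**self.scale_factors, **other.scale_factors},
            outcome_transform=(
                other.outcome_transform
                if other.outcome_transform != "none"
                else self.outcome_transform
            ),
            n_excluded_nonpositive=self.n_excluded_nonpositive
            + other.n_excluded_nonpositive,
        )


def filter_positive_outcome(
    data: ClusteredDataset,
) -> tuple[ClusteredDataset, PreprocessReport]:
    """Drop rows with outcome <= 0 (a zero-day stay has no log)."""
    if data.family != GAUSSIAN:
        raise PreprocessError("positive-outcome filter applies to the gaussian family")
    keep = data.y > 0
    n_excluded = int((~keep).sum())
    if n_excluded == data.n:
        raise DataError("all rows have nonpositive outcome; nothing to analyse")
    out = data.subset_rows(keep) if n_excluded else data
    return out, PreprocessReport(n_excluded_nonpositive=n_excluded)


def log_transform_outcome(data: ClusteredDataset) -> ClusteredDataset:
    """Natural log of the positive continuous outcome; downstream models,
    predictions and the RMSE all operate on this scale."""
    if data.family != GAUSSIAN:
        raise PreprocessError("log transform applies to the gaussian family")
    if np.any(data.y <= 0):
        raise PreprocessError("log transform requires strictly positive outcome")
    return data.with_outcome(np.log(data.y))


def drop_zero_variance(
    data: ClusteredDataset,
) -> tuple[ClusteredDataset, PreprocessReport]:
    """Remove constant predictor columns (they cannot be scaled)."""
    sd = data.X.std(axis=0)
    keep = sd > 0
    dropped = [name for name, k in zip(data.var_names, keep) if not k]
    if not keep.any():
        raise DataError("all predictor columns are constant")
    out = data.subset_cols(keep) if dropped else data
    return out, PreprocessReport(dropped_zero_variance=dropped)


def drop_collinear(
    data: ClusteredDataset,
    threshold: float = 0.95,
    iterative: bool = True,
) -> tuple[ClusteredDataset, PreprocessReport]:
    """Break near-duplicate predictor pairs.

    For every pair with |Pearson r| > ``threshold``, the member whose
    absolute correlation with the outcome is smaller is removed. Pairs are
    visited in descending |r| (ties by column order); with ``iterative``
    (default) remaining pairs are re-examined after each removal, otherwise
    a single pass over the original pairs is made.
    """
    if data.p < 2:
        return data, PreprocessReport()
    X, y = data.X, data.y
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise PreprocessError("run drop_zero_variance before drop_collinear")

    corr = np.corrcoef(X, rowvar=False)
    ycorr = np.abs(
        np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(data.p)])
    )
    alive = np.ones(data.p, dtype=bool)
    dropped: list[tuple[str, str, float]] = []

    def pairs_above():
        out = []
        idx = np.flatnonzero(alive)
        for a_pos, j in enumerate(idx):
            for k in idx[a_pos + 1 :]:
                r = abs(corr[j, k])
                if r > threshold:
                    out.append((r, j, k))
        # descending |r|; ties broken by column order
        out.sort(key=lambda t: (-t[0], t[1], t[2]))
        return out

    pending = pairs_above()
    while pending:
        r, j, k = pending[0]
        if alive[j] and alive[k]:
            loser, winner = (k, j) if ycorr[j] >= ycorr[k] else (j, k)
            alive[loser] = False
            dropped.append(
                (data.var_names[winner], data.var_names[loser], float(r))
            )
        if iterative:
            pending = pairs_above()
        else:
            pending = pending[1:]

    report = PreprocessReport(dropped_correlated=dropped)
    out = data.subset_cols(alive) if dropped else data
    return out, report


def scale_unit_variance(
    train: ClusteredDataset,
    test: ClusteredDataset | None = None,
    center: bool = False,
) -> tuple[ClusteredDataset, ClusteredDataset | None, PreprocessReport]:
    """Scale predictors to unit variance using training-fold statistics.

    Each column is divided by its training SD (population SD, ddof=0); the
    same factors are applied to the test fold. Columns are not mean-centered
    by default — the intercept absorbs means — but ``center=True`` subtracts
    the training mean first.
    """
    sd = train.X.std(axis=0)
    if np.any(sd <= 0):
        bad = [n for n, s in zip(train.var_names, sd) if s <= 0]
        raise PreprocessError(
            f"zero training variance in {bad}; run drop_zero_variance first"
        )
    mean = train.X.mean(axis=0) if center else np.zeros(train.p)

    def apply(ds: ClusteredDataset) -> ClusteredDataset:
        from dataclasses import replace

        return replace(ds, X=(ds.X - mean) / sd, standardized=True)

    report = PreprocessReport(
        scale_factors={n: float(s) for n, s in zip(train.var_names, sd)}
    )
    return apply(train), (apply(test) if test is not None else None), report


def prepare_global(
    data: ClusteredDataset, corr_threshold: float = 0.95
) -> tuple[ClusteredDataset, PreprocessReport]:
    """Whole-dataset preparation run once before subsampling.

    Gaussian family: positive-outcome filter then log transform. Both
    families: zero-variance removal, then the collinearity filter.
    Per-fold steps (zero-variance within the fold, scaling) are applied by
    the evaluation loop.
    """
    report = PreprocessReport()
    if data.family == GAUSSIAN:
        data, rep = filter_positive_outcome(data)
        report = report.merge(rep)
        data = log_transform_outcome(data)
        report.outcome_transform = "log"
    data, rep = drop_zero_variance(data)
    report = report.merge(rep)
    data, rep = drop_collinear(data, threshold=corr_threshold)
    report = report.merge(rep)
    return data, report
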
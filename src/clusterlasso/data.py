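"""Core data container for clustered (hospital-nested) tabular data.

Every stage of the pipeline — synthetic generation, preprocessing, model
fitting, evaluation — consumes and produces :class:`ClusteredDataset`: a
predictor matrix, an outcome vector, a hospital label per row, and a family
tag saying whether the outcome is a positive continuous quantity (length of
stay, modelled on the log scale) or a binary event (in-hospital mortality).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GAUSSIAN = "gaussian"
BINOMIAL = "binomial"
FAMILIES = (GAUSSIAN, BINOMIAL)


class DataError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class ClusteredDataset:
    """Patient-level predictors with a hospital label per row.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Predictor matrix; binary indicators coded 0/1, numerics as-is.
    y : ndarray of shape (n,)
        Outcome. Positive reals for the gaussian family (raw stay duration
        before the log transform, log-stay after), 0/1 for binomial.
    cluster : ndarray of shape (n,)
        Hospital identifier per row (string or integer labels).
    var_names : list of str
        Column labels for ``X``.
    family : {"gaussian", "binomial"}
    standardized : bool
        Whether predictors have been scaled to unit training variance.
    """

    X: np.ndarray
    y: np.ndarray
    cluster: np.ndarray
    var_names: list[str]
    family: str
    standardized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DataError("X must be a 2-d array")
        self.y = np.asarray(self.y, dtype=float)
        self.cluster = np.asarray(self.cluster)
        self.var_names = list(self.var_names)
        n, p = self.X.shape
        if len(self.y) != n or len(self.cluster) != n:
            raise DataError(
                f"length mismatch: X has {n} rows, y has {len(self.y)}, "
                f"cluster has {len(self.cluster)}"
            )
        if len(self.var_names) != p:
            raise DataError(f"{len(self.var_names)} names for {p} columns")
        if self.family not in FAMILIES:
            raise DataError(f"unknown family {self.family!r}")
        if self.family == BINOMIAL:
            if not np.isin(self.y, (0.0, 1.0)).all():
                raise DataError("binomial outcome must be coded 0/1")
        else:
            if not np.isfinite(self.y).all():
                raise DataError("gaussian outcome must be finite")

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def cluster_labels(self) -> np.ndarray:
        """Sorted unique hospital labels."""
        return np.unique(self.cluster)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    def cluster_index(self) -> np.ndarray:
        """Integer cluster codes aligned with :attr:`cluster_labels`."""
        _, idx = np.unique(self.cluster, return_inverse=True)
        return idx

    # -- functional updates ------------------------------------------------
    def subset_rows(self, rows: np.ndarray) -> "ClusteredDataset":
        return replace(
            self, X=self.X[rows], y=self.y[rows], cluster=self.cluster[rows]
        )

    def subset_cols(self, cols) -> "ClusteredDataset":
        cols = np.asarray(cols)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return replace(
            self,
            X=self.X[:, cols],
            var_names=[self.var_names[int(j)] for j in cols],
        )

    def with_outcome(self, y: np.ndarray) -> "ClusteredDataset":
        return replace(self, y=np.asarray(y, dtype=float))

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.var_names)
        df.insert(0, "outcome", self.y)
        df.insert(0, "hospital_id", self.cluster.astype(str))
        return df

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(
        cls, path, family: str, sep: str = ",", standardized: bool = False
    ) -> "ClusteredDataset":
        """Read the pipeline's CSV layout.

        First column is the hospital identifier (kept as string), second the
        outcome, remaining columns the predictors. A header row is required.
        """
        df = pd.read_csv(path, sep=sep, dtype={0: str})
        if df.shape[1] < 3:
            raise DataError("CSV needs hospital_id, outcome and >=1 predictor")
        cluster = df.iloc[:, 0].to_numpy(dtype=str)
        y = df.iloc[:, 1].to_numpy(dtype=float)
        X = df.iloc[:, 2:].to_numpy(dtype=float)
        return cls(
            X=X,
            y=y,
            cluster=cluster,
            var_names=list(df.columns[2:]),
            family=family,
            standardized=standardized,
        )
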
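"""Tabular dataset container shared by all forest and testing routines.

A :class:`TabularDataset` is a numeric feature matrix plus one outcome
vector.  The outcome is continuous for regression forests and strictly
0/1 for classification forests.  All downstream routines (forest
training, residualization, the resampling test) operate on this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGRESSION = "regression"
CLASSIFICATION = "classification"
_TASKS = (REGRESSION, CLASSIFICATION)


class DataValidationError(ValueError):
    """Raised when input data violate the container's invariants."""


@dataclass
class TabularDataset:
    """Feature matrix, outcome vector and task kind.

    Parameters
    ----------
    features : pandas.DataFrame
        n x p numeric matrix with column names; no missing values.
    outcome : numpy.ndarray
        Length-n vector; continuous for ``task="regression"``, values in
        {0, 1} for ``task="classification"``.
    task : str
        Either ``"regression"`` or ``"classification"``.
    """

    features: pd.DataFrame
    outcome: np.ndarray
    task: str = REGRESSION
    outcome_name: str = field(default="Y")

    def __post_init__(self) -> None:
        if not isinstance(self.features, pd.DataFrame):
            self.features = pd.DataFrame(np.asarray(self.features))
            self.features.columns = [f"X{j + 1}" for j in range(self.features.shape[1])]
        self.outcome = np.asarray(self.outcome, dtype=np.float64).ravel()
        if self.task not in _TASKS:
            raise DataValidationError(f"task must be one of {_TASKS}, got {self.task!r}")
        n, p = self.features.shape
        if n < 2:
            raise DataValidationError(f"need at least 2 rows, got {n}")
        if p < 1:
            raise DataValidationError("need at least one feature column")
        if len(self.outcome) != n:
            raise DataValidationError(
                f"outcome length {len(self.outcome)} does not match {n} feature rows"
            )
        values = self.features.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataValidationError("features must be numeric")
        if not np.isfinite(values).all():
            raise DataValidationError("features contain missing or non-finite values")
        if not np.isfinite(self.outcome).all():
            raise DataValidationError("outcome contains missing or non-finite values")
        if self.task == CLASSIFICATION:
            uniq = set(np.unique(self.outcome))
            if not uniq <= {0.0, 1.0}:
                raise DataValidationError(
                    "classification outcome must take values in {0, 1}; "
                    f"found {sorted(uniq)[:5]}"
                )

    # -- basic geometry ------------------------------------------------
    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.features.columns)

    @property
    def X(self) -> np.ndarray:
        """Features as a C-contiguous float64 array."""
        return np.ascontiguousarray(self.features.to_numpy(), dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.outcome

    # -- manipulation helpers used by the resampling test --------------
    def column_index(self, name: str) -> int:
        if name not in self.features.columns:
            raise KeyError(f"column {name!r} not in dataset ({self.columns})")
        return int(self.features.columns.get_loc(name))

    def select_rows(self, rows: np.ndarray) -> "TabularDataset":
        """Row-subset copy (used for subsample iterations)."""
        return TabularDataset(
            self.features.iloc[rows].reset_index(drop=True),
            self.outcome[rows],
            self.task,
            self.outcome_name,
        )

    def replace_column(
        self, name: str, values: np.ndarray, new_name: str | None = None
    ) -> "TabularDataset":
        """Copy with column ``name`` replaced (e.g. Z by its residuals)."""
        self.column_index(name)
        feats = self.features.copy()
        feats[name] = np.asarray(values, dtype=np.float64)
        if new_name is not None:
            feats = feats.rename(columns={name: new_name})
        return TabularDataset(feats, self.outcome, self.task, self.outcome_name)

    def drop_column(self, name: str) -> tuple[pd.DataFrame, np.ndarray]:
        """Remaining features and the dropped column's values."""
        j = self.column_index(name)
        z = self.features.iloc[:, j].to_numpy(dtype=np.float64)
        return self.features.drop(columns=[name]), z


def from_dataframe(
    df: pd.DataFrame, outcome: str, task: str = REGRESSION
) -> TabularDataset:
    """Build a dataset from one frame holding features plus the outcome."""
    if outcome not in df.columns:
        raise DataValidationError(f"outcome column {outcome!r} not found")
    y = df[outcome].to_numpy()
    return TabularDataset(df.drop(columns=[outcome]), y, task, outcome_name=outcome)


def read_table(path: str, outcome: str, task: str = REGRESSION) -> TabularDataset:
    """Read a delimited text file (CSV, or TSV for .tsv/.txt) with header."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return from_dataframe(df, outcome, task)
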
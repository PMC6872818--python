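"""Regression evaluation statistics: AARD, RMSEP, squared correlation.

All three are computed on the physical (de-normalized, eV) scale when
reporting model performance:

* ``AARD`` — absolute average relative deviation, mean of
  ``|yhat_i - y_i| / y_i`` with the *actual* value in the denominator.
  Requires strictly nonzero actuals (absorption energies are positive).
* ``RMSEP`` — root-mean-square error of prediction.
* ``R^2`` — squared Pearson correlation between actual and predicted
  values (centered cross-product squared over the product of centered
  sums of squares), symmetric in its arguments.

:func:`evaluate_model` assembles these per data subset into a report with
an ``average`` row that is the arithmetic mean of the three subset rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .errors import ContractError, DataValidationError

__all__ = [
    "aard",
    "rmsep",
    "mse",
    "r_squared",
    "SubsetMetrics",
    "EvaluationReport",
    "evaluate_model",
    "evaluate_predictions",
]

SUBSETS = ("training", "validation", "testing")


def _paired(actual, predicted):
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise ContractError(f"length mismatch: actual {a.size}, predicted {p.size}")
    if a.size == 0:
        raise ContractError("empty vectors")
    return a, p


def aard(actual, predicted) -> float:
    """Absolute average relative deviation, ``mean(|yhat - y| / y)``.

    Not symmetric in its arguments: the denominator is always the actual
    value, which must be nonzero.
    """
    a, p = _paired(actual, predicted)
    if np.any(a == 0.0):
        raise DataValidationError("aard undefined when an actual value is zero")
    return float(np.mean(np.abs(p - a) / a))


def rmsep(actual, predicted) -> float:
    """Root-mean-square error of prediction."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def mse(actual, predicted) -> float:
    """Mean squared error; equals ``rmsep(actual, predicted) ** 2``."""
    a, p = _paired(actual, predicted)
    return float(np.mean((a - p) ** 2))


def r_squared(actual, predicted) -> float:
    """Squared Pearson correlation between actual and predicted values."""
    a, p = _paired(actual, predicted)
    if a.size < 2:
        raise ContractError("r_squared needs at least two pairs")
    da = a - a.mean()
    dp = p - p.mean()
    ssa = float(np.sum(da**2))
    ssp = float(np.sum(dp**2))
    if ssa == 0.0 or ssp == 0.0:
        raise DataValidationError(
            "r_squared undefined for a constant vector (zero variance)"
        )
    value = float(np.sum(da * dp)) ** 2 / (ssa * ssp)
    # guard against rounding pushing a perfect correlation past 1
    return min(value, 1.0)


@dataclass
class SubsetMetrics:
    n: int
    aard: float
    r_squared: float
    rmsep: float
    mse: float


@dataclass
class EvaluationReport:
    """Per-subset metrics plus an arithmetic-mean ``average`` row.

    Subsets absent from the data are simply missing from ``rows`` (never
    reported as zeros); the average is taken over the subsets present.
    """

    rows: Dict[str, SubsetMetrics] = field(default_factory=dict)

    @property
    def average(self) -> Optional[SubsetMetrics]:
        present = [self.rows[s] for s in SUBSETS if s in self.rows]
        if not present:
            return None
        return SubsetMetrics(
            n=int(sum(m.n for m in present)),
            aard=float(np.mean([m.aard for m in present])),
            r_squared=float(np.mean([m.r_squared for m in present])),
            rmsep=float(np.mean([m.rmsep for m in present])),
            mse=float(np.mean([m.mse for m in present])),
        )

    def to_frame(self) -> pd.DataFrame:
        """Table with columns Subset, N, AARD, R2, RMSEP (plus Average)."""
        records = []
        for name in SUBSETS:
            if name in self.rows:
                m = self.rows[name]
                records.append((name.capitalize(), m.n, m.aard, m.r_squared, m.rmsep))
        avg = self.average
        if avg is not None and len(records) > 1:
            records.append(("Average", avg.n, avg.aard, avg.r_squared, avg.rmsep))
        return pd.DataFrame(records, columns=["Subset", "N", "AARD", "R2", "RMSEP"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __str__(self) -> str:
        frame = self.to_frame()
        return frame.to_string(
            index=False,
            formatters={
                "AARD": "{:.4f}".format,
                "R2": "{:.4f}".format,
                "RMSEP": "{:.4f}".format,
            },
        )


def evaluate_predictions(
    actual_by_subset: Dict[str, np.ndarray], predicted_by_subset: Dict[str, np.ndarray]
) -> EvaluationReport:
    """Build a report from already-computed predictions per subset."""
    report = EvaluationReport()
    for name in SUBSETS:
        if name not in actual_by_subset:
            continue
        a = np.asarray(actual_by_subset[name], dtype=float)
        if a.size == 0:
            continue
        p = np.asarray(predicted_by_subset[name], dtype=float)
        report.rows[name] = SubsetMetrics(
            n=int(a.size),
            aard=aard(a, p),
            r_squared=r_squared(a, p),
            rmsep=rmsep(a, p),
            mse=mse(a, p),
        )
    return report


def evaluate_model(model, table: pd.DataFrame) -> EvaluationReport:
    """Evaluate a trained model on a split-labeled descriptor table.

    Predictions are made from the model's own normalization state and
    compared with the actual targets on the original eV scale.
    """
    from .data import SPLIT_COLUMN  # local import to avoid a cycle

    if SPLIT_COLUMN not in table.columns:
        raise DataValidationError("table has no split labels; run the split first")
    actual, predicted = {}, {}
    for name in SUBSETS:
        subset = table[table[SPLIT_COLUMN] == name]
        if len(subset) == 0:
            continue
        actual[name] = subset["E"].to_numpy(dtype=float)
        predicted[name] = model.predict_table(subset)
    return evaluate_predictions(actual, predicted)
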
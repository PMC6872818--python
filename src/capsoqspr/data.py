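"""Descriptor-table I/O, stratified splitting, and normalization.

A descriptor table has one row per molecule and nine required numeric
columns: the eight input descriptors

    Ec   theoretical absorption energy (eV, cheap quantum-chemistry level)
    Ne   molecular electron count
    Os   oscillator strength
    Ndb  number of double bonds
    Na   total atom count
    Nh   hydrogen count
    Nc   carbon count
    NN   nitrogen count

plus the experimental absorption energy ``E`` (eV, the regression
target), an ``id`` string, and an optional ``split`` label in
{training, validation, testing}.

The split is stratified by energy: molecules are binned into five energy
strata and, within each stratum of size n, round-half-to-even(0.15 n)
molecules go to validation, the same number to testing, and the
remainder to training.  That quota rule reproduces the reference
stratum bookkeeping exactly, including the n = 30 stratum where
round-half-up would differ (22/4/4, not 20/5/5).

Normalization statistics are fitted on training rows only and are
invertible; validation/testing rows may map outside the nominal range
without error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataValidationError

__all__ = [
    "FEATURE_COLUMNS",
    "TARGET_COLUMN",
    "REQUIRED_COLUMNS",
    "SPLIT_COLUMN",
    "SPLIT_LABELS",
    "DEFAULT_ENERGY_BINS",
    "SplitSpec",
    "NormalizationParams",
    "read_table",
    "write_table",
    "validate_table",
    "assign_strata",
    "split_quotas",
    "stratified_split",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
    "to_arrays",
]

ID_COLUMN = "id"
FEATURE_COLUMNS: Tuple[str, ...] = ("Ec", "Ne", "Os", "Ndb", "Na", "Nh", "Nc", "NN")
TARGET_COLUMN = "E"
REQUIRED_COLUMNS: Tuple[str, ...] = (ID_COLUMN,) + FEATURE_COLUMNS + (TARGET_COLUMN,)
SPLIT_COLUMN = "split"
SPLIT_LABELS = ("training", "validation", "testing")
COUNT_COLUMNS = ("Ne", "Ndb", "Na", "Nh", "Nc", "NN")

#: five energy strata (closed intervals, eV) spanning the reference data
DEFAULT_ENERGY_BINS: Tuple[Tuple[float, float], ...] = (
    (2.69, 2.99),
    (3.01, 3.96),
    (4.00, 4.68),
    (4.70, 5.08),
    (5.10, 6.66),
)

#: plausible window for organic absorption energies; a warning outside
ENERGY_WINDOW = (1.0, 10.0)


@dataclass
class SplitSpec:
    """Energy bins, per-stratum fractions and the split seed."""

    bins: Tuple[Tuple[float, float], ...] = DEFAULT_ENERGY_BINS
    fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15)  # train/val/test
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ConfigurationError("fractions must be three non-negative numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError(f"fractions must sum to 1, got {self.fractions}")
        bins = tuple((float(lo), float(hi)) for lo, hi in self.bins)
        if not bins or any(lo > hi for lo, hi in bins):
            raise ConfigurationError(f"malformed bins {bins}")
        if list(bins) != sorted(bins):
            raise ConfigurationError("bins must be sorted by energy")
        self.bins = bins


@dataclass
class NormalizationParams:
    """Per-column affine transform ``(x - offset) / scale`` fitted on training rows.

    ``minmax_0_1`` uses offset = min, scale = max - min (a constant column
    gets scale 0 and maps to 0.5, with a warning at fit time); ``zscore``
    uses offset = mean, scale = standard deviation.
    """

    method: str
    columns: Tuple[str, ...]
    offset: Dict[str, float] = field(default_factory=dict)
    scale: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "columns": list(self.columns),
            "offset": dict(self.offset),
            "scale": dict(self.scale),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NormalizationParams":
        return cls(
            method=payload["method"],
            columns=tuple(payload["columns"]),
            offset={k: float(v) for k, v in payload["offset"].items()},
            scale={k: float(v) for k, v in payload["scale"].items()},
        )


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, types and invariants; return a typed copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataValidationError(f"missing required column(s): {', '.join(missing)}")
    out = table.copy()
    out[ID_COLUMN] = out[ID_COLUMN].astype(str)
    dup = out[ID_COLUMN][out[ID_COLUMN].duplicated()]
    if len(dup):
        raise DataValidationError(f"duplicate molecule id(s): {sorted(set(dup))}")
    for col in FEATURE_COLUMNS + (TARGET_COLUMN,):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[coerced.isna()]
        if len(bad):
            raise DataValidationError(
                f"non-numeric value in column {col!r} at row(s) {list(bad[:5])}"
            )
        out[col] = coerced.astype(float)
    for col in COUNT_COLUMNS:
        vals = out[col]
        if np.any(vals < 0) or np.any(vals != np.round(vals)):
            raise DataValidationError(f"column {col!r} must hold non-negative integers")
        out[col] = vals.astype(int)
    if np.any(out["Os"] < 0):
        raise DataValidationError("oscillator strength Os must be non-negative")
    atoms = out["Nh"] + out["Nc"] + out["NN"]
    bad = out.index[out["Na"] < atoms]
    if len(bad):
        raise DataValidationError(
            f"Na < Nh + Nc + NN at row(s) {list(bad[:5])}: total atom count "
            "cannot be below the sum of H, C and N counts"
        )
    lo, hi = ENERGY_WINDOW
    outside = out.index[(out[TARGET_COLUMN] < lo) | (out[TARGET_COLUMN] > hi)]
    if len(outside):
        warnings.warn(
            f"{len(outside)} target energy value(s) outside the plausible "
            f"window [{lo}, {hi}] eV",
            stacklevel=2,
        )
    if SPLIT_COLUMN in out.columns:
        labels = out[SPLIT_COLUMN].dropna()
        unknown = set(labels) - set(SPLIT_LABELS)
        if unknown:
            raise DataValidationError(f"unknown split label(s): {sorted(unknown)}")
    return out


def read_table(path) -> pd.DataFrame:
    """Read and validate a descriptor CSV (UTF-8, '.' decimal, any column order)."""
    table = pd.read_csv(path, dtype={ID_COLUMN: str})
    return validate_table(table)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a descriptor table as CSV; a write->read round trip is value-identical."""
    cols = [c for c in REQUIRED_COLUMNS if c in table.columns]
    if SPLIT_COLUMN in table.columns:
        cols.append(SPLIT_COLUMN)
    table.to_csv(path, index=False, columns=cols)


def assign_strata(
    energies: np.ndarray, bins: Sequence[Tuple[float, float]] = DEFAULT_ENERGY_BINS
) -> np.ndarray:
    """Map each energy to a stratum index.

    Bins are closed intervals; a value falling in a gap between printed
    bin edges is assigned to the nearest bin, values outside the overall
    range to the first/last bin.
    """
    energies = np.asarray(energies, dtype=float)
    idx = np.empty(energies.shape, dtype=int)
    edges = np.asarray(bins, dtype=float)
    for i, e in np.ndenumerate(energies):
        inside = np.flatnonzero((edges[:, 0] <= e) & (e <= edges[:, 1]))
        if len(inside):
            idx[i] = inside[0]
        else:
            dist = np.minimum(np.abs(edges[:, 0] - e), np.abs(edges[:, 1] - e))
            idx[i] = int(np.argmin(dist))
    return idx


def split_quotas(n: int, fractions: Sequence[float] = (0.70, 0.15, 0.15)) -> Tuple[int, int, int]:
    """Per-stratum (training, validation, testing) counts for a stratum of size n.

    Validation and testing quotas are round-half-to-even of their
    fraction times n (computed after snapping away float dust); training
    takes the remainder.
    """
    if n < 0:
        raise ConfigurationError("stratum size must be >= 0")
    n_val = int(round(round(fractions[1] * n, 9)))
    n_test = int(round(round(fractions[2] * n, 9)))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise DataValidationError(
            f"stratum of size {n} smaller than validation+testing quota "
            f"{n_val}+{n_test}"
        )
    return n_train, n_val, n_test


def stratified_split(table: pd.DataFrame, spec: Optional[SplitSpec] = None) -> pd.DataFrame:
    """Label every row training/validation/testing, stratified by energy.

    Within each stratum, membership is chosen uniformly at random from
    ``spec.rng_seed``; quotas are deterministic functions of the stratum
    size, so two seeds give identical counts (possibly different members).
    """
    spec = spec or SplitSpec()
    out = table.copy()
    strata = assign_strata(out[TARGET_COLUMN].to_numpy(), spec.bins)
    labels = np.empty(len(out), dtype=object)
    rng = np.random.default_rng(spec.rng_seed)
    for s in range(len(spec.bins)):
        members = np.flatnonzero(strata == s)
        if len(members) == 0:
            continue
        n_train, n_val, n_test = split_quotas(len(members), spec.fractions)
        order = rng.permutation(members)
        labels[order[:n_train]] = "training"
        labels[order[n_train : n_train + n_val]] = "validation"
        labels[order[n_train + n_val :]] = "testing"
    out[SPLIT_COLUMN] = labels
    return out


def fit_normalization(
    training_rows: pd.DataFrame,
    method: str = "minmax_0_1",
    columns: Iterable[str] = FEATURE_COLUMNS + (TARGET_COLUMN,),
) -> NormalizationParams:
    """Fit per-column normalization statistics on training rows only."""
    if method not in ("minmax_0_1", "zscore"):
        raise ConfigurationError(f"unknown normalization method {method!r}")
    columns = tuple(columns)
    if len(training_rows) == 0:
        raise DataValidationError("cannot fit normalization on an empty training set")
    params = NormalizationParams(method=method, columns=columns)
    for col in columns:
        vals = training_rows[col].to_numpy(dtype=float)
        if method == "minmax_0_1":
            lo, hi = float(vals.min()), float(vals.max())
            offset, scale = lo, hi - lo
        else:
            offset, scale = float(vals.mean()), float(vals.std(ddof=0))
        if scale == 0.0:
            warnings.warn(
                f"column {col!r} is constant on the training rows; "
                "normalized values are mapped to 0.5",
                stacklevel=2,
            )
        params.offset[col] = offset
        params.scale[col] = scale
    return params


def apply_normalization(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    """Normalize the fitted columns; rows outside the training range pass through."""
    out = table.copy()
    for col in params.columns:
        if col not in out.columns:
            continue
        scale = params.scale[col]
        if scale == 0.0:
            out[col] = 0.5
        else:
            out[col] = (out[col].astype(float) - params.offset[col]) / scale
    return out


def invert_normalization(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`apply_normalization` (identity up to float rounding)."""
    out = table.copy()
    for col in params.columns:
        if col not in out.columns:
            continue
        scale = params.scale[col]
        if scale == 0.0:
            out[col] = params.offset[col]
        else:
            out[col] = out[col].astype(float) * scale + params.offset[col]
    return out


def normalize_target(params: NormalizationParams, values: np.ndarray) -> np.ndarray:
    """Normalize a raw target vector with the fitted target statistics."""
    scale = params.scale[TARGET_COLUMN]
    if scale == 0.0:
        return np.full_like(np.asarray(values, dtype=float), 0.5)
    return (np.asarray(values, dtype=float) - params.offset[TARGET_COLUMN]) / scale


def denormalize_target(params: NormalizationParams, values: np.ndarray) -> np.ndarray:
    """Map normalized predictions back to the physical (eV) scale."""
    scale = params.scale[TARGET_COLUMN]
    if scale == 0.0:
        return np.full_like(np.asarray(values, dtype=float), params.offset[TARGET_COLUMN])
    return np.asarray(values, dtype=float) * scale + params.offset[TARGET_COLUMN]


def to_arrays(table: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """Extract the (n, 8) descriptor matrix and (n,) target vector."""
    X = table.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = table[TARGET_COLUMN].to_numpy(dtype=float)
    return X, y
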
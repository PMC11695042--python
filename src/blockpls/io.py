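"""Data containers, delimited-text readers/writers, prefiltering and autoscaling.

The core object is :class:`Dataset`: a samples-by-variables numeric matrix
``X`` (in the motivating application, per-gene evolutionary-distance scores
for each genome) together with an optional single phenotype vector ``y``.
Multiple phenotypes are modelled one at a time, so ``y`` is always a single
column; the CLI slices a multi-column response file before constructing a
Dataset.

All modelling stages work on autoscaled data (columns centred and divided by
their sample standard deviation).  :class:`ScalingParams` stores the training
means and standard deviations so that held-out data is scaled with the
*training* parameters and predictions can be mapped back to original units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "ScalingParams",
    "PrefilterReport",
    "read_matrix",
    "write_matrix",
    "prefilter_genes",
    "autoscale",
    "apply_scaling",
    "invert_scaling",
]


class MatrixParseError(ValueError):
    """Raised when a delimited file cannot be parsed into a numeric matrix."""


@dataclass
class Dataset:
    """Numeric samples-by-variables matrix with identifiers and optional response.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_variables)
        Numeric score matrix.  May contain NaN only on the prefiltering path.
    sample_ids, variable_ids : sequences of str
        Row and column identifiers; lengths must match the matrix.
    y : ndarray of shape (n_samples,), optional
        A single phenotype vector.
    response_name : str
        Name of the response column, used in reports.
    """

    X: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]
    y: np.ndarray | None = None
    response_name: str = "y"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D samples-by-variables matrix")
        n, p = self.X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 variable")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.variable_ids) != p:
            raise ValueError(
                f"{len(self.variable_ids)} variable ids for {p} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample ids")
        if len(set(self.variable_ids)) != p:
            raise ValueError("duplicated variable ids")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float).ravel()
            if self.y.shape[0] != n:
                raise ValueError("response length does not match sample count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def select_variables(self, indices) -> "Dataset":
        """Return a copy restricted to the given variable column indices."""
        idx = np.asarray(indices, dtype=int)
        return Dataset(
            X=self.X[:, idx],
            sample_ids=list(self.sample_ids),
            variable_ids=[self.variable_ids[i] for i in idx],
            y=None if self.y is None else self.y.copy(),
            response_name=self.response_name,
        )

    def select_samples(self, indices) -> "Dataset":
        """Return a copy restricted to the given sample row indices."""
        idx = np.asarray(indices, dtype=int)
        return Dataset(
            X=self.X[idx, :],
            sample_ids=[self.sample_ids[i] for i in idx],
            variable_ids=list(self.variable_ids),
            y=None if self.y is None else self.y[idx].copy(),
            response_name=self.response_name,
        )

    def with_response(self, y, name: str = "y") -> "Dataset":
        return Dataset(
            X=self.X,
            sample_ids=self.sample_ids,
            variable_ids=self.variable_ids,
            y=np.asarray(y, dtype=float),
            response_name=name,
        )


@dataclass
class ScalingParams:
    """Training-set column means and standard deviations for X (and y).

    Standard deviations use the n-1 denominator.  Applying and then
    inverting the transformation is the identity up to round-off.
    """

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float | None = None
    y_sd: float | None = None

    def __post_init__(self) -> None:
        self.x_mean = np.asarray(self.x_mean, dtype=float).ravel()
        self.x_sd = np.asarray(self.x_sd, dtype=float).ravel()
        if self.x_mean.shape != self.x_sd.shape:
            raise ValueError("x_mean and x_sd must have equal length")
        if np.any(self.x_sd <= 0):
            raise ValueError("every sd must be > 0; prefilter constant columns first")
        if (self.y_sd is not None) and self.y_sd <= 0:
            raise ValueError("response sd must be > 0")

    def to_json(self, path) -> None:
        payload = {
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "ScalingParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            x_mean=np.array(payload["x_mean"], dtype=float),
            x_sd=np.array(payload["x_sd"], dtype=float),
            y_mean=payload["y_mean"],
            y_sd=payload["y_sd"],
        )

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ScalingParams":
        return cls(
            x_mean=np.array(payload["x_mean"], dtype=float),
            x_sd=np.array(payload["x_sd"], dtype=float),
            y_mean=payload["y_mean"],
            y_sd=payload["y_sd"],
        )


@dataclass
class PrefilterReport:
    """Identifiers removed by :func:`prefilter_genes`, with the reason each was dropped."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def removed_ids(self, reason: str | None = None) -> list[str]:
        return [v for v, r in self.removed if reason is None or r == reason]


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    head = path.open("r", encoding="utf-8").readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def read_matrix(
    path,
    orientation: str = "samples",
    delimiter: str | None = None,
    allow_missing: bool = False,
) -> Dataset:
    """Read a delimited numeric table (header row + id column) into a Dataset.

    ``orientation="samples"`` means rows are samples; ``"variables"`` means
    rows are variables and the matrix is transposed on read.  A non-numeric
    or (unless ``allow_missing``) empty cell raises :class:`MatrixParseError`
    naming the offending row and column rather than silently producing NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if orientation not in ("samples", "variables"):
        raise ValueError("orientation must be 'samples' or 'variables'")
    sep = _sniff_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise MatrixParseError(f"duplicated row id {dup!r} in {path}")
    if pd.Index(raw.columns).duplicated().any():
        dup = raw.columns[pd.Index(raw.columns).duplicated()][0]
        raise MatrixParseError(f"duplicated column id {dup!r} in {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    blank = raw.apply(lambda col: col.str.strip() == "")
    missing_nan = raw.apply(lambda col: col.str.strip().str.lower().isin(["nan", "na"]))
    bad = numeric.isna() & ~(blank | missing_nan)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"non-numeric value {raw.iat[i, j]!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r} in {path}"
        )
    if not allow_missing and numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise MatrixParseError(
            f"missing value at row {raw.index[i]!r}, column {raw.columns[j]!r} "
            f"in {path}; pass allow_missing=True to defer to prefiltering"
        )
    values = numeric.to_numpy(dtype=float)
    row_ids = [str(i) for i in raw.index]
    col_ids = [str(c) for c in raw.columns]
    if orientation == "variables":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return Dataset(X=values, sample_ids=row_ids, variable_ids=col_ids)


def write_matrix(ds: Dataset, path, delimiter: str = ",") -> None:
    """Write a Dataset's X to delimited text with full float precision."""
    frame = pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.variable_ids)
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def prefilter_genes(
    ds: Dataset, min_variance: float = 0.0, drop_missing: bool = True
) -> tuple[Dataset, PrefilterReport]:
    """Remove variables with missing values or variance not exceeding a cutoff.

    Retained columns are complete and have sample variance strictly greater
    than ``min_variance`` (default 0, i.e. only constant columns go).  The
    report lists every removed variable id with reason ``"missing"`` or
    ``"low_variance"``.  Idempotent: a second pass removes nothing.
    """
    if min_variance < 0:
        raise ValueError("min_variance must be >= 0")
    report = PrefilterReport()
    keep: list[int] = []
    has_nan = np.isnan(ds.X).any(axis=0)
    # Variance of complete columns only; NaN columns are handled separately.
    with np.errstate(invalid="ignore"):
        variances = np.nanvar(ds.X, axis=0, ddof=1)
    for j in range(ds.p):
        if has_nan[j]:
            if not drop_missing:
                raise ValueError(
                    f"variable {ds.variable_ids[j]!r} has missing values and "
                    "drop_missing is disabled"
                )
            report.removed.append((ds.variable_ids[j], "missing"))
        elif not variances[j] > min_variance:
            report.removed.append((ds.variable_ids[j], "low_variance"))
        else:
            keep.append(j)
    if not keep:
        raise ValueError("prefilter removed every variable; lower min_variance")
    return ds.select_variables(keep), report


def autoscale(ds: Dataset) -> tuple[Dataset, ScalingParams]:
    """Centre each column of X (and y, if present) and scale to unit sd.

    Uses the n-1 denominator.  Errors on constant columns, pointing the user
    to :func:`prefilter_genes`.
    """
    x_mean = ds.X.mean(axis=0)
    x_sd = ds.X.std(axis=0, ddof=1)
    if np.any(x_sd <= 0) or np.any(~np.isfinite(x_sd)):
        j = int(np.argmin(np.where(np.isfinite(x_sd), x_sd, -np.inf)))
        raise ValueError(
            f"variable {ds.variable_ids[j]!r} has zero or undefined sd; "
            "run prefilter_genes first"
        )
    y_mean = y_sd = None
    if ds.y is not None:
        y_mean = float(ds.y.mean())
        y_sd = float(ds.y.std(ddof=1))
        if not y_sd > 0:
            raise ValueError("response is constant; cannot autoscale")
    params = ScalingParams(x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd)
    return apply_scaling(ds, params), params


def apply_scaling(ds: Dataset, params: ScalingParams) -> Dataset:
    """Scale a Dataset with stored (training) parameters; never recomputes them."""
    if params.x_mean.shape[0] != ds.p:
        raise ValueError(
            f"scaling parameters are for {params.x_mean.shape[0]} variables, "
            f"data has {ds.p}"
        )
    Xs = (ds.X - params.x_mean) / params.x_sd
    ys = None
    if ds.y is not None:
        if params.y_mean is None:
            ys = ds.y.copy()
        else:
            ys = (ds.y - params.y_mean) / params.y_sd
    return Dataset(
        X=Xs,
        sample_ids=list(ds.sample_ids),
        variable_ids=list(ds.variable_ids),
        y=ys,
        response_name=ds.response_name,
    )


def invert_scaling(values, params: ScalingParams, which: str = "y"):
    """Map scaled values back to original units (``which`` is "y" or "x")."""
    values = np.asarray(values, dtype=float)
    if which == "y":
        if params.y_mean is None:
            return values
        return values * params.y_sd + params.y_mean
    if which == "x":
        return values * params.x_sd + params.x_mean
    raise ValueError("which must be 'y' or 'x'")
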
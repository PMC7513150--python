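"""Regression data container and CSV/TSV loading."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["RegressionData", "load_csv"]


@dataclass
class RegressionData:
    """Design matrix and strictly positive response for the multiplicative
    model ``y_i = exp(x_i' beta) * eps_i``.

    The library never adds an all-ones intercept column silently; if the
    design has one, record its index in ``intercept_column`` so that
    scale-equivariance-aware reporting (a factor ``sigma`` on ``y`` shifts
    the intercept coefficient by ``log sigma``) can use it.
    """

    X: np.ndarray
    y: np.ndarray
    intercept_column: Optional[int] = None
    predictor_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]}")
        if self.X.size == 0 or self.y.size == 0:
            raise ValueError("empty data")
        if not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(f"non-finite predictor at row {bad[0]}, "
                             f"column {bad[1]}")
        bad = np.flatnonzero(~(np.isfinite(self.y) & (self.y > 0)))
        if bad.size:
            raise ValueError(
                "response must be strictly positive and finite; offending "
                f"rows (0-based): {bad[:10].tolist()}")
        if self.intercept_column is not None:
            j = self.intercept_column
            if not (0 <= j < self.X.shape[1]):
                raise ValueError("intercept_column out of range")
            if not np.allclose(self.X[:, j], 1.0):
                raise ValueError(
                    f"column {j} declared as intercept is not all ones")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def scaled_response(self, sigma: float) -> "RegressionData":
        """Return a copy with ``y`` multiplied by ``sigma > 0``."""
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return RegressionData(self.X.copy(), self.y * sigma,
                              intercept_column=self.intercept_column,
                              predictor_names=self.predictor_names)


def load_csv(path, response: str = "y", sep: Optional[str] = None,
             intercept_column: Optional[int] = None) -> RegressionData:
    """Read (X, y) from a delimited text file with a header row.

    The column named ``response`` is the response; every other column must
    be numeric and becomes a predictor (in file order).  ``sep=None`` picks
    tab for ``.tsv`` files and comma otherwise.
    """
    path = str(path)
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not found; columns "
                         f"are {list(df.columns)}")
    y = pd.to_numeric(df[response], errors="coerce").to_numpy(float)
    bad = np.flatnonzero(~(np.isfinite(y) & (y > 0)))
    if bad.size:
        raise ValueError(
            f"response column {response!r} must be strictly positive; "
            f"offending data rows (0-based): {bad[:10].tolist()}")
    pred = df.drop(columns=[response])
    try:
        X = pred.apply(pd.to_numeric).to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric predictor column: {exc}") from exc
    return RegressionData(X, y, intercept_column=intercept_column,
                          predictor_names=list(pred.columns))
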
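"""Shannon-entropy prioritization of operations.

Input is a positive operations-score matrix with one row per assessment
method (m rows) and one column per production operation, each method
scoring on its own native scale.  Each operation column is normalized to
a distribution over the m methods (``P[i, j] = x[i, j] / sum_i x[i, j]``,
which cancels per-method scale differences), optionally multiplied by a
per-method weight (here: the total-gap values produced by the ranking
stage), and the Shannon entropy of each column is taken with the constant
``k = 1 / ln(m)`` so that unweighted entropies live in ``[0, 1]``:

    e_j = -k * sum_i M[i, j] * ln M[i, j]        (0 * ln 0 := 0)
    d_j = 1 - e_j
    w_j = d_j / sum_j d_j

Operations with higher ``w_j`` disperse information less evenly across
methods and receive a higher ergonomic priority.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import TOL

WEIGHT_MODES = ("weighted", "unweighted")


@dataclass(frozen=True)
class ScoreMatrix:
    """Labeled positive score matrix, methods x operations."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.values, dtype=float)
        if df.empty:
            raise ValueError("empty score matrix")
        if (df.to_numpy() <= 0).any():
            raise ValueError("score matrix entries must be strictly positive")
        object.__setattr__(self, "values", df)

    @property
    def methods(self) -> list:
        return list(self.values.index)

    @property
    def operations(self) -> list:
        return list(self.values.columns)


@dataclass(frozen=True)
class EntropyResult:
    """Per-operation entropy ``e``, diversification ``d`` and weight ``w``."""

    e: pd.Series
    d: pd.Series
    w: pd.Series
    k: float
    mode: str
    method_weights: pd.Series | None

    def ranking(self) -> list:
        """Operations ordered by descending priority weight."""
        return list(self.w.sort_values(ascending=False, kind="stable").index)

    def ranking_string(self) -> str:
        return " >> ".join(str(o) for o in self.ranking())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"e": self.e, "d": self.d, "w": self.w})


def column_normalize(x: ScoreMatrix) -> pd.DataFrame:
    """Normalize each operation column over the methods: columns sum to 1."""
    df = x.values
    sums = df.sum(axis=0)
    zero = sums[sums <= TOL]
    if not zero.empty:
        raise ValueError(f"zero column sums for operations: {list(zero.index)}")
    return df / sums


def weighted_matrix(P: pd.DataFrame, method_weights: Mapping | Sequence | pd.Series
                    ) -> pd.DataFrame:
    """Multiply each method row by a strictly positive per-method weight."""
    if isinstance(method_weights, pd.Series):
        wv = method_weights.reindex(P.index)
        if wv.isna().any():
            raise ValueError(
                f"method weights missing for: {list(wv[wv.isna()].index)}"
            )
    else:
        try:
            wv = pd.Series(dict(method_weights)).reindex(P.index)
            if wv.isna().any():
                raise ValueError(
                    f"method weights missing for: {list(wv[wv.isna()].index)}"
                )
        except (TypeError, ValueError) as exc:
            seq = list(method_weights)
            if len(seq) != len(P.index):
                raise ValueError(
                    f"{len(seq)} weights for {len(P.index)} methods"
                ) from exc
            wv = pd.Series(seq, index=P.index, dtype=float)
    if (wv <= 0).any():
        raise ValueError(f"method weights must be positive, got {list(wv)}")
    return P.mul(wv, axis=0)


def entropy(M: pd.DataFrame, m: int | None = None, mode: str = "weighted",
            method_weights: pd.Series | None = None) -> EntropyResult:
    """Column-wise Shannon entropy with ``k = 1/ln(m)``.

    ``m`` defaults to the number of method rows in ``M``.  ``mode`` is a
    label recording whether ``M`` was pre-multiplied by method weights.
    """
    if mode not in WEIGHT_MODES:
        raise ValueError(f"mode must be one of {WEIGHT_MODES}")
    if m is None:
        m = M.shape[0]
    if m < 2:
        raise ValueError("entropy needs at least two alternatives")
    k = 1.0 / math.log(m)
    A = M.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(A > 0.0, A * np.log(np.where(A > 0.0, A, 1.0)), 0.0)
    e = pd.Series(-k * plogp.sum(axis=0), index=M.columns)
    d = 1.0 - e
    w = d / d.sum()
    return EntropyResult(e=e, d=d, w=w, k=k, mode=mode,
                         method_weights=method_weights)


def prioritize_operations(
    x: ScoreMatrix,
    method_weights=None,
    weight_mode: str = "raw_gap",
) -> EntropyResult:
    """Full entropy stage on a score matrix.

    ``method_weights`` are the per-method values from the ranking stage
    (total gaps by default).  ``weight_mode`` selects how they enter:

    - ``"raw_gap"`` — use the total-gap values as given (default),
    - ``"normalized"`` — divide by their sum,
    - ``"inverse"`` — use ``1/Q`` (renormalized),
    - ``"complement"`` — use ``1 - Q`` (renormalized),
    - ``"none"`` — unweighted entropy of the normalized columns.
    """
    P = column_normalize(x)
    if method_weights is None or weight_mode == "none":
        return entropy(P, mode="unweighted")
    wv = pd.Series(method_weights, dtype=float)
    if weight_mode == "raw_gap":
        pass
    elif weight_mode == "normalized":
        wv = wv / wv.sum()
    elif weight_mode == "inverse":
        wv = (1.0 / wv)
        wv = wv / wv.sum()
    elif weight_mode == "complement":
        wv = 1.0 - wv
        wv = wv / wv.sum()
    else:
        raise ValueError(f"unknown weight_mode: {weight_mode!r}")
    M = weighted_matrix(P, wv)
    return entropy(M, m=x.values.shape[0], mode="weighted", method_weights=wv)
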
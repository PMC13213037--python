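"""Ideal-real gap ranking of alternatives (MAIRCA).

MAIRCA (Multi-Attributive Ideal-Real Comparative Analysis) starts from
equal a-priori preference ``P = 1/m`` for each of the ``m`` alternatives.
The theoretical matrix ``t_P[i, j] = w_j / m`` is the score every
alternative would realize if it were ideal on every criterion; the real
matrix ``t_R = t_P * r`` scales it by the min-max normalized performance
``r`` in ``[0, 1]``; and the gap ``g = t_P - t_R`` accumulates into the
total gap ``Q_i = sum_j g[i, j]``.  The alternative with the smallest
total gap ranks first.

Panel ratings enter as linguistic terms per decision maker, are mapped
through a rating scale, aggregated per cell with the weighted average
operator and defuzzified with the score function before the (crisp)
min-max normalization — interval arithmetic offers no subtraction or
division, so normalization operates on the defuzzified matrix.

Criterion directions are configurable.  Ratings that express the risk
level an alternative carries are cost-like (lower is better); ratings
that express adequacy are benefit-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import IVOFN, TOL, DMWeights, ivffwa
from .scales import LinguisticScale

DIRECTIONS = ("benefit", "cost")


@dataclass(frozen=True)
class RatingPanel:
    """Complete alternatives x criteria x decision-makers linguistic ratings.

    ``ratings[alt][crit]`` is the tuple of one term per decision maker.
    """

    alternatives: tuple
    criteria: tuple
    ratings: Mapping[str, Mapping[str, Sequence[str]]]
    dm_weights: DMWeights

    def __init__(self, alternatives, criteria, ratings, dm_weights):
        object.__setattr__(self, "alternatives", tuple(alternatives))
        object.__setattr__(self, "criteria", tuple(criteria))
        object.__setattr__(
            self,
            "ratings",
            {a: {c: tuple(t) for c, t in row.items()} for a, row in ratings.items()},
        )
        object.__setattr__(self, "dm_weights", dm_weights)
        n_dm = len(dm_weights)
        for a in self.alternatives:
            if a not in self.ratings:
                raise ValueError(f"alternative {a!r} has no ratings")
            for c in self.criteria:
                cell = self.ratings[a].get(c)
                if cell is None:
                    raise ValueError(f"missing cell ({a!r}, {c!r})")
                if len(cell) != n_dm:
                    raise ValueError(
                        f"cell ({a!r}, {c!r}): {len(cell)} terms for {n_dm} DMs"
                    )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dm_weights: DMWeights | None = None
                   ) -> "RatingPanel":
        """Build from a long table: one row per (alternative, dm), criterion
        columns holding term codes — the rating-panel CSV layout."""
        if not {"alternative", "dm"} <= set(frame.columns):
            raise ValueError("frame needs 'alternative' and 'dm' columns")
        crit_cols = [c for c in frame.columns if c not in ("alternative", "dm")]
        alternatives = list(dict.fromkeys(frame["alternative"]))
        dms = list(dict.fromkeys(frame["dm"]))
        if dm_weights is None:
            dm_weights = DMWeights.equal(len(dms))
        ratings: dict = {}
        for a in alternatives:
            sub = frame[frame["alternative"] == a].set_index("dm")
            ratings[a] = {
                c: [str(sub.loc[d, c]).strip() for d in dms] for c in crit_cols
            }
        return cls(alternatives, crit_cols, ratings, dm_weights)


@dataclass(frozen=True)
class CriteriaSpec:
    """Criterion weights plus benefit/cost direction per criterion."""

    weights: Mapping[str, float]
    directions: Mapping[str, str]

    def __init__(self, weights, directions="cost"):
        weights = dict(weights)
        if isinstance(directions, str):
            directions = {c: directions for c in weights}
        else:
            directions = dict(directions)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "directions", directions)
        if any(w < -TOL for w in weights.values()):
            raise ValueError("criterion weights must be non-negative")
        if abs(sum(weights.values()) - 1.0) > 1e-6:
            raise ValueError(
                f"criterion weights must sum to 1, got {sum(weights.values())}"
            )
        missing = [c for c in weights if c not in directions]
        if missing:
            raise ValueError(f"criteria without direction: {missing}")
        bad = {c: d for c, d in directions.items() if d not in DIRECTIONS}
        if bad:
            raise ValueError(f"invalid directions: {bad}")

    @property
    def criteria(self) -> list:
        return list(self.weights)


@dataclass(frozen=True)
class MaircaResult:
    """All intermediate matrices and the final total gaps/ranks."""

    aggregated: pd.DataFrame          # IVOFN-valued (object dtype)
    defuzzified: pd.DataFrame
    normalized: pd.DataFrame          # r in [0, 1]
    theoretical: pd.DataFrame         # t_P
    real: pd.DataFrame                # t_R
    gaps: pd.DataFrame                # g = t_P - t_R
    Q: pd.Series                      # total gap per alternative
    ranks: pd.Series                  # 1 = smallest total gap
    tie_note: str | None = None


def aggregate_ratings(panel: RatingPanel, scale: LinguisticScale,
                      aggregation: str = "linear") -> pd.DataFrame:
    """Panel terms -> per-cell aggregated IVOFN matrix (object-dtype frame)."""
    data = {}
    for a in panel.alternatives:
        row = {}
        for c in panel.criteria:
            numbers = [scale[t] for t in panel.ratings[a][c]]
            row[c] = ivffwa(numbers, panel.dm_weights, form=aggregation)
        data[a] = row
    frame = pd.DataFrame.from_dict(data, orient="index")
    return frame.loc[list(panel.alternatives), list(panel.criteria)]


def defuzzify(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Score-function defuzzification applied cell-wise."""
    return aggregated.map(lambda f: f.score())


def theoretical_matrix(m: int, spec: CriteriaSpec) -> pd.DataFrame:
    """Equal-preference theoretical matrix: every row is ``w_j / m``."""
    if m < 1:
        raise ValueError("need at least one alternative")
    row = {c: spec.weights[c] / m for c in spec.criteria}
    return pd.DataFrame([row] * m)


def normalize(defuzzified: pd.DataFrame, spec: CriteriaSpec) -> pd.DataFrame:
    """Column-wise min-max normalization honoring criterion directions.

    Benefit columns map the column maximum to 1, cost columns the minimum.
    A constant column carries no discrimination and maps to all ones.
    """
    out = pd.DataFrame(index=defuzzified.index, columns=spec.criteria, dtype=float)
    for c in spec.criteria:
        col = defuzzified[c].astype(float)
        hi, lo = col.max(), col.min()
        if abs(hi - lo) <= TOL:
            out[c] = 1.0
        elif spec.directions[c] == "benefit":
            out[c] = (col - lo) / (hi - lo)
        else:
            out[c] = (col - hi) / (lo - hi)
    return out


def gaps_and_rank(t_P: pd.DataFrame, r: pd.DataFrame, *,
                  aggregated: pd.DataFrame | None = None,
                  defuzzified: pd.DataFrame | None = None) -> MaircaResult:
    """Real matrix, gap matrix, total gaps and ranks (1 = smallest gap).

    Ties in the total gap are broken by alternative declaration order and
    flagged in ``tie_note``.
    """
    t_P = t_P.set_axis(r.index, axis=0).set_axis(r.columns, axis=1)
    t_R = t_P * r
    g = t_P - t_R
    Q = g.sum(axis=1)
    order = sorted(range(len(Q)), key=lambda i: (Q.iloc[i], i))
    ranks = pd.Series(0, index=Q.index, dtype=int)
    for pos, i in enumerate(order, start=1):
        ranks.iloc[i] = pos
    tie_note = None
    rounded = Q.round(12)
    if rounded.duplicated().any():
        tied = rounded[rounded.duplicated(keep=False)].index.tolist()
        tie_note = (
            f"total-gap tie among {tied}; broken by declaration order"
        )
    empty = pd.DataFrame(index=r.index, columns=r.columns)
    return MaircaResult(
        aggregated=aggregated if aggregated is not None else empty,
        defuzzified=defuzzified if defuzzified is not None else empty,
        normalized=r,
        theoretical=t_P,
        real=t_R,
        gaps=g,
        Q=Q,
        ranks=ranks,
        tie_note=tie_note,
    )


def rank_methods(panel: RatingPanel, spec: CriteriaSpec,
                 scale: LinguisticScale,
                 aggregation: str = "linear") -> MaircaResult:
    """Full pipeline: aggregate, defuzzify, normalize, gap, rank."""
    missing = [c for c in spec.criteria if c not in panel.criteria]
    if missing:
        raise ValueError(
            f"criteria in spec but not in panel: {missing}"
        )
    agg = aggregate_ratings(panel, scale, aggregation)
    crisp = defuzzify(agg)
    r = normalize(crisp, spec)
    t_P = theoretical_matrix(len(panel.alternatives), spec)
    return gaps_and_rank(t_P, r, aggregated=agg, defuzzified=crisp)
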
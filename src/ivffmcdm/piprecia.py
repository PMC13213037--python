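"""Sequential pairwise criterion weighting (PIPRECIA) in a fuzzy setting.

PIPRECIA (PIvot Pairwise RElative Criteria Importance Assessment) weights
criteria from a chain of pairwise judgments: each decision maker states,
for every criterion after the first in the pass order, whether it is more,
equally or less important than its predecessor.  Per criterion the panel's
linguistic terms are mapped to fuzzy numbers, aggregated across decision
makers with the weighted average operator, and defuzzified to a crisp
value ``s_j``.  The recursion

    k_j = 1 if j is the reference criterion else 2 - s_j
    q_j = 1 if reference else q_{j-1} / k_j
    w_j = q_j / sum(q)

yields pass weights.  An inverse pass repeats the procedure from the last
criterion backwards, and the final weight of each criterion is the mean of
its forward and inverse pass weights.

``s_j`` is by default the raw score-function value in ``[-1, 1]``, fed
directly into ``2 - s_j`` (so ``k_j`` lies in ``[1, 3]`` and weights decay
away from the reference criterion).  ``score_mode="shift"`` adds 1 first
(``s_j`` in ``[0, 2]``, the classical PIPRECIA range, where an 'equal'
judgment leaves the running weight unchanged); it is provided for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .fuzzy import IVOFN, TOL, DMWeights, FuzzyValidationError, ivffwa
from .scales import LinguisticScale

SCORE_MODES = ("raw", "shift")


@dataclass(frozen=True)
class ComparisonSeries:
    """One pass of panel judgments over an ordered criterion list.

    ``criteria`` is the pass order (for an inverse pass, typically the
    reversed canonical order).  ``judgments`` maps every non-reference
    criterion to one linguistic term per decision maker; the first
    criterion of the pass carries no judgment.
    """

    criteria: tuple
    judgments: Mapping[str, Sequence[str]]
    dm_weights: DMWeights

    def __init__(self, criteria, judgments, dm_weights):
        object.__setattr__(self, "criteria", tuple(criteria))
        object.__setattr__(
            self, "judgments", {c: tuple(t) for c, t in dict(judgments).items()}
        )
        object.__setattr__(self, "dm_weights", dm_weights)
        if len(self.criteria) < 2:
            raise ValueError("a comparison series needs at least 2 criteria")
        ref = self.criteria[0]
        if ref in self.judgments:
            raise ValueError(
                f"reference criterion {ref!r} must not carry a judgment"
            )
        missing = [c for c in self.criteria[1:] if c not in self.judgments]
        if missing:
            raise ValueError(f"criteria without judgments: {missing}")
        n_dm = len(dm_weights)
        for c in self.criteria[1:]:
            if len(self.judgments[c]) != n_dm:
                raise ValueError(
                    f"criterion {c!r}: {len(self.judgments[c])} terms for "
                    f"{n_dm} decision makers"
                )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dm_weights: DMWeights | None = None
                   ) -> "ComparisonSeries":
        """Build from a criteria x DM table of term codes.

        Rows are criteria in pass order; the first row holds ``-`` (or NaN)
        placeholders.  Matches the panel CSV layout.
        """
        if dm_weights is None:
            dm_weights = DMWeights.equal(frame.shape[1])
        criteria = list(frame.index)
        judgments = {}
        for c in criteria[1:]:
            judgments[c] = [str(t).strip() for t in frame.loc[c]]
        return cls(criteria, judgments, dm_weights)


@dataclass(frozen=True)
class PipreciaTrace:
    """Per-criterion intermediates of one pass, in pass order."""

    criteria: tuple
    aggregated: Mapping[str, IVOFN]
    s: Mapping[str, float]
    k: Mapping[str, float]
    q: Mapping[str, float]
    w: Mapping[str, float]
    direction: str  # "forward" | "inverse"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"s": self.s, "k": self.k, "q": self.q, "w": self.w}
        ).loc[list(self.criteria)]


@dataclass(frozen=True)
class CriterionWeights:
    """Final averaged criterion weights plus the two pass traces."""

    weights: Mapping[str, float]
    forward: PipreciaTrace
    inverse: PipreciaTrace

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.weights), name="weight")

    def __getitem__(self, criterion: str) -> float:
        return self.weights[criterion]


def run_pass(
    series: ComparisonSeries,
    scale: LinguisticScale,
    direction: str = "forward",
    score_mode: str = "raw",
    aggregation: str = "linear",
) -> PipreciaTrace:
    """Execute one PIPRECIA pass over ``series.criteria`` in the given order."""
    if score_mode not in SCORE_MODES:
        raise ValueError(f"score_mode must be one of {SCORE_MODES}")
    agg: dict[str, IVOFN] = {}
    s: dict[str, float] = {}
    k: dict[str, float] = {}
    q: dict[str, float] = {}
    prev_q = 1.0
    for j, c in enumerate(series.criteria):
        if j == 0:
            k[c] = 1.0
            q[c] = 1.0
            continue
        numbers = [scale[t] for t in series.judgments[c]]
        agg[c] = ivffwa(numbers, series.dm_weights, form=aggregation)
        sj = agg[c].score()
        if score_mode == "shift":
            sj = sj + 1.0
        s[c] = sj
        kj = 2.0 - sj
        if kj <= 0:
            # unreachable with a score function bounded by 1 (even shifted);
            # fail loudly rather than divide through a non-positive pivot
            raise FuzzyValidationError(
                f"non-positive pivot k={kj} at criterion {c!r} (s={sj})"
            )
        k[c] = kj
        q[c] = prev_q / kj
        prev_q = q[c]
    total = sum(q.values())
    w = {c: q[c] / total for c in series.criteria}
    return PipreciaTrace(
        criteria=series.criteria, aggregated=agg, s=s, k=k, q=q, w=w,
        direction=direction,
    )


def run_inverse_pass(
    series: ComparisonSeries,
    scale: LinguisticScale,
    score_mode: str = "raw",
    aggregation: str = "linear",
) -> PipreciaTrace:
    """Inverse pass: ``series`` must already list criteria in inverse order
    (last canonical criterion first), as laid out in the inverse panel table.
    """
    return run_pass(series, scale, direction="inverse",
                    score_mode=score_mode, aggregation=aggregation)


def final_weights(forward: PipreciaTrace, inverse: PipreciaTrace) -> CriterionWeights:
    """Average the two normalized pass weight vectors criterion by criterion.

    The result is re-indexed to the forward pass's criterion order.
    """
    if set(forward.criteria) != set(inverse.criteria):
        raise ValueError(
            "forward and inverse passes cover different criterion sets: "
            f"{sorted(forward.criteria)} vs {sorted(inverse.criteria)}"
        )
    weights = {
        c: 0.5 * (forward.w[c] + inverse.w[c]) for c in forward.criteria
    }
    total = sum(weights.values())
    assert abs(total - 1.0) < 1e-6, total
    return CriterionWeights(weights=weights, forward=forward, inverse=inverse)


def weigh_criteria(
    forward_series: ComparisonSeries,
    inverse_series: ComparisonSeries,
    scale: LinguisticScale,
    score_mode: str = "raw",
    aggregation: str = "linear",
) -> CriterionWeights:
    """Convenience wrapper: both passes plus the final averaging."""
    fwd = run_pass(forward_series, scale, "forward", score_mode, aggregation)
    inv = run_inverse_pass(inverse_series, scale, score_mode, aggregation)
    return final_weights(fwd, inv)
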
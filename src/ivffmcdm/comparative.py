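"""Cross-framework comparison and perturbation robustness.

The same panels can be evaluated under the intuitionistic (q=1),
Pythagorean (q=2) and Fermatean (q=3) rungs by re-interpreting the
linguistic scales and re-running the whole weighting/ranking pipeline.
Rank agreement between runs is measured with the Spearman rank
correlation (closed form ``rho = 1 - 6*sum(d^2)/(n*(n^2-1))`` for untied
ranks, average-rank formula otherwise) and with the count of pairwise
rank reversals (unordered pairs ordered oppositely; pairs tied in either
ranking count as concordant).

Robustness runs re-execute the three pipeline stages after proportional
interval-width perturbation of both linguistic scales (width multiplier
``k``; ``k=1`` is the base case) and report rank correlations and
reversal counts of method and operation rankings against the base run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import EntropyResult, ScoreMatrix, prioritize_operations
from .mairca import CriteriaSpec, MaircaResult, RatingPanel, rank_methods
from .piprecia import ComparisonSeries, CriterionWeights, weigh_criteria
from .scales import LinguisticScale, PerturbationScenario


@dataclass(frozen=True)
class RankVector:
    """Ordered map item -> integer rank, 1 = best; a permutation of 1..n."""

    ranks: Mapping[str, int]

    def __init__(self, ranks: Mapping[str, int] | pd.Series):
        if isinstance(ranks, pd.Series):
            ranks = ranks.to_dict()
        ranks = {k: int(v) for k, v in dict(ranks).items()}
        object.__setattr__(self, "ranks", ranks)
        n = len(ranks)
        if sorted(ranks.values()) != list(range(1, n + 1)):
            raise ValueError(
                f"ranks must be a permutation of 1..{n}: {ranks}"
            )

    def aligned_with(self, other: "RankVector") -> tuple[list, list]:
        if set(self.ranks) != set(other.ranks):
            raise ValueError("rank vectors cover different items")
        items = list(self.ranks)
        return ([self.ranks[i] for i in items], [other.ranks[i] for i in items])


def spearman_rho(a: RankVector | Sequence[float], b: RankVector | Sequence[float]
                 ) -> float:
    """Spearman rank correlation between two rankings of the same items."""
    if isinstance(a, RankVector):
        ra, rb = a.aligned_with(b)
    else:
        ra, rb = list(a), list(b)
        if len(ra) != len(rb):
            raise ValueError("rank vectors differ in length")
    n = len(ra)
    if n < 2:
        raise ValueError("need at least two items")
    if len(set(ra)) == n and len(set(rb)) == n:
        d2 = sum((x - y) ** 2 for x, y in zip(ra, rb))
        return 1.0 - 6.0 * d2 / (n * (n * n - 1))
    # ties: Pearson correlation of average ranks
    sa = pd.Series(ra).rank().to_numpy()
    sb = pd.Series(rb).rank().to_numpy()
    sa = sa - sa.mean()
    sb = sb - sb.mean()
    return float((sa @ sb) / np.sqrt((sa @ sa) * (sb @ sb)))


def count_reversals(a: RankVector, b: RankVector) -> int:
    """Number of unordered item pairs ranked oppositely in the two vectors."""
    ra, rb = a.aligned_with(b)
    n = len(ra)
    count = 0
    for i, j in itertools.combinations(range(n), 2):
        da = ra[i] - ra[j]
        db = rb[i] - rb[j]
        if da * db < 0:
            count += 1
    return count


@dataclass(frozen=True)
class PipelineResult:
    """Outputs of one full weighting -> ranking -> prioritization run."""

    q: int
    criterion_weights: CriterionWeights
    mairca: MaircaResult
    entropy: EntropyResult | None

    def method_ranks(self) -> RankVector:
        return RankVector(self.mairca.ranks)

    def operation_ranks(self) -> RankVector:
        if self.entropy is None:
            raise ValueError("pipeline was run without a score matrix")
        order = self.entropy.ranking()
        return RankVector({o: i + 1 for i, o in enumerate(order)})


def run_framework(
    q: int,
    comparison_scale: LinguisticScale,
    rating_scale: LinguisticScale,
    forward_series: ComparisonSeries,
    inverse_series: ComparisonSeries,
    rating_panel: RatingPanel,
    score_matrix: ScoreMatrix | None = None,
    directions: Mapping[str, str] | str = "cost",
    score_mode: str = "raw",
    entropy_weight_mode: str = "raw_gap",
) -> PipelineResult:
    """Run the full pipeline under rung exponent ``q``.

    Scales declared for a different rung are converted with
    :meth:`LinguisticScale.with_q` (same endpoints, feasibility repair);
    ``q=3`` with Fermatean scales is the base pipeline, bit for bit.
    """
    cs = comparison_scale.with_q(q)
    rs = rating_scale.with_q(q)
    weights = weigh_criteria(forward_series, inverse_series, cs,
                             score_mode=score_mode)
    spec = CriteriaSpec(weights.weights, directions)
    mairca_res = rank_methods(rating_panel, spec, rs)
    ent = None
    if score_matrix is not None:
        ent = prioritize_operations(score_matrix, mairca_res.Q,
                                    weight_mode=entropy_weight_mode)
    return PipelineResult(q=q, criterion_weights=weights, mairca=mairca_res,
                          entropy=ent)


@dataclass(frozen=True)
class FrameworkComparison:
    """Per-rung pipeline outputs plus cross-framework agreement statistics."""

    results: Mapping[str, PipelineResult]
    weight_table: pd.DataFrame         # criterion x framework weights + dispersion
    q_table: pd.DataFrame              # alternative x framework total gaps
    rank_table: pd.DataFrame           # alternative x framework ranks
    rho: pd.DataFrame                  # framework x framework Spearman rho
    reversals: pd.DataFrame            # framework x framework reversal counts


FRAMEWORK_RUNGS = {"IF": 1, "PF": 2, "IVFF": 3}


def compare_frameworks(
    comparison_scale: LinguisticScale,
    rating_scale: LinguisticScale,
    forward_series: ComparisonSeries,
    inverse_series: ComparisonSeries,
    rating_panel: RatingPanel,
    score_matrix: ScoreMatrix | None = None,
    rungs: Mapping[str, int] | None = None,
    **pipeline_kw,
) -> FrameworkComparison:
    """Re-run the pipeline under each rung and tabulate agreement statistics."""
    rungs = dict(rungs or FRAMEWORK_RUNGS)
    results = {
        name: run_framework(q, comparison_scale, rating_scale, forward_series,
                            inverse_series, rating_panel, score_matrix,
                            **pipeline_kw)
        for name, q in rungs.items()
    }
    weight_table = pd.DataFrame(
        {name: pd.Series(dict(res.criterion_weights.weights))
         for name, res in results.items()}
    )
    weight_table["mean"] = weight_table[list(rungs)].mean(axis=1)
    weight_table["std"] = weight_table[list(rungs)].std(axis=1, ddof=1)
    per_rung_rank = weight_table[list(rungs)].rank(ascending=False).astype(int)
    weight_table["rank_range"] = [
        f"{row.min():d}-{row.max():d}" for _, row in per_rung_rank.iterrows()
    ]
    q_table = pd.DataFrame({n: r.mairca.Q for n, r in results.items()})
    rank_table = pd.DataFrame({n: r.mairca.ranks for n, r in results.items()})
    names = list(rungs)
    rho = pd.DataFrame(index=names, columns=names, dtype=float)
    rev = pd.DataFrame(index=names, columns=names, dtype=int)
    for na in names:
        for nb in names:
            va, vb = results[na].method_ranks(), results[nb].method_ranks()
            rho.loc[na, nb] = spearman_rho(va, vb)
            rev.loc[na, nb] = count_reversals(va, vb)
    return FrameworkComparison(results=results, weight_table=weight_table,
                               q_table=q_table, rank_table=rank_table,
                               rho=rho, reversals=rev)


def run_robustness(
    scenarios: Iterable[float],
    comparison_scale: LinguisticScale,
    rating_scale: LinguisticScale,
    forward_series: ComparisonSeries,
    inverse_series: ComparisonSeries,
    rating_panel: RatingPanel,
    score_matrix: ScoreMatrix | None = None,
    base_k: float = 1.0,
    **pipeline_kw,
) -> pd.DataFrame:
    """Interval-width perturbation study.

    For each width multiplier ``k`` both scales are perturbed about their
    interval midpoints and the full pipeline is re-run; the returned table
    reports method-rank rho/reversals (and operation-rank rho/reversals if
    a score matrix is given) against the ``base_k`` run.
    """
    q = comparison_scale.q

    def run_at(k: float) -> PipelineResult:
        sc = PerturbationScenario(k)
        return run_framework(
            q, comparison_scale.perturb(sc), rating_scale.perturb(sc),
            forward_series, inverse_series, rating_panel, score_matrix,
            **pipeline_kw,
        )

    base = run_at(base_k)
    rows = []
    for k in scenarios:
        res = run_at(k)
        row = {"k": k}
        row["methods_rho"] = spearman_rho(base.method_ranks(), res.method_ranks())
        row["method_reversals"] = count_reversals(
            base.method_ranks(), res.method_ranks()
        )
        if score_matrix is not None:
            row["operations_rho"] = spearman_rho(
                base.operation_ranks(), res.operation_ranks()
            )
            row["operation_reversals"] = count_reversals(
                base.operation_ranks(), res.operation_ranks()
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")
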
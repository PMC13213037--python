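"""Synthetic expert panels and score matrices for property testing.

The generator emulates the structure of the case study's inputs: a small
expert panel rating criteria chains and alternatives on linguistic
scales, and a positive operations-score matrix whose rows live on
heterogeneous per-method scales (one method scoring roughly an order of
magnitude higher than the rest, as questionnaire-style instruments do
next to small integer-score instruments).

Panel concordance is controlled by a single parameter: each judged item
has a latent term drawn uniformly from the scale, and every decision
maker independently either copies it (probability ``concordance``) or
draws an independent uniform term.  ``concordance=1`` makes all decision
makers identical; ``concordance=0`` makes them independent.  All
randomness flows from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import ScoreMatrix
from .fuzzy import DMWeights
from .mairca import RatingPanel
from .piprecia import ComparisonSeries
from .scales import LinguisticScale


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and behaviour of the synthetic study.

    Defaults mirror the emulated study: 12 criteria, 6 alternatives,
    3 decision makers, 23 operations.
    """

    n_criteria: int = 12
    n_alternatives: int = 6
    n_dms: int = 3
    n_operations: int = 23
    concordance: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_criteria < 2 or self.n_alternatives < 2:
            raise ValueError("need at least 2 criteria and 2 alternatives")
        if self.n_dms < 1 or self.n_operations < 1:
            raise ValueError("need at least 1 decision maker and 1 operation")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def criteria(self) -> list[str]:
        return [f"C{i}" for i in range(1, self.n_criteria + 1)]

    @property
    def alternatives(self) -> list[str]:
        return [f"EAM{i}" for i in range(1, self.n_alternatives + 1)]

    @property
    def operations(self) -> list[str]:
        return [f"O{i}" for i in range(1, self.n_operations + 1)]


def _draw_terms(rng: np.random.Generator, terms: list[str], cfg: SyntheticConfig,
                n_items: int) -> list[list[str]]:
    """One latent term per item; per DM copy-or-independent resampling."""
    latent = rng.integers(0, len(terms), size=n_items)
    out = []
    for i in range(n_items):
        row = []
        for _ in range(cfg.n_dms):
            if rng.random() < cfg.concordance:
                row.append(terms[latent[i]])
            else:
                row.append(terms[rng.integers(0, len(terms))])
        out.append(row)
    return out


def generate_comparison_series(
    cfg: SyntheticConfig, scale: LinguisticScale, inverse: bool = False,
) -> ComparisonSeries:
    """Random comparison panel in forward (or reversed) pass order."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1 if inverse else 0])
    )
    order = cfg.criteria[::-1] if inverse else cfg.criteria
    terms = scale.terms()
    drawn = _draw_terms(rng, terms, cfg, len(order) - 1)
    judgments = {c: drawn[i] for i, c in enumerate(order[1:])}
    return ComparisonSeries(order, judgments, DMWeights.equal(cfg.n_dms))


def generate_rating_panel(cfg: SyntheticConfig, scale: LinguisticScale
                          ) -> RatingPanel:
    """Random complete alternatives x criteria rating panel."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    terms = scale.terms()
    ratings: dict = {}
    for a in cfg.alternatives:
        drawn = _draw_terms(rng, terms, cfg, cfg.n_criteria)
        ratings[a] = {c: drawn[j] for j, c in enumerate(cfg.criteria)}
    return RatingPanel(cfg.alternatives, cfg.criteria, ratings,
                       DMWeights.equal(cfg.n_dms))


def generate_score_matrix(cfg: SyntheticConfig) -> ScoreMatrix:
    """Positive methods x operations score matrix with one large-scale row.

    Most rows draw integer-like scores in [2, 13]; one designated row
    (the second-to-last method, mimicking a questionnaire-percentage
    instrument) draws on a 10x larger scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    m, n = cfg.n_alternatives, cfg.n_operations
    base = rng.integers(2, 14, size=(m, n)).astype(float)
    big_row = max(m - 2, 0)
    base[big_row, :] = rng.uniform(60.0, 80.0, size=n)
    return ScoreMatrix(pd.DataFrame(base, index=cfg.alternatives,
                                    columns=cfg.operations))
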
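"""Comparator rankings and evaluation statistics.

Comparators against the integrated mND score:

* RP      — rank product of the raw per-layer scores (average ranks on ties,
            smaller product = better);
* NDPROD  — product of the per-layer diffusion scores x*_il;
* NDMIN   — minimum of the per-layer diffusion scores.

Evaluation statistics:

* recall at module size — fraction of a planted module's M genes appearing
  in the top M positions of a ranking;
* pAUC_n — partial area under the ROC curve truncated at the n highest-
  ranked negatives: (1 / (n * TP)) * sum_{i=1..n} TP_i, where TP_i counts
  the positives ranked above the i-th best negative;
* DP(n) — per pathway, the number of pathway genes in the reference
  method's top n minus the best of the comparator methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diffusion import ScoreMatrix

__all__ = [
    "Ranking",
    "TruthSet",
    "rank_product",
    "nd_prod",
    "nd_min",
    "ranking_from_scores",
    "recall_at_module",
    "pauc",
    "pathway_gain",
]


@dataclass
class Ranking:
    """An ordered gene list, best first, with the score that produced it.

    Ties are broken deterministically by (score desc, gene id asc) — or
    ascending score for smaller-is-better scores like the rank product.
    """

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranking must be a permutation of unique genes")

    def top(self, n: int) -> list[str]:
        return self.genes[:n]


@dataclass
class TruthSet:
    """Known positives (e.g. cancer genes or a planted module) in a universe."""

    positives: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.positives <= self.universe:
            raise ValueError("positives must be a subset of the universe")


def ranking_from_scores(genes: Sequence[str], scores: np.ndarray,
                        ascending: bool = False) -> Ranking:
    """Deterministic ranking: by score (desc unless ``ascending``), gene id asc."""
    scores = np.asarray(scores, dtype=float)
    sign = 1.0 if ascending else -1.0
    order = sorted(range(len(genes)), key=lambda i: (sign * scores[i], genes[i]))
    return Ranking([genes[i] for i in order], scores[order])


def rank_product(scores: ScoreMatrix) -> Ranking:
    """Rank product of the raw scores: per layer, genes are ranked descending
    (average ranks on ties); RP_i is the product of the per-layer ranks and
    the ranking is ascending in RP."""
    ranks = np.column_stack([
        rankdata(-scores.X[:, l], method="average") for l in range(scores.n_layers)
    ])
    rp = ranks.prod(axis=1)
    return ranking_from_scores(list(scores.genes), rp, ascending=True)


def nd_prod(Xstar: np.ndarray, genes: Sequence[str]) -> Ranking:
    """Product of diffusion scores across layers (needs >= 2 layers)."""
    Xstar = np.asarray(Xstar, dtype=float)
    if Xstar.shape[1] < 2:
        raise ValueError("NDPROD needs at least 2 layers")
    return ranking_from_scores(list(genes), Xstar.prod(axis=1))


def nd_min(Xstar: np.ndarray, genes: Sequence[str]) -> Ranking:
    """Minimum of diffusion scores across layers (needs >= 2 layers)."""
    Xstar = np.asarray(Xstar, dtype=float)
    if Xstar.shape[1] < 2:
        raise ValueError("NDMIN needs at least 2 layers")
    return ranking_from_scores(list(genes), Xstar.min(axis=1))


def recall_at_module(ranking: Ranking, module_genes: Iterable[str]) -> float:
    """|module ∩ top-M| / M with M the module size."""
    module = set(module_genes)
    if not module:
        raise ValueError("module is empty")
    if not module <= set(ranking.genes):
        raise ValueError("module genes missing from the ranking universe")
    M = len(module)
    return len(module & set(ranking.top(M))) / M


def pauc(ranking: Ranking, truth: TruthSet, n: int) -> float:
    """Partial AUC truncated at the ``n`` highest-ranked negatives.

    TP_i = number of positives ranked strictly above the i-th best negative;
    pAUC_n = sum(TP_i, i=1..n) / (n * TP) with TP the total positive count.
    1.0 for a ranking with all positives first, 0.0 for the reverse.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if set(ranking.genes) != truth.universe:
        raise ValueError("ranking universe does not match the truth set")
    is_pos = np.fromiter((g in truth.positives for g in ranking.genes),
                         dtype=bool, count=len(ranking.genes))
    TP = int(is_pos.sum())
    if TP == 0:
        raise ValueError("truth set has no positives in the universe")
    n_neg = is_pos.size - TP
    if n_neg < n:
        raise ValueError(f"need at least n={n} negatives, universe has {n_neg}")
    # positives seen before each successive negative, in rank order
    pos_before = np.cumsum(is_pos)[~is_pos]   # at each negative: positives above it
    return float(pos_before[:n].sum()) / (n * TP)


def pathway_gain(
    rankings: Mapping[str, Ranking],
    pathways: Mapping[str, Iterable[str]],
    n_values: Sequence[int] = (50, 100, 150, 250, 300),
    reference: str = "mND",
) -> pd.DataFrame:
    """Per-pathway gain DP(n) of the reference ranking over the best comparator.

    For each pathway and cutoff n, D_method(n) counts pathway genes in the
    method's top n; DP(n) = D_reference(n) - max over the other rankings.
    """
    if reference not in rankings:
        raise KeyError(f"unknown reference ranking {reference!r}")
    others = [name for name in rankings if name != reference]
    if not others:
        raise ValueError("need at least one comparator ranking")
    rows = []
    for name, genes in pathways.items():
        gset = set(genes)
        for n in n_values:
            counts = {m: len(gset & set(r.top(n))) for m, r in rankings.items()}
            rows.append({
                "pathway": name,
                "n": n,
                "D_reference": counts[reference],
                "D_best_other": max(counts[m] for m in others),
                "DP": counts[reference] - max(counts[m] for m in others),
            })
    return pd.DataFrame(rows)
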
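"""Per-layer four-way gene classification.

Two gene sets are built in each layer l: H_l, the high-scoring genes by the
*original* data X (e.g. every mutated gene, or the differentially expressed
genes below an FDR cut), and N_l, the genes whose neighbourhood carries the
most signal, ranked by tp_il = -log10(p^t_il) * T_il. Membership in the two
sets determines the label:

    in H_l and in N_l  -> MODULE     (member of a high-scoring module)
    not in H_l, in N_l -> LINKER     (low own signal, high neighbourhood)
    in H_l, not in N_l -> ISOLATED   (high own signal, quiet neighbourhood)
    in neither         -> NS         (not significant)

By default |N_l| = |H_l|; the cardinality can instead be fixed explicitly,
set by a p^t threshold, or both combined (intersection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .diffusion import ScoreMatrix

__all__ = ["HRule", "NRule", "LayerCriteria", "build_H", "build_N", "classify_genes",
           "LABELS"]

LABELS = ("MODULE", "LINKER", "ISOLATED", "NS")


@dataclass
class HRule:
    """How the high-scoring set H_l of one layer is defined from raw scores."""

    kind: Literal["threshold", "top_n", "explicit"]
    value: float = 0.0          # threshold value or n
    strict: bool = False        # threshold: > instead of >=
    genes: frozenset[str] = field(default_factory=frozenset)  # explicit list

    @classmethod
    def from_config(cls, cfg: Mapping) -> "HRule":
        kind = cfg["kind"]
        if kind == "explicit":
            return cls("explicit", genes=frozenset(cfg["genes"]))
        return cls(kind, value=float(cfg["value"]), strict=bool(cfg.get("strict", False)))


@dataclass
class NRule:
    """How the cardinality / membership of the neighbourhood set N_l is set."""

    kind: Literal["match_h", "top_n", "pt_threshold", "combined"] = "match_h"
    n: int = 0
    pt_max: float = 0.05

    @classmethod
    def from_config(cls, cfg: Mapping | None) -> "NRule":
        if cfg is None:
            return cls()
        kind = cfg.get("kind", "match_h")
        return cls(kind, n=int(cfg.get("n", 0)), pt_max=float(cfg.get("pt_max", 0.05)))


@dataclass
class LayerCriteria:
    """Per-layer H and N rules; every scored layer needs an H rule."""

    h_rules: dict[str, HRule]
    n_rules: dict[str, NRule] = field(default_factory=dict)

    def n_rule(self, layer: str) -> NRule:
        return self.n_rules.get(layer, NRule())


def build_H(scores: ScoreMatrix, criteria: LayerCriteria) -> dict[str, set[str]]:
    """High-scoring gene sets per layer, from the raw (pre-diffusion) scores.

    Deterministic: top-n ties break by (score desc, gene id asc).
    """
    H: dict[str, set[str]] = {}
    for layer, rule in criteria.h_rules.items():
        if layer not in scores.layers:
            raise KeyError(f"H criterion references unknown layer {layer!r}")
        col = scores.X[:, scores.layers.index(layer)]
        if rule.kind == "threshold":
            mask = col > rule.value if rule.strict else col >= rule.value
            H[layer] = {g for g, m in zip(scores.genes, mask) if m}
        elif rule.kind == "top_n":
            n = int(rule.value)
            if n < 0 or n > scores.n_genes:
                raise ValueError(f"top_n={n} out of range for {scores.n_genes} genes")
            order = sorted(range(scores.n_genes), key=lambda i: (-col[i], scores.genes[i]))
            H[layer] = {scores.genes[i] for i in order[:n]}
        elif rule.kind == "explicit":
            missing = rule.genes - set(scores.genes)
            if missing:
                raise ValueError(f"explicit H list contains unknown genes: {sorted(missing)[:5]}")
            H[layer] = set(rule.genes)
        else:
            raise ValueError(f"unknown H rule kind {rule.kind!r}")
    return H


def build_N(
    tp: np.ndarray,
    pt: np.ndarray,
    genes: list[str],
    layers: list[str],
    criteria: LayerCriteria,
    H_sizes: Mapping[str, int],
) -> dict[str, set[str]]:
    """Neighbourhood sets per layer: the genes with the highest tp scores.

    Default cardinality equals |H_l|. Ties break by (tp desc, pt asc,
    gene id asc), so the sets are deterministic.
    """
    tp = np.asarray(tp, dtype=float)
    pt = np.asarray(pt, dtype=float)
    N: dict[str, set[str]] = {}
    n_genes = len(genes)
    for l, layer in enumerate(layers):
        rule = criteria.n_rule(layer)
        order = sorted(range(n_genes), key=lambda i: (-tp[i, l], pt[i, l], genes[i]))
        if rule.kind == "match_h":
            n = H_sizes.get(layer, 0)
            if n > n_genes:
                raise ValueError(f"requested N cardinality {n} exceeds {n_genes} genes")
            N[layer] = {genes[i] for i in order[:n]}
        elif rule.kind == "top_n":
            if rule.n > n_genes:
                raise ValueError(f"requested N cardinality {rule.n} exceeds {n_genes} genes")
            N[layer] = {genes[i] for i in order[: rule.n]}
        elif rule.kind == "pt_threshold":
            N[layer] = {genes[i] for i in range(n_genes) if pt[i, l] <= rule.pt_max}
        elif rule.kind == "combined":
            by_n = {genes[i] for i in order[: rule.n]}
            by_pt = {genes[i] for i in range(n_genes) if pt[i, l] <= rule.pt_max}
            N[layer] = by_n & by_pt
        else:
            raise ValueError(f"unknown N rule kind {rule.kind!r}")
    return N


def classify_genes(
    H: Mapping[str, set[str]],
    N: Mapping[str, set[str]],
    genes: list[str],
    layers: list[str] | None = None,
) -> pd.DataFrame:
    """Assign MODULE / LINKER / ISOLATED / NS per gene and layer.

    The label is a pure function of the two memberships; every gene gets
    exactly one label per layer, so the four classes partition the genes.
    """
    if layers is None:
        layers = sorted(H)
    out = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=list(layers), dtype=object)
    for layer in layers:
        h = H.get(layer, set())
        n = N.get(layer, set())
        labels = []
        for gene in genes:
            in_h, in_n = gene in h, gene in n
            if in_h and in_n:
                labels.append("MODULE")
            elif in_n:
                labels.append("LINKER")
            elif in_h:
                labels.append("ISOLATED")
            else:
                labels.append("NS")
        out[layer] = labels
    return out
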
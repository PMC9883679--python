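"""Synthetic planted-module benchmark instances and null-score generators.

The benchmark emulates a disease-module recovery task: a connected gene
module (a pathway-like subgraph) is embedded in a larger background
interactome, and in each layer a chosen fraction of the module genes
receives "high" scores drawn from a layer-specific pool. Surplus high
values go to random background genes, and everything else is filled from a
"low" pool — so the module is only partially marked in any single layer and
integration across layers plus network proximity is required to recover it.

Two parametric score pools mimic the statistical character of common omics
layers:

* ``mutation-frequency`` — sparse, heavy-tailed values in [0, 1]: the low
  pool is mostly exact zeros (most genes are unmutated in a cohort), the
  high pool spans ~0.05-0.4;
* ``neglog-fdr`` — dense nonnegative values resembling -log10(FDR) from a
  differential-expression analysis: the high pool sits above 7 (FDR below
  1e-7), the low pool below ~3.

Graphs come either from a random-graph generator (background Erdős–Rényi
plus a denser planted module, the test default) or from a user edge list
plus a GMT of pathway gene sets, taking each set's largest connected
component as the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .diffusion import ScoreMatrix
from .interactome import Interactome, from_networkx, load_edge_list, load_gmt

__all__ = [
    "ModuleBenchmarkConfig",
    "PlantedInstance",
    "make_graph",
    "plant_signal",
    "default_pools",
    "null_scores",
]

LAYER_STYLES = ("mutation-frequency", "neglog-fdr")


@dataclass
class ModuleBenchmarkConfig:
    """Parameters of one planted-module benchmark configuration.

    Random-graph mode (default): an Erdős–Rényi background of
    ``n_background`` genes with edge probability ``background_density``
    plus a module of ``module_size`` genes whose internal edge probability
    is ``module_density`` (a random spanning tree guarantees the module is
    connected); module genes attach to the background at background
    density. Pathway mode: ``edge_list_path`` + ``gmt_path`` +
    ``pathway_name`` select the module as the largest connected component
    of a real gene set inside a real network.

    ``pct_high`` gives, per layer, the fraction of module genes that carry
    high-pool values; ``layer_styles`` choose the parametric pools. The
    high pool holds round(pct_high * M) values for the module plus a
    surplus (``high_surplus_frac`` of the background size) that lands on
    non-module genes, making the task a genuine needle-in-haystack search.
    """

    module_size: int = 20
    n_background: int = 200
    background_density: float = 0.04
    module_density: float = 0.3
    pct_high: Sequence[float] = (0.1, 0.1)
    layer_styles: Sequence[str] = ("mutation-frequency", "neglog-fdr")
    high_surplus_frac: float = 0.05
    n_replicates: int = 10
    seed: int = 0
    # pathway mode
    edge_list_path: str | Path | None = None
    gmt_path: str | Path | None = None
    pathway_name: str | None = None
    # optional explicit pools (lists of values, drawn without replacement)
    high_pools: Sequence[Sequence[float]] | None = None
    low_pools: Sequence[Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if self.module_size < 3:
            raise ValueError("module_size must be >= 3")
        if not all(0 < p <= 1 for p in self.pct_high):
            raise ValueError("pct_high entries must lie in (0, 1]")
        if len(self.pct_high) != len(self.layer_styles):
            raise ValueError("pct_high and layer_styles must have one entry per layer")
        for s in self.layer_styles:
            if s not in LAYER_STYLES:
                raise ValueError(f"unknown layer style {s!r}")

    @property
    def n_layers(self) -> int:
        return len(self.pct_high)


@dataclass
class PlantedInstance:
    """One generated benchmark dataset: graph, scores and ground truth."""

    net: Interactome
    scores: ScoreMatrix
    module: set[str]
    high_module_genes: list[set[str]]   # per layer: module genes given high values


def make_graph(config: ModuleBenchmarkConfig, seed: int | None = None
               ) -> tuple[Interactome, set[str]]:
    """Build the benchmark graph and its module gene set.

    Random mode embeds a connected ``module_size``-gene module in an
    Erdős–Rényi background; pathway mode loads the configured edge list and
    takes the largest connected component of the named GMT gene set.
    """
    if config.edge_list_path is not None:
        net = load_edge_list(config.edge_list_path)
        sets = load_gmt(config.gmt_path)
        if config.pathway_name not in sets:
            raise KeyError(f"gene set {config.pathway_name!r} not in GMT")
        members = [g for g in sets[config.pathway_name] if g in set(net.genes)]
        g = nx.from_scipy_sparse_array(net.adjacency)
        relabel = dict(enumerate(net.genes))
        g = nx.relabel_nodes(g, relabel)
        sub = g.subgraph(members)
        if sub.number_of_nodes() == 0:
            raise ValueError("gene set shares no genes with the network")
        module = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)[0]))
        return net, set(module)

    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    m, nb = config.module_size, config.n_background
    if nb < 1:
        raise ValueError("need at least one background gene")
    n = m + nb
    if m > n:
        raise ValueError("module size exceeds graph size")
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    # module nodes 0..m-1: random spanning tree (connectivity) + extra density
    perm = rng.permutation(m)
    for idx in range(1, m):
        graph.add_edge(int(perm[idx]), int(perm[rng.integers(0, idx)]))
    for i in range(m):
        for j in range(i + 1, m):
            if rng.random() < config.module_density:
                graph.add_edge(i, j)
    # background + module-background attachment at background density
    for i in range(n):
        lo = max(i + 1, m) if i < m else i + 1
        for j in range(lo, n):
            if rng.random() < config.background_density:
                graph.add_edge(i, j)
    mapping = {i: (f"M{i:03d}" if i < m else f"B{i - m:04d}") for i in range(n)}
    graph = nx.relabel_nodes(graph, mapping)
    module = {mapping[i] for i in range(m)}
    return from_networkx(graph), module


def default_pools(
    layer_style: str,
    n_high: int,
    n_low: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric high/low score pools for one layer.

    Pools are disjoint in range (min(high) > max(low)) so "high scoring" is
    well defined on every instance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    if layer_style == "mutation-frequency":
        # heavy-tailed frequencies: most cohort genes unmutated
        high = 0.05 + 0.35 * rng.power(0.5, n_high)      # skewed into [0.05, 0.4]
        low = np.where(rng.random(n_low) < 0.85, 0.0,
                       rng.uniform(0.0005, 0.01, n_low))
    elif layer_style == "neglog-fdr":
        high = 7.0 + rng.exponential(2.0, n_high)        # FDR below 1e-7
        low = rng.uniform(0.0, 3.0, n_low)               # FDR above ~1e-3
    else:
        raise ValueError(f"unknown layer style {layer_style!r}")
    return high, low


def plant_signal(
    net: Interactome,
    module: set[str],
    config: ModuleBenchmarkConfig,
    seed: int | None = None,
) -> PlantedInstance:
    """Assign scores: high values inside the module, surplus outside, low fill.

    Per layer, independently: round(pct_high * M) module genes are sampled
    and given draws from the high pool; unused high-pool values go to random
    non-module genes; every remaining gene receives a low-pool value.
    Explicit (finite-list) pools are consumed without replacement.
    """
    seed = config.seed if seed is None else seed
    genes = list(net.genes)
    index = {g: i for i, g in enumerate(genes)}
    module_list = sorted(module)
    outside = sorted(set(genes) - module)
    M, n = len(module_list), len(genes)
    X = np.zeros((n, config.n_layers))
    high_module: list[set[str]] = []
    for l in range(config.n_layers):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, l]))
        n_hi_mod = int(round(config.pct_high[l] * M))
        surplus = int(round(config.high_surplus_frac * len(outside)))
        n_high = n_hi_mod + surplus
        if config.high_pools is not None:
            high = rng.permutation(np.asarray(config.high_pools[l], dtype=float))
            low = rng.permutation(np.asarray(config.low_pools[l], dtype=float))
            if high.size < n_high or low.size < n - n_high:
                raise ValueError("explicit pools too small for the assignment")
        else:
            high, low = default_pools(config.layer_styles[l], n_high, n - n_high,
                                      seed=int(rng.integers(2**31)))
        if high.size and low.size and float(high.min()) <= float(low.max()):
            raise ValueError("high and low pools must be disjoint in range")
        chosen = rng.choice(M, size=n_hi_mod, replace=False)
        hi_genes = {module_list[i] for i in chosen}
        high_module.append(hi_genes)
        out_chosen = rng.choice(len(outside), size=surplus, replace=False)
        hi_out = [outside[i] for i in out_chosen]
        receivers = sorted(hi_genes) + hi_out
        for g, v in zip(receivers, high[: len(receivers)]):
            X[index[g], l] = v
        rest = [g for g in genes if g not in set(receivers)]
        for g, v in zip(rest, low[: len(rest)]):
            X[index[g], l] = v
    layers = [f"L{l + 1}_{config.layer_styles[l]}" for l in range(config.n_layers)]
    return PlantedInstance(net, ScoreMatrix(genes, layers, X), set(module), high_module)


def null_scores(
    N: int,
    L: int,
    distribution: Literal["exponential", "uniform", "constant"] = "exponential",
    seed: int = 0,
) -> ScoreMatrix:
    """I.i.d. nonnegative scores, exchangeable across genes, for calibration."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    if distribution == "exponential":
        X = rng.exponential(1.0, size=(N, L))
    elif distribution == "uniform":
        X = rng.uniform(0.0, 1.0, size=(N, L))
    elif distribution == "constant":
        X = np.ones((N, L))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    genes = [f"g{i:05d}" for i in range(N)]
    layers = [f"L{l + 1}" for l in range(L)]
    return ScoreMatrix(genes, layers, X)
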
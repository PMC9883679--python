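# mndiff — multi-layer network-diffusion gene relevance

`mndiff` ranks genes by combining several layers of molecular evidence —
mutation frequencies, differential-expression significance, per-patient
mutation profiles — with the topology of a genome-scale interaction
network. It is aimed at analysts doing multi-omics gene prioritization and
disease-module detection: the typical question is *which genes matter when
each individual omics layer is noisy, sparse and incomplete, but the
relevant genes cluster in the interactome?*

## Method

Inputs are an undirected interactome `G` with adjacency `A` and a
gene-by-layer matrix `X` of nonnegative scores (one column per layer).

1. **Network diffusion.** Each layer is smoothed by random walk with
   restart over the symmetrically normalized adjacency
   `w_ij = a_ij / sqrt(d_i d_j)`:

   `X_{q+1} = α W X_q + (1 − α) X_0`, iterated until
   `max |X_{q+1} − X_q| < 10⁻⁶` (default `α = 0.7`). The steady state is
   column-normalized by its maximum, giving `X*` with every layer on
   [0, 1].

2. **Neighbour selection.** For gene `i` and layer `l`,
   `T_il` sums the `k_i = min(k, d_i)` largest diffusion scores among the
   first neighbours of `i` (default `k = 3`); `0 ≤ T_il ≤ k_i`.

3. **Integration.** `mND_i = (1/k_i) · (Σ_l x*_il) · (Σ_l T_il)`, the
   product of a gene's own diffused evidence and its neighbourhood's,
   bounded by `L²` for `L` layers. Optional positive per-layer weights
   enter both sums.

4. **Significance.** Gene labels of `X` are permuted (a shared row
   permutation by default), the whole pipeline is recomputed per
   permutation, and `p_i` is the fraction of datasets — observed plus
   permuted, 1000 in total by default — with `mND†_i ≥ mND_i`. The
   significance-weighted score is `mNDp_i = −log10(p_i) · mND_i`; the same
   permutations give per-layer `p^t_il` for `T` and
   `tp_il = −log10(p^t_il) · T_il`.

5. **Classification.** Per layer, `H_l` holds the high-scoring genes by
   raw data and `N_l` the genes with the highest `tp`; each gene is then
   MODULE (in both), LINKER (only in `N_l`), ISOLATED (only in `H_l`) or
   NS (neither).

The package also ships the comparator rankings used to benchmark the
integrated score — rank product (RP) of the raw scores, product (NDPROD)
and minimum (NDMIN) of the per-layer diffusion scores — plus evaluation
statistics (recall at module size, partial AUC `pAUC_n`, per-pathway gain
`DP(n)`) and a synthetic planted-module generator.

## Worked example

Generate a synthetic benchmark instance — a 30-gene connected module
embedded in a 200-gene background network, with 30% of the module genes
marked per layer (one sparse mutation-frequency-like layer, one dense
−log10 FDR-like layer) — then score it:

```python
import mndiff as m

cfg = m.ModuleBenchmarkConfig(module_size=30, pct_high=(0.3, 0.3), seed=11)
net, module = m.make_graph(cfg)
inst = m.plant_signal(net, module, cfg)

result, summary, Xstar = m.run_mnd(inst.scores, net, k=3, alpha=0.7,
                                   n_perm=200, seed=11)
ranking = m.ranking_from_scores(net.genes, result.mNDp)
for g in ranking.top(5):
    i = net.index_of(g)
    print(f"{g}  mND={result.mND[i]:.3f}  p={result.p[i]:.3f}  "
          f"in_module={g in module}")
```

prints

```
M025  mND=2.274  p=0.005  in_module=True
M009  mND=2.068  p=0.005  in_module=True
M026  mND=2.049  p=0.005  in_module=True
M016  mND=1.837  p=0.005  in_module=True
M029  mND=1.823  p=0.005  in_module=True
```

All five top genes are planted module members (`M...` ids) at the smallest
attainable empirical p-value `1/200 = 0.005`. Recall at module size —
the fraction of the 30 module genes in the top 30 of the ranking — is
0.767 for mND versus 0.433 for the rank product of the raw scores, and
the partial AUC at the 50 best-ranked negatives is `pAUC_50 = 0.897`:
network diffusion plus neighbourhood integration recovers module genes
that carry little direct signal in either layer.

The same pipeline is available from the shell:

```sh
mndiff simulate --out-dir inst --module-size 30 --seed 11
mndiff score --network inst/network.tsv --scores inst/scores.tsv \
             --out-dir run --n-perm 200 --seed 11
mndiff benchmark --out bench.tsv --k 1,2,3,5,10
```

`mndiff score` writes a per-gene score table, a per-layer classification
table and a manifest (parameters, seed, input checksums) that makes the
run reproducible byte for byte.

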
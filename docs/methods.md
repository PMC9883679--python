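# Methods

## Model and assumptions

The pipeline treats gene relevance as a joint property of evidence and
topology. Each layer of the input matrix `X` (genes × layers, nonnegative)
is smoothed over the undirected interactome by random walk with restart,

    X_{q+1} = α W X_q + (1 − α) X_0,

with `W` the symmetric degree-normalized adjacency
`w_ij = a_ij / √(d_i d_j)`. Since the spectral radius of `W` is at most 1
and `α < 1`, the iteration is a contraction with the unique fixed point
`X^ss = (1 − α)(I − α W)⁻¹ X_0`; convergence is guaranteed for every
graph. `X^ss` is column-normalized by each column's maximum to `X*`.
Because diffusion is linear per column, `X*` — and hence every downstream
quantity — is invariant to rescaling any input layer by a positive
constant. This is what licenses mixing heterogeneous layers (sparse
frequencies next to dense −log10 FDR values) without further calibration,
and it is why only `X^ss`, not the input, needs normalizing.

The integrated score multiplies a gene's own diffused evidence with that
of its strongest neighbours:

    T_il  = sum of the k_i largest x*_jl over first neighbours j of i,
    mND_i = (1/k_i) (Σ_l x*_il) (Σ_l T_il),      k_i = min(k, d_i).

The underlying assumption is the standard disease-module hypothesis:
relevant genes and their functional partners occupy a connected
neighbourhood of the interactome, so a gene flanked by high-evidence
neighbours in *any* combination of layers deserves a boost that neither
the raw scores nor per-layer diffusion alone provides.

Significance is purely empirical. Gene labels of `X` are permuted, the
whole pipeline is recomputed, and `p_i` is the fraction of datasets
(observed + permuted, `P` total) with `mND†_i ≥ mND_i`. The observed
dataset counts in the denominator, so `p ∈ [1/P, 1]` and the transforms
`mNDp = −log10(p)·mND` and `tp = −log10(p^t)·T` are always finite. The
`tp` score also breaks the frequent ties among genes with equal `T`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha`   | 0.7   | topology-vs-input trade-off of the walk; larger spreads evidence further |
| `tol`     | 1e-6  | termination threshold on `max |ΔX|`, checked on the un-normalized iterate |
| `max_iter`| 10000 | safety cap; convergence is geometric at rate ≈ α, so ~50 iterations suffice in practice |
| `k`       | 3     | neighbours aggregated into `T`; small k focuses on the strongest partners |
| `n_perm`  | 1000  | total permutation datasets (observed + 999), p-value floor 1/1000 |
| `scheme`  | joint-rows | one shared row permutation across layers |
| `layer_weights` | all 1 | positive coefficients in the two sums of the score |

`alpha = 0.7` and `k = 3` are the conventional operating point for this
family of propagation methods; results are insensitive to one-step changes
in either. The `k`-sweep benchmark (`mndiff benchmark --k 1,2,3,5,10`)
shows recall saturating by `k ≈ 3-5` on planted modules.

### Permutation scheme

Joint-rows (default) moves whole rows of `X`, preserving each gene's
cross-layer correlation under the null — the appropriate null when layers
are biologically coupled (a mutated gene is often also differentially
expressed). Per-layer permutation destroys that coupling and yields a
stricter null for cross-layer agreement; it is available via
`scheme="per-layer"`. This is the main interpretive choice in the
significance machinery, and the two schemes give visibly different
p-values on correlated inputs.

### Classification criteria

`H_l` (high by raw data) accepts a threshold (≥ or >), a top-n cut, or an
explicit gene list per layer. `N_l` (high by neighbourhood) defaults to
the top `|H_l|` genes by `tp` — the simplest reading of "in proportion to
|H_l|" — and can instead be an explicit n, a `p^t` threshold, or the
intersection of both. Membership of "the neighbourhood of i in `N_l`" is
operationalized as membership of gene i itself in `N_l`, since `N_l` is
defined over genes through their own neighbourhood summary `T_i`. All tie
breaks are deterministic: (score desc, gene id asc) for `H`, (tp desc,
p^t asc, gene id asc) for `N`.

## Numerical choices

- Termination is checked on the un-normalized iterate; `X*` is computed
  once after convergence.
- Inside the permutation loop the steady state is obtained from the
  precomputed dense kernel `K = (1 − α)(I − α W)⁻¹` when the network has
  ≤ 2000 genes (one solve, then one matrix product per permutation), and
  by the iterative scheme otherwise. The two routes agree elementwise to
  better than 1e-5 (tested), and comparison counts are identical on
  non-degenerate data.
- Each permutation is seeded independently from (master seed, permutation
  index), so results are bitwise independent of loop chunking and any
  future parallelism.
- Top-k selection uses partial sorting; the selected values are summed in
  ascending neighbour order, which makes `T` bitwise identical to the
  exhaustive subset-enumeration oracle. Ties among neighbour values do not
  affect `T` (tied values contribute equally).
- Degenerate genes: degree-0 genes have `T = 0`, `k_i = 0` and are
  assigned `mND = 0`, `p = 1`; their steady state is `(1 − α)x_0` (no
  incoming flow). All-zero layers are permitted with a warning — patient-
  level layers can legitimately be empty. The theoretical bounds
  `0 < T ≤ k_i` and `0 < mND ≤ L²` hold strictly for non-degenerate genes
  and with 0 attained only in these degenerate cases.
- Output tables are written at full double precision with no timestamps,
  so a rerun from the manifest is byte-identical.

## Synthetic benchmark

The generator emulates a pathway-module recovery task. A connected module
of `M` genes (random spanning tree + internal edge probability 0.3) is
embedded in an Erdős–Rényi background of 200 genes with mean degree ≈ 8
(edge probability 0.04); module genes attach to the background at
background density. Per layer, `round(pct_high · M)` module genes receive
draws from a high pool, the surplus of the high pool (5% of the
background size) lands on random non-module genes, and all other genes
draw from a low pool — so a ranking method must exploit both layers and
topology, not just find every high value.

Two parametric pools mimic common evidence types: `mutation-frequency`
(low pool 85% exact zeros, rest ≤ 0.01; high pool skewed over
[0.05, 0.4]) and `neglog-fdr` (high pool ≥ 7, i.e. FDR < 1e-7; low pool
uniform on [0, 3]). High and low pools are disjoint in range by
construction, and finite user-supplied pools are consumed without
replacement. Pathway mode replaces the random graph with a user edge list
and a GMT gene set, taking the set's largest connected component inside
the network as the module.

What the generator does **not** reproduce: scale-free degree structure of
real interactomes, correlated evidence between layers, empirical score
distributions of any particular cohort, or overlapping modules. Passing
benchmarks therefore demonstrate correct mechanics and the qualitative
advantage of neighbourhood integration, not performance guarantees on any
real dataset.

Problem sizes in the shipped benchmark — 9 configurations (module sizes
10/30/50 × marked fractions 0.1/0.3/0.5), 10 signal replicates each,
220-250-gene graphs, 200-permutation nulls at 500 genes — were chosen as
the smallest sizes at which the recall orderings and calibration
stabilize across seeds.

## Known limitations

- Single fixed topology shared by all layers; no edge directions.
- Weighted-adjacency mode exists but is off by default; the scoring
  theory (bounds on `T`, `mND`) assumes binary incidence.
- Empirical p-values are granular at `1/n_perm`; with the default 1000
  permutations nothing below 0.001 is resolvable.
- The permutation null treats genes as exchangeable; strong degree-
  evidence correlation in real data (mutation frequency vs gene length,
  say) is not modelled and may make the null optimistic.
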
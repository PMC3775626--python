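# phylodiv

Phylogenetic and discrete alpha-diversity toolkit centred on the
balance-weighted phylogenetic diversity family **BWPD_θ**, which
interpolates between classical (unrooted) Faith PD (θ = 0) and a fully
abundance-weighted variant (θ = 1):

    BWPD_θ(s) = Σ_i ℓ_i · [2 · min(x_i, 1 − x_i)]^θ

where ℓ_i is the length of edge *i* and x_i is the fraction of the sample's
reads on the distal side of that edge.

The package provides:

- **`phylodiv.data_model`** — Newick trees (quoted labels, multifurcations,
  rerooting), count tables (TSV and BIOM-JSON v1.0), tree/table alignment,
  and per-edge distal read masses computed in one post-order pass.
- **`phylodiv.phylo_alpha`** — unrooted PD, BWPD_θ, rooted RBWPD_θ,
  phylogenetic quadratic entropy, phylogenetic entropy, and the order-q
  phylogenetic Hill diversity ^qD̄(T), plus a batch samples × measures API.
- **`phylodiv.discrete_alpha`** — Shannon, Gini-Simpson, Chao1
  (bias-corrected by default), and ACE on plain abundance vectors.
- **`phylodiv.rarefaction`** — subsampling without replacement
  (multivariate hypergeometric), mean-over-replicates protocol, the exact
  closed form E[PQE_k] = (k−1)/(k·n·(n−1)) · Σ ℓ_i d_i (n−d_i) for quadratic
  entropy under rarefaction, and a full-vs-rarefied sensitivity experiment.
- **`phylodiv.comparative`** — Pearson correlation between measures,
  hierarchical clustering at distance 1 − r, leave-one-out logistic-regression
  accuracy, linear R², Welch t / ANOVA stratification p-values, and mean-rank
  aggregation.
- **`phylodiv.synthetic`** — deterministic toy trees and a two-state
  (dominated vs even) Dirichlet-multinomial community generator for testing
  without any external dataset.

## CLI

```sh
# simulate a two-state fixture (tree, table, metadata, params sidecar)
phylodiv simulate --n-leaves 64 --n-samples 50 --seed 1 --out-dir sim/

# per-sample measures, as means over 100 rarefactions to the minimum depth
phylodiv fpd --tree sim/tree.nwk --table sim/table.tsv \
    --rarefy min --replicates 100 --seed 1 --out measures.tsv

# unrarefied values
phylodiv fpd --tree sim/tree.nwk --table sim/table.tsv \
    --rarefy none --measures pd_u,bwpd_0.25,bwpd_0.5,bwpd_1,pqe --out measures.tsv

# rarefy a table to a common depth
phylodiv rarefy --table sim/table.tsv --k min --seed 1 --out rarefied.tsv

# rank measures against the metadata (state / score / stratum columns)
phylodiv compare --matrix measures.tsv --metadata sim/metadata.tsv --out-dir report/
```

Measure ids: `pd_u`, `bwpd_<θ>`, `rbwpd_<θ>`, `pqe`, `phylo_entropy`,
`qdt_<q>`, `shannon`, `simpson`, `chao1`, `ace`. Default grids are
θ ∈ {0, 0.25, 0.5, 1} and q ∈ {0, 0.25, 0.5}. Exit codes: 0 success,
1 internal error, 2 user/input error. Each command writes a
`provenance.json` next to its outputs.

Conventions: an edge belongs to its child node (the root carries no edge);
`pd_u`, `bwpd_*` and `pqe` are invariant to the root placement, while
`rbwpd_*`, `phylo_entropy` and `qdt_*` are root-dependent and expect the
caller to fix a meaningful root (see `phylodiv.data_model.reroot`).
Entropies use natural log. `qdt_<q>` reports the effective-number (mean
diversity) form; `hill_qdt(..., scaled=True)` exposes the branch-length
scaled product instead.

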
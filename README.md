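# persimod

Persistent-homology disease modules of GWAS hits in protein–protein
interaction (PPI) networks.

Genes associated with a complex disease tend to cluster into a connected
*disease module* in the interactome; the classical observable module is the
largest connected component (LCC) of the subnetwork induced by the
genome-wide-significant GWAS genes. `persimod` generalizes this idea to
higher-order topology: as the association p-value threshold δ grows from 0
to the genome-wide cutoff 5×10⁻⁸, the hit-induced subnetwork grows, and its
clique (flag) complex

  W_δ = { σ = [v₀,…,v_k] ∈ K : p(vᵢ) ≤ δ for all i }

forms a filtration of simplicial complexes. Persistent homology over ℤ/2ℤ
tracks when connected components (H₀), loops (H₁) and voids (H₂) are born
and die along this filtration. The *n-th persistent disease module* is the
union of the n-dimensional holes that survive every threshold — the LCC for
n = 0, and the union of essential-cycle representatives for n ≥ 1. Module
sizes are tested against a degree-preserving null: random node sets matched
to the hit genes' degree profile, scored as z = (LCC_obs − ⟨LCC⟩_rnd)/σ_rnd
with an add-one right-tail empirical p over the randomized repetitions.

The package is for network-medicine and topological-data-analysis
practitioners who want to run this pipeline on their own GWAS + interactome
data, or validate it end to end on synthetic studies with planted ground
truth.

## What is inside

| module | purpose |
| --- | --- |
| `persimod.io` | PPI edge lists, GWAS tables (catalog or gene/p dialects), locus→gene mapping rules, exact log₁₀-p parsing for p-values far below float underflow (e.g. `3e-695`) |
| `persimod.filtration` | flag-complex filtration of the hit-induced subgraph, lower-star (max-vertex) values |
| `persimod.persistence` | GF(2) boundary-matrix column reduction with representative cycles, Betti curves, and an independent dense GF(2) rank oracle |
| `persimod.modules` | persistent-module extraction and summaries |
| `persimod.nullmodel` | degree-binned node sampling, null distributions, z-scores, empirical p |
| `persimod.enrichment` | offline hypergeometric over-representation against GMT gene sets with Benjamini–Hochberg adjustment |
| `persimod.synthetic` | scale-free study generator with planted chordless cycles and connected components (ground truth manifests) |
| `persimod.cli` | `persimod run / persist / null / simulate / enrich` |

## Worked example

Generate a synthetic study (a 200-node scale-free network with one planted
chordless 5-cycle, a 20-gene connected hit component and 8 background
hits), then run the full pipeline:

```sh
persimod simulate --n 200 --cycles 5 --component-size 20 --background 8 \
    --seed 4 --out study/
persimod run --ppi study/ppi.tsv --gwas study/gwas.tsv \
    --maxdim 2 --nreps 200 --seed 4 --out study/out/
```

which prints:

```
[read_ppi] nodes=205, edges=403
[map_hits] n_hits=33, drops={}
[filtration] n_simplices=63, by_dim={0: 33, 1: 29, 2: 1}
[persistence] n_pairs=10, essential={0: 6, 1: 1}
[module_dim0] dim=0, n_nodes=28, n_edges=29, n_classes=1
[module_dim1] dim=1, n_nodes=5, n_edges=5, n_classes=1
[null_lcc_size] observed=28.0, mean=5.9, z=7.727, p=0.00498
[null_module_size] observed=5.0, mean=0.06, z=10.16, p=0.00498
done in 0.2s -> study/out
```

Reading the output: 33 of the simulated genes are genome-wide-significant
hits present in the network; their induced flag complex has 63 simplices.
Six connected components never merge (essential H₀ classes) — the largest,
28 nodes / 29 edges, is the 0-th persistent disease module. Exactly one
loop persists over all thresholds: the planted 5-cycle, recovered as the
1-st persistent disease module with 5 nodes / 5 edges. Both modules are
far larger than degree-matched chance (z = 7.7 and 10.2; add-one empirical
p ≈ 0.005 at 200 repetitions). The output directory also holds
the persistence diagram (`diagram.csv`), Betti curves
(`betti_curves.csv`), per-dimension module node/edge tables and the null
summary JSON, each stamped with a config hash.

For real data, point `--ppi` at an interactome edge list and `--gwas` at
either a two-column gene/p table or a GWAS-catalog-style association export
(`--gwas-format catalog`), and raise `--nreps` to 1000.

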
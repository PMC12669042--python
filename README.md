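# mirank

Network-propagation ranking of bioactive molecules and drugs against a
disease on a heterogeneous **multiscale interactome** — a graph whose nodes
are proteins (genes) and biological functions, joined by protein–protein,
protein–function, and function–function (hierarchy) edges.

The motivating application is nutraceutical and drug repurposing for
polygenic disorders such as polycystic ovary syndrome (PCOS): given a small
set of disease-associated genes and target tables for thousands of food
compounds or pharmacological agents, which molecules act on the disease's
network neighborhood — including through indirect, multi-hop pathways that
a direct gene-overlap comparison misses?

## Method

Each entity (molecule, drug, or the disease itself) is a binary seed vector
over the `N` interactome nodes: `m_i = 1` if protein `i` is a target of the
molecule, `d_i = 1` if gene `i` is associated with the disease. A biased
random walk with restarts is propagated from the seeds,

```
p_{t+1} = (1 − r) · Wᵀ p_t + r · p_0,     t = 0 … k−1
```

where `p_0` is uniform over the seeds, `r` is the restart probability
(default 0.15), `W` is the row-stochastic transition operator whose move
weights depend on the traversal type (protein→protein, protein→function,
function→protein, and up/down the function hierarchy), and `k = 1000`
steps, which converges geometrically at rate `(1 − r)` to the fixed point.
The result is the entity's **diffusion profile** `DP ∈ ℝ^N`, a probability
distribution describing how often the walk visits each node.

Molecules are ranked by the cosine similarity `cos(DP⁽ᵐ⁾, DP⁽ᵈ⁾) ∈ [0, 1]`
to the disease profile. Downstream stages:

- **Elbow detection** finds the cutoff between top candidates and the
  remainder as the largest successive drop in the sorted score curve.
- **Fisher validation** tests whether literature-labelled "beneficial"
  molecules are enriched above the cut (exact hypergeometric arithmetic,
  one-sided by default).
- **Overlap baseline** ranks by direct target/disease-gene set cosine, the
  standard non-propagation comparison.
- **Subset robustness** re-runs the pipeline with a reduced disease gene
  set and reports top-k agreement.
- **Localized subgraphs** extract the region where a molecule's and the
  disease's profiles are jointly high, for mechanism-of-action figures.
- **Target-set classes** group drugs with identical resolved target sets
  (identical seed vectors ⇒ identical scores).

A synthetic-data module generates desk-scale heterogeneous interactomes
(scale-free protein layer, tree-structured function layer) with *planted*
beneficial molecules whose targets concentrate around the disease
neighborhood, so the whole pipeline is testable without external downloads.

## Worked example

```
$ mirank simulate --preset bench --seed 11 --out demo
bench: 580 nodes, 100 molecules -> demo

$ mirank rank --interactome demo --targets demo/targets.tsv \
              --disease demo/disease_genes.txt --out demo/ranking.csv
elbow after rank 12 (drop 0.1198)
100 entities ranked -> demo/ranking.csv

$ head -4 demo/ranking.csv
rank,entity_id,entity_name,entity_class,similarity
1,M013,molecule-13,bioactive_molecule,0.903922
2,M002,molecule-2,bioactive_molecule,0.887653
3,M011,molecule-11,bioactive_molecule,0.887547

$ mirank validate --ranking demo/ranking.csv --categories demo/categories.tsv \
                  --cut auto --window 15
{
  "cut": 12,
  "window": 15,
  "table": [[12, 0], [3, 12]],
  "p_greater": 2.617370365384903e-05,
  "p_two_sided": 3.658566049197359e-05
}
```

The simulated bundle plants 15 beneficial molecules (500-protein network);
the walk ranks 12 of them above the detected elbow with none of the
next-window background molecules mislabelled beneficial, and the one-sided
exact test confirms the enrichment is far from chance (`p ≈ 2.6e-5`).
`mirank profile` exports a single diffusion profile, and `mirank subgraph`
writes the GraphML/DOT mechanism subgraph for one molecule.

All functionality is available as a library:

```python
from mirank import SimParams, generate_benchmark, rank_against_disease

graph, disease_genes, molecules, labels = generate_benchmark(seed=0)
result = rank_against_disease(graph, molecules, disease_genes)
print(result.ranking.entries[0])
```

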
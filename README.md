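# crcinvasion

Invasion-subtype analysis of colorectal tumor cohorts, built for comparative
(dog–human) studies. The package implements the computational chain that turns
tumor expression matrices, gene-set signatures, microbial read-count tables
and ortholog protein sequences into:

* **expression clusters** — NMF metagene factorization with restart-consensus
  rank selection, hierarchical clustering of top-variable genes, and PCA;
* **signature enrichment profiles** — single-sample GSEA (ssGSEA) scores and
  two-group GSEA with a permutation null;
* **invasion-subtype calls** — each tumor assigned to *proliferative*,
  *collective*, *crypt-like* or *EMT* invasion (or left unclassified) from its
  signature profile, with cross-tabulation against external labels such as the
  consensus molecular subtypes (CMS);
* **microbiome profiles** — taxonomy-level aggregation, per-taxon log2
  enrichment against the cohort median, and Simpson/Shannon diversity;
* **cross-species mutation annotations** — ortholog residue mapping by global
  protein alignment, β-catenin phosphodegron flagging, and premature-stop
  detection in intron-retaining transcripts.

A synthetic-cohort generator (`crcinvasion.synthetic`) produces every input
the pipeline consumes, with planted ground truth, so all workflows run and are
tested without any external download. It is first-class, tested code, not a
fixture dump.

## The statistics at the core

**ssGSEA running sum.** Within each sample, genes are replaced by ranks
(1 = lowest; ties broken by gene id). For a gene set *S* with the genes walked
in descending rank order, the enrichment score is

    ES(S) = Σ_i [ P_hit(i) − P_miss(i) ]
    P_hit(i)  = Σ_{g ∈ S, rank ≥ i-th} rank(g)^α / Σ_{g ∈ S} rank(g)^α
    P_miss(i) = #{g ∉ S above position i} / #{g ∉ S}

with weight exponent α = 0.25 by default. Positive ES: the set concentrates at
the top of the sample's expression profile.

**Nearest-archetype classification.** ssGSEA scores are z-scaled per
signature across the cohort (population SD). Each subtype is an *archetype*: a
±1/0 pattern over signatures (shipped as an editable TSV,
`src/crcinvasion/data/archetypes.tsv`). A sample's similarity to an archetype
is the cosine between its z-score vector and the ±1 pattern over the
archetype's nonzero support; the best archetype's label is assigned when the
similarity ≥ τ (default 0.5) and the margin over the runner-up ≥ δ
(default 0.12), otherwise the sample is `unclassified`.

**Diversity.** For per-species read counts *n_i* with total *N*:
Simpson `D = 1 − Σ n_i(n_i−1)/(N(N−1))` and Shannon `D = −Σ p_i ln p_i`,
`p_i = n_i/N` (natural log).

**Cross-tabulation.** Per-cell one-sided hypergeometric over-representation
p-values on the contingency table of our labels vs an external labelling.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
python examples/01_cluster_expression_cohort.py
```

prints (abridged):

```
cohort: 560 expressed genes x 26 samples

rank selection profile (stability + error elbow):
      cophenetic  reconstruction_error  improvement
rank
2          1.000               144.242        0.181
3          1.000               122.963        0.148
4          1.000               110.093        0.105
5          0.999               106.669        0.031
6          1.000               103.229        0.032
chosen rank: 4  (4 groups were planted)

NMF assignments vs truth: adjusted Rand index = 1.00 (1.0 = perfect)
hclust (top-500 variable genes) ARI = 1.00
```

Reading: every candidate rank is stable across restarts (cophenetic ≈ 1), but
only up to rank 4 does an extra metagene buy a ≥5% drop in reconstruction
error — the planted four-group structure. At that rank the argmax-coefficient
assignments reproduce the planted groups exactly (ARI 1.0), as does
hierarchical clustering on the 500 most variable genes.

`examples/03_subtype_classification.py` runs the full classification chain on
a 200-tumor archetype cohort (classifying ~80% of tumors, with both crypt-like
and EMT calls concentrating in the mesenchymal-like external subtype), and
`examples/05_mutation_mapping.py` shows the +13 ortholog offset mapping,
degron flags for the recurrent β-catenin hotspots, and premature-stop
detection.

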
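# Methods

This note documents the models, parameter defaults and design choices behind
`crcinvasion`, what the synthetic cohorts do and do not emulate, and the known
limitations. Nothing here states an empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## 1. Expression model and the synthetic cohorts

Expression values live on a log2(FPKM+1)-like scale. The generator draws
every gene i.i.d. Gaussian: background genes at `baseline_mean` (default 5.0)
with `noise_sd` (default 1.0); each planted signature gene is shifted by
`direction × effect × noise_sd` in the subtypes that activate (+1) or suppress
(−1) its set. A Gaussian marginal is a deliberate simplification — the
downstream methods are rank-based (ssGSEA) or variance/correlation-based
(clustering, PCA), so the marginal family is not critical, and it keeps effect
sizes interpretable in SD units. Values are not clipped at zero (negatives are
~5 SD events at the default baseline); the NMF entry point clips residual
negatives with a logged count.

What the cohorts do **not** emulate: gene–gene correlation beyond the planted
sets, heavy-tailed and zero-inflated FPKM marginals, library-size and batch
effects, and any relationship between signature genes and real gene
identities. Passing recovery tests therefore demonstrates that the methods
recover the structure they are designed for at realistic effect sizes — not
that any particular real cohort would classify identically.

Two presets define the package's study conditions:

* **Archetype (human-scale) cohort** — 4 subtypes × 50 tumors, one planted
  25-gene set per signature column of the archetype matrix (published CRC
  signatures are typically tens of genes), 400 background genes, effect 1 SD.
  Used for classifier calibration and recovery.
* **Canine-like cohort** — 26 samples in four groups (12 proliferative, 8
  invasive, 4 normal-like, 2 stromal), each with a 40-gene marker program
  *high at home and low abroad* (+1/−1 directions, effect 2.5 SD, i.e. a 5-SD
  between-group contrast on markers). Tissue markers are on/off in log space;
  a one-sided bump over a shared baseline leaves NMF baseline-dominated and
  makes rank identification ill-posed, so the two-sided design is the
  realistic as well as the analyzable one.

Reproducibility: a config plus seed yields byte-identical output; configs
carry a SHA-256 digest into the truth labels.

## 2. ssGSEA and two-group GSEA

Ranks are assigned within each sample, 1 = lowest. Ties get **distinct** ranks
by lexicographic gene id: average ranks would break the running sum's integer
steps, and the lexicographic rule is deterministic across platforms. The
running-sum score uses hit weights `rank^α` normalised over in-set genes and
uniform miss increments; the score is the *sum* of the running difference over
all positions (the integral form), so it is invariant under any strictly
increasing per-sample transform of expression. Defaults: weight exponent
α = 0.25; optional normalization divides all scores by the global max−min of
the score matrix. Both are flags — conventional choices, since the upstream
literature rarely states them. A set must have ≥ 2 genes in the matrix and
must not cover the whole universe (the miss denominator would vanish).

The two-group test ranks genes by signal-to-noise `(m₁−m₂)/(s₁+s₂)` with each
group SD floored at `0.2·|mean| + 1e−8` (the standard guard against
zero-variance genes), computes the weighted Kolmogorov–Smirnov statistic
(maximum deviation, signed, hit weights `|metric|^1`), and calibrates by
permutation: **phenotype** (label) permutation when both groups have ≥ 7
samples, **gene-set** permutation otherwise — tiny cohorts cannot support
label permutation. P-values use the add-one estimator
`(1 + #{|null| ≥ |obs|})/(n_perm + 1)`, so p = 0 is impossible and granularity
is 1/(n_perm+1). No multiple-testing correction is applied across sets (raw
p-values are reported); leading-edge reporting and preranked mode are out of
scope.

## 3. NMF metagene clustering and rank selection

The factorization is Lee–Seung multiplicative updates minimising squared
Frobenius error — the reference algorithm for metagene extraction, chosen
because its monotonicity is provable and is *asserted on every iteration* (a
violation aborts the run). Defaults: 30 restarts, max 2000 iterations,
relative-change tolerance 1e−6, uniform random initialisation scaled to the
matrix mean. Sample assignment is the argmax coefficient after rescaling H by
the W column norms (the multiplicative scale ambiguity otherwise makes the
argmax arbitrary); ties go to the lowest component index.

Rank selection fits each candidate with restarts and accepts a candidate only
if it is both **stable** — cophenetic correlation of the restart-consensus
(co-assignment) matrix ≥ 0.95 — and **informative** — relative reconstruction
error improvement over the next-lower rank ≥ 5%. The largest accepted
candidate wins; if none is accepted (pure noise) the lowest candidate is
returned with a warning. Stability alone cannot select the rank: on cleanly
separated data the consensus stays near-perfectly ultrametric well past the
true rank, whereas the error elbow (≈10% improvement entering the true rank,
≈3% past it on the canine-like preset) localises it. The 5% threshold sits
between those regimes and is exposed as a parameter.

"Expressed" means value > 0 on the log2 scale in at least `min_expressed_samples`
samples (default 1). Hierarchical clustering uses 1 − Pearson correlation
distance over the top-variance genes with average linkage; constant sample
profiles are an error naming the sample. PCA centers genes across samples.

## 4. Subtype classification

The classifier is a transparent nearest-archetype rule, documented as a
reconstruction rather than a byte-level reimplementation of any published
pipeline. Scores are z-scaled per signature with the **population** SD
(divide by n) so small hand checks are exact; constant rows become zeros with
a warning. Similarity is the **uncentered correlation (cosine)** between the
z-vector and the ±1 pattern over the archetype's nonzero entries. Cosine
rather than a second Pearson centering because archetype supports may be
one-sided (the crypt-like pattern is all +1), which has zero variance and
would make Pearson undefined; the scores are already cohort-centered by the
z-scaling, so the two coincide in spirit. A zero-norm sample vector over a
support gets similarity 0. Ties in the best similarity break by archetype row
order (proliferative, collective, crypt-like, EMT) and are logged.

Thresholds: a sample is labelled only if confidence ≥ τ = 0.5 and margin
(best − second best) ≥ δ = 0.12. These defaults were calibrated once so that
roughly a fifth of a 1-SD-effect archetype cohort falls below threshold,
matching the unclassified rate typical of cohort-scale CRC subtyping; both are
exposed. Under the shipped archetype table the mutually closest pairs are
proliferative↔collective and crypt-like↔EMT; margins are smallest for the
former, and crypt-like and EMT are each other's runner-up archetype
essentially always — the structural sense in which those two invasion modes
are "similar".

Cross-tabulation reports per-cell one-sided hypergeometric
over-representation p-values (population = doubly-labelled samples, successes
= row total, draws = column total) plus a Bonferroni column; enrichment claims
in the source literature are qualitative, so raw p-values are primary.

Known limitation: the flag depends only on the archetype patterns and
thresholds supplied; reproducing any specific published cohort's per-subtype
counts would additionally require that cohort's expression data and exact
signature gene lists, which are deliberately out of scope.

## 5. Microbiome profiling

Input is a taxa × samples integer read-count table with phylum/family/species
lineage — the product of host-read depletion and database mapping, which is
out of scope (an external aligner's job). Aggregation sums counts within a
lineage level and conserves per-sample totals. Enrichment is
`log2((rpm + c) / (cohort median rpm + c))` with pseudocount c = 0.5 —
the cohort median baseline and the pseudocount are this package's explicit
choices, switchable, since heatmap-style enrichment is rarely given a formula.
Diversity is computed at species level: Simpson in the unbiased
pairwise-draw form `1 − Σ nᵢ(nᵢ−1)/(N(N−1))` (N ≥ 2 required), Shannon with
natural log and the 0·ln 0 → 0 convention (N ≥ 1 required). Group comparison
uses medians/IQRs and two-sided Mann–Whitney tests; identical groups report
p = 1.

The taxon generator draws cohort propensities from a symmetric Dirichlet
(α = 0.3, heavy-tailed as shotgun profiles are), perturbs them per sample
(Dirichlet, concentration 200), applies planted fold-changes, and draws
multinomial counts at exactly the configured depth — depleted samples get
depth/10. Defaults: 300 taxa, 5,000 reads per typical sample. Those are the
realistic magnitudes for WGS-scavenged tumor microbiomes, where only
thousands of microbial reads survive host depletion; they also matter
mechanistically, because the plug-in Shannon estimator's downward bias
(≈(S−1)/2N) is what links lower sequencing depth to lower measured diversity.
At metagenomic depths (≥10⁵ reads) Shannon is effectively depth-invariant and
a pure-depletion contrast would vanish. A planted fold-enrichment is only
detectable on a taxon whose baseline abundance clears sampling noise;
workflows that exercise planted enrichment should target an abundant taxon.

## 6. Mutation annotation

Global protein alignment uses Needleman–Wunsch with affine gaps via
Biopython's `PairwiseAligner` (BLOSUM62, gap open 10, gap extend 0.5 —
standard protein defaults), taking the aligner's first optimal traceback for
determinism. The residue correspondence map is monotone and injective on
non-gapped positions; coordinates are 1-based everywhere in the protein and
CDS interfaces.

The β-catenin degron spec marks D32 and G34 as motif-structural, S33/S37/T41
as phospho-acceptors and S45 as the priming phospho-site. T41 is included as
part of the canonical CK1/GSK3 phosphorylation cascade even though it is
interpretive rather than derived from a reported mutation. Flagging is purely
positional — the alternate residue is not scored (a conservative substitution
at a critical site flags identically), a documented limitation. Ortholog
sequences (e.g. real TP53 pairs) are user-supplied FASTA; the shipped
generator builds toy pairs with known truth maps instead of bundling
downloads.

Premature-stop detection scans non-overlapping codons from a frame offset and
reports TAA/TAG/TGA starts (optionally only those before an annotated
canonical stop) plus the truncated protein length. The two-stop
intron-retention example in the tests is a constructed fixture, not a real
intron sequence.

## 7. Problem sizes and numerical conventions

Simulation-based tests and the acceptance script use: the 200-sample archetype
cohort; ten 26-sample canine-like cohorts each for factorization recovery and
for rank selection (10 restarts, candidates 2–6); 500 null simulations of a
60-gene, 10 + 10-sample cohort at 199 permutations for type-I calibration; 100
replicate 300-taxon tables for the diversity contrast; and the exhaustive
ssGSEA oracle over all 1,002 subsets of sizes 2–8 of a 10-gene universe × 100
samples at tolerance 1e−9. These sizes are chosen so the full suite runs in a
few minutes on a single CPU while leaving every comparison statistically
interpretable. All stochastic tests fix seeds; acceptance derives every stream
from the `--seed` argument.
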
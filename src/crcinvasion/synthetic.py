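"""Synthetic cohort generation.

Every downstream stage of the pipeline (clustering, enrichment scoring, subtype
classification, microbiome profiling, mutation mapping) is exercised on data from
this module, so no external download is ever required.  Three generators are
provided:

* :func:`generate_expression_cohort` — a genes × samples log2-scale expression
  matrix with planted subtype structure: each configured gene set is shifted up
  or down (in SD units) in the subtypes that activate or suppress it, on top of
  i.i.d. Gaussian background noise.
* :func:`generate_taxon_counts` — a taxa × samples read-count table drawn
  multinomially from Dirichlet-perturbed cohort propensities, with optional
  planted fold-enrichments and depth-depleted samples (emulating a tumor whose
  mucosa microbiota has been lost).
* :func:`generate_toy_protein_pair` — an ortholog-like protein pair where the
  second sequence carries known insertions and substitutions, together with the
  ground-truth residue correspondence.

All generators are deterministic: the same configuration and seed reproduce the
same output byte-for-byte after serialization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "SignatureSpec",
    "CohortConfig",
    "TruthLabels",
    "generate_expression_cohort",
    "generate_taxon_counts",
    "generate_toy_protein_pair",
]


@dataclass(frozen=True)
class SignatureSpec:
    """One planted gene set: its size, per-subtype direction and effect size.

    ``directions`` maps subtype name -> -1 / 0 / +1 (suppressed / irrelevant /
    activated); subtypes absent from the mapping default to 0.  ``effect`` is
    the mean shift in units of the background SD.
    """

    name: str
    n_genes: int
    directions: Mapping[str, int]
    effect: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        if self.n_genes < 1:
            raise ValueError(f"signature {self.name!r}: n_genes must be >= 1")
        if self.effect < 0:
            raise ValueError(f"signature {self.name!r}: effect size must be >= 0")
        for subtype, d in self.directions.items():
            if d not in (-1, 0, 1):
                raise ValueError(
                    f"signature {self.name!r}: direction for {subtype!r} must be in {{-1,0,1}}"
                )


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic expression cohort."""

    n_samples_per_subtype: Mapping[str, int]
    n_background_genes: int
    signature_spec: Sequence[SignatureSpec] = field(default_factory=tuple)
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples_per_subtype:
            raise ValueError("at least one subtype is required")
        for subtype, n in self.n_samples_per_subtype.items():
            if n < 1:
                raise ValueError(f"subtype {subtype!r} has zero samples configured")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        names = [s.name for s in self.signature_spec]
        if len(set(names)) != len(names):
            raise ValueError("signature set names must be unique")
        known = set(self.n_samples_per_subtype)
        for s in self.signature_spec:
            unknown = set(s.directions) - known
            if unknown:
                raise ValueError(
                    f"signature {s.name!r} references unknown subtypes: {sorted(unknown)}"
                )

    def digest(self) -> str:
        """Stable SHA-256 digest of the configuration (for provenance)."""
        payload = {
            "n_samples_per_subtype": dict(self.n_samples_per_subtype),
            "n_background_genes": self.n_background_genes,
            "signature_spec": [
                [s.name, s.n_genes, dict(s.directions), s.effect]
                for s in self.signature_spec
            ],
            "noise_sd": self.noise_sd,
            "baseline_mean": self.baseline_mean,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


@dataclass(frozen=True)
class TruthLabels:
    """Ground-truth per-sample labels plus generation provenance."""

    labels: Mapping[str, str]
    seed: int
    config_digest: str

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.labels), name="label")


def _signature_gene_names(spec: SignatureSpec) -> list[str]:
    width = max(3, len(str(spec.n_genes)))
    return [f"{spec.name}_{i + 1:0{width}d}" for i in range(spec.n_genes)]


def generate_expression_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, TruthLabels]:
    """Draw a genes × samples matrix with planted subtype structure.

    Background genes are N(baseline_mean, noise_sd²) in every subtype; each
    signature gene is additionally shifted by ``direction × effect × noise_sd``
    in the subtypes its set is directed in.  Values live on a log2(FPKM+1)-like
    scale.

    Returns the expression matrix (genes as rows, samples as columns) and the
    matching :class:`TruthLabels`.
    """
    rng = np.random.default_rng(config.seed)

    gene_names: list[str] = [
        f"BG{i + 1:05d}" for i in range(config.n_background_genes)
    ]
    for spec in config.signature_spec:
        gene_names.extend(_signature_gene_names(spec))
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("generated gene identifiers are not unique")

    sample_names: list[str] = []
    labels: dict[str, str] = {}
    for subtype, n in config.n_samples_per_subtype.items():
        for i in range(n):
            sid = f"{subtype}_{i + 1:03d}"
            sample_names.append(sid)
            labels[sid] = subtype

    n_genes = len(gene_names)
    n_samples = len(sample_names)
    values = rng.normal(
        loc=config.baseline_mean, scale=config.noise_sd, size=(n_genes, n_samples)
    )

    # add the planted shifts block by block
    row = config.n_background_genes
    col_of = {sid: j for j, sid in enumerate(sample_names)}
    for spec in config.signature_spec:
        rows = slice(row, row + spec.n_genes)
        for subtype, d in spec.directions.items():
            if d == 0:
                continue
            cols = [col_of[s] for s, lab in labels.items() if lab == subtype]
            values[rows, cols] += d * spec.effect * config.noise_sd
        row += spec.n_genes

    matrix = pd.DataFrame(values, index=gene_names, columns=sample_names)
    truth = TruthLabels(labels=labels, seed=config.seed, config_digest=config.digest())
    return matrix, truth


def signature_gene_sets(config: CohortConfig) -> dict[str, list[str]]:
    """Gene membership of each planted set (for building GMT fixtures)."""
    return {s.name: _signature_gene_names(s) for s in config.signature_spec}


def signature_collection(config: CohortConfig):
    """The planted gene sets of a cohort config as a SignatureCollection."""
    from .signatures import GeneSet, SignatureCollection

    coll = SignatureCollection()
    for name, genes in signature_gene_sets(config).items():
        coll.add(GeneSet(name=name, description="planted synthetic signature",
                         genes=tuple(g.upper() for g in genes)))
    return coll


def archetype_cohort_config(
    archetypes: "pd.DataFrame",
    n_per_subtype: int = 50,
    n_genes_per_set: int = 25,
    n_background_genes: int = 400,
    effect: float = 1.0,
    noise_sd: float = 1.0,
    baseline_mean: float = 5.0,
    seed: int = 0,
) -> CohortConfig:
    """Cohort config whose subtypes follow an archetype (±1/0) pattern matrix.

    Each signature column of ``archetypes`` becomes one planted gene set whose
    direction in every subtype is the archetype entry.  Defaults emulate a
    human-cohort-scale study: 50 tumors per subtype, 25 genes per signature
    (typical published CRC signature sizes are tens of genes), 400 direction-
    free background genes, a 1-SD activation effect on a baseline of
    5 log2(FPKM+1) units with unit noise.
    """
    specs = tuple(
        SignatureSpec(
            name=sig,
            n_genes=n_genes_per_set,
            directions={s: int(archetypes.loc[s, sig]) for s in archetypes.index},
            effect=effect,
        )
        for sig in archetypes.columns
    )
    return CohortConfig(
        n_samples_per_subtype={s: n_per_subtype for s in archetypes.index},
        n_background_genes=n_background_genes,
        signature_spec=specs,
        noise_sd=noise_sd,
        baseline_mean=baseline_mean,
        seed=seed,
    )


def canine_cohort_config(
    group_sizes: Mapping[str, int] | None = None,
    n_marker_genes: int = 40,
    n_background_genes: int = 400,
    effect: float = 2.5,
    noise_sd: float = 1.0,
    baseline_mean: float = 5.0,
    seed: int = 0,
) -> CohortConfig:
    """A 26-sample canine-like cohort with four planted expression groups.

    Group sizes default to the composition of a small surgical cohort — 12
    proliferative tumors, 8 invasive tumors, 4 normal-like samples and 2
    stromal tumors.  Each group carries a marker-gene program that is *high in
    the group and low everywhere else* (direction +1 at home, −1 abroad),
    emulating tissue-specific marker expression, which is on/off on the log
    scale: the 2.5-SD two-sided contrast gives a 5-SD between-group separation
    on marker genes, the regime in which histologically distinct groups live.
    """
    if group_sizes is None:
        group_sizes = {"proliferative": 12, "invasive": 8, "normal": 4, "stromal": 2}
    specs = tuple(
        SignatureSpec(
            name=f"{group}_markers",
            n_genes=n_marker_genes,
            directions={other: (1 if other == group else -1) for other in group_sizes},
            effect=effect,
        )
        for group in group_sizes
    )
    return CohortConfig(
        n_samples_per_subtype=dict(group_sizes),
        n_background_genes=n_background_genes,
        signature_spec=specs,
        noise_sd=noise_sd,
        baseline_mean=baseline_mean,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# taxon count tables
# ---------------------------------------------------------------------------

def generate_taxon_counts(
    n_taxa: int,
    n_samples: int,
    planted: Sequence[tuple[str, str, float]] = (),
    depleted_samples: Sequence[str] = (),
    depth: int = 5_000,
    seed: int = 0,
    *,
    base_alpha: float = 0.3,
    sample_concentration: float = 200.0,
    taxa_per_family: int = 5,
    families_per_phylum: int = 4,
) -> tuple[pd.DataFrame, TruthLabels]:
    """Draw a taxa × samples read-count table with planted structure.

    Cohort-level taxon propensities are drawn once from a symmetric
    Dirichlet(``base_alpha``) — small alpha gives the skewed, heavy-tailed
    abundance profile typical of shotgun metagenomics.  Each sample perturbs
    them with a Dirichlet re-draw at concentration ``sample_concentration``,
    then ``planted`` (taxon, sample, fold) cells multiply that sample's
    propensity by ``fold`` before renormalisation.  Counts are multinomial at
    ``depth`` reads per sample; samples listed in ``depleted_samples`` receive
    ``depth // 10`` reads, a ≥10× depletion emulating a tumor stripped of its
    mucosa microbiota.

    Returns a DataFrame with columns ``phylum, family, species`` followed by
    one count column per sample (index = taxon id), and TruthLabels marking
    each sample ``depleted`` or ``typical``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if n_taxa < 1 or n_samples < 1:
        raise ValueError("n_taxa and n_samples must be >= 1")

    rng = np.random.default_rng(seed)
    taxa = [f"TAX{i + 1:04d}" for i in range(n_taxa)]
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    taxon_pos = {t: i for i, t in enumerate(taxa)}
    sample_pos = {s: j for j, s in enumerate(samples)}

    for taxon, sample, fold in planted:
        if taxon not in taxon_pos or sample not in sample_pos:
            raise ValueError(f"planted cell ({taxon!r}, {sample!r}) not in table")
        if fold <= 0:
            raise ValueError("planted fold must be > 0")
    unknown_depleted = set(depleted_samples) - set(samples)
    if unknown_depleted:
        raise ValueError(f"depleted samples not in table: {sorted(unknown_depleted)}")

    lineage = pd.DataFrame(
        {
            "phylum": [
                f"P{(i // (taxa_per_family * families_per_phylum)) + 1:02d}"
                for i in range(n_taxa)
            ],
            "family": [f"F{(i // taxa_per_family) + 1:03d}" for i in range(n_taxa)],
            "species": [f"sp_{t}" for t in taxa],
        },
        index=pd.Index(taxa, name="taxon"),
    )

    base = rng.dirichlet(np.full(n_taxa, base_alpha))
    base = np.maximum(base, 1e-12)

    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    depleted = set(depleted_samples)
    for j, sample in enumerate(samples):
        props = rng.dirichlet(base * sample_concentration)
        for taxon, target, fold in planted:
            if target == sample:
                props = props.copy()
                props[taxon_pos[taxon]] *= fold
                props = props / props.sum()
        n_reads = depth // 10 if sample in depleted else depth
        counts[:, j] = rng.multinomial(n_reads, props)

    table = pd.concat(
        [lineage, pd.DataFrame(counts, index=lineage.index, columns=samples)], axis=1
    )
    labels = {s: ("depleted" if s in depleted else "typical") for s in samples}
    digest = hashlib.sha256(
        json.dumps(
            [n_taxa, n_samples, sorted(map(list, planted)), sorted(depleted), depth, seed],
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()
    truth = TruthLabels(labels=labels, seed=seed, config_digest=digest)
    return table, truth


# ---------------------------------------------------------------------------
# toy ortholog protein pairs
# ---------------------------------------------------------------------------

def generate_toy_protein_pair(
    length: int,
    insertions: Sequence[tuple[int, int]] = (),
    n_substitutions: int = 0,
    seed: int = 0,
) -> tuple[str, str, dict[int, int]]:
    """Build an ortholog-like pair (A, B) with a known residue correspondence.

    B equals A with each ``(position, length)`` insertion applied — the
    inserted segment is placed *before* A's 1-based ``position`` (position 1 is
    the N-terminus, position ``length + 1`` appends at the C-terminus) — and
    ``n_substitutions`` random point substitutions.  The returned truth map
    sends each 1-based A position to its 1-based B position.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if n_substitutions >= length:
        raise ValueError("substitution count must be < sequence length")
    positions = [p for p, _ in insertions]
    if len(set(positions)) != len(positions):
        raise ValueError("overlapping insertions (duplicate positions)")
    for pos, ins_len in insertions:
        if not 1 <= pos <= length + 1:
            raise ValueError(f"insertion position {pos} outside sequence bounds")
        if ins_len < 1:
            raise ValueError("insertion length must be >= 1")

    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    seq_a = "".join(rng.choice(aas, size=length))

    # offsets accumulate over insertions sorted by position
    b_chars = list(seq_a)
    truth = {p: p for p in range(1, length + 1)}
    for pos, ins_len in sorted(insertions, key=lambda t: t[0], reverse=True):
        segment = "".join(rng.choice(aas, size=ins_len))
        b_chars[pos - 1 : pos - 1] = list(segment)
    offset = 0
    ins_sorted = sorted(insertions)
    for p in range(1, length + 1):
        while ins_sorted and ins_sorted[0][0] <= p:
            offset += ins_sorted.pop(0)[1]
        truth[p] = p + offset

    if n_substitutions:
        sub_positions = rng.choice(length, size=n_substitutions, replace=False)
        for p in sub_positions:
            b_idx = truth[int(p) + 1] - 1
            current = b_chars[b_idx]
            choices = [a for a in AMINO_ACIDS if a != current]
            b_chars[b_idx] = str(rng.choice(choices))

    return seq_a, "".join(b_chars), truth
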
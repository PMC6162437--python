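"""Cross-species mutation interpretation.

Three capabilities, all coordinate-1-based at the protein/CDS level:

* **Residue mapping between ortholog proteins.**  A global (Needleman-Wunsch,
  affine-gap) alignment of two protein sequences yields a monotone residue
  correspondence, so a mutation observed at position p in species A can be
  read out at its equivalent position in species B.  This is how, e.g., canine
  TP53 hotspot mutations are recognised as the classic human DNA-binding-domain
  hotspots despite a 13-residue N-terminal offset between the orthologs.
* **Phosphodegron flagging for β-catenin.**  The N-terminal destruction motif
  D(32)pS(33)G(34)·φ·X·pS(37) plus the T41/S45 priming cascade is the docking
  site of the β-TrCP1 E3 ligase; missense changes at these residues block
  phosphorylation or ligase binding and stabilise β-catenin.  A mutation is
  flagged by position against a :class:`DegronSpec`; note the flag depends on
  position only, not on the alternate residue (a documented limitation).
* **Premature stop codons from intron retention.**  Scanning a CDS that
  retains an intron, in a given reading frame, reports every in-frame stop
  codon (TAA/TAG/TGA) and the length of the protein that would be translated
  before the first one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")
STOP_CODONS = {"TAA", "TAG", "TGA"}
GAPPED = "gapped"

__all__ = [
    "MutationRecord",
    "DegronSpec",
    "CTNNB1_DEGRON",
    "ProteinAlignment",
    "align_proteins",
    "map_residue",
    "flag_degron_mutation",
    "detect_premature_stops",
]


@dataclass(frozen=True)
class MutationRecord:
    """A missense mutation: gene, 1-based protein position, ref and alt residue."""

    gene: str
    position: int
    ref: str
    alt: str
    species: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("protein position must be >= 1")
        for residue in (self.ref, self.alt):
            if residue not in VALID_AA:
                raise ValueError(f"invalid amino-acid letter {residue!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt residues must differ")

    @classmethod
    def parse(cls, notation: str, gene: str, species: str = "") -> "MutationRecord":
        """Parse compact notation like ``S45F`` or ``D32Y``."""
        m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", notation.strip())
        if not m:
            raise ValueError(f"cannot parse mutation notation {notation!r}")
        return cls(gene=gene, position=int(m.group(2)), ref=m.group(1), alt=m.group(3),
                   species=species)


@dataclass(frozen=True)
class DegronSpec:
    """Critical residues of a degradation motif, with their roles."""

    gene: str
    motif: str
    critical: tuple[tuple[int, str], ...]  # (1-based position, role)

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.critical]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("critical positions must be strictly increasing")
        for _, role in self.critical:
            if role not in ("phospho-acceptor", "motif-structural", "priming-phospho"):
                raise ValueError(f"unknown degron role {role!r}")

    @property
    def span(self) -> tuple[int, int]:
        positions = [p for p, _ in self.critical]
        return min(positions), max(positions)


#: β-catenin destruction motif: the DpSGφXpS box (D32-S33-G34...S37) recognised
#: by β-TrCP1, plus the GSK3/CK1 cascade sites T41 and the S45 priming site.
CTNNB1_DEGRON = DegronSpec(
    gene="CTNNB1",
    motif="DpSGphiXpS destruction motif, peptide D32-S47 (DSGIHSGATTTAPSLS)",
    critical=(
        (32, "motif-structural"),
        (33, "phospho-acceptor"),
        (34, "motif-structural"),
        (37, "phospho-acceptor"),
        (41, "phospho-acceptor"),
        (45, "priming-phospho"),
    ),
)


@dataclass
class ProteinAlignment:
    """A global pairwise alignment plus its residue correspondence map."""

    aligned_a: str
    aligned_b: str
    score: float
    parameters: dict = field(default_factory=dict)
    a_to_b: dict[int, int] = field(default_factory=dict)  # 1-based, non-gapped only

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")
        seq_a = self.aligned_a.replace("-", "")
        seq_b = self.aligned_b.replace("-", "")
        if not self.a_to_b:
            pa = pb = 0
            for ca, cb in zip(self.aligned_a, self.aligned_b):
                if ca != "-":
                    pa += 1
                if cb != "-":
                    pb += 1
                if ca != "-" and cb != "-":
                    self.a_to_b[pa] = pb
        self.length_a = len(seq_a)
        self.length_b = len(seq_b)


def _check_protein(seq: str, label: str) -> str:
    seq = str(seq).strip().upper()
    if not seq:
        raise ValueError(f"sequence {label} is empty")
    for i, ch in enumerate(seq, start=1):
        if ch not in VALID_AA:
            raise ValueError(f"sequence {label}: invalid character {ch!r} at position {i}")
    return seq


def align_proteins(
    seq_a: str,
    seq_b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> ProteinAlignment:
    """Optimal global alignment of two protein sequences (affine gap penalty).

    Defaults are the standard protein choices (BLOSUM62, open 10, extend 0.5).
    The traceback is deterministic: the aligner's first-reported optimal
    alignment is used.
    """
    seq_a = _check_protein(seq_a, "A")
    seq_b = _check_protein(seq_b, "B")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    return ProteinAlignment(
        aligned_a=str(alignment[0]),
        aligned_b=str(alignment[1]),
        score=float(alignment.score),
        parameters={
            "substitution_matrix": substitution_matrix,
            "gap_open": gap_open,
            "gap_extend": gap_extend,
        },
    )


def map_residue(alignment: ProteinAlignment, position_in_a: int) -> int | str:
    """The aligned partner (1-based) in B of A's ``position_in_a``, or ``"gapped"``."""
    if not 1 <= position_in_a <= alignment.length_a:
        raise ValueError(
            f"position {position_in_a} outside A (length {alignment.length_a})"
        )
    return alignment.a_to_b.get(position_in_a, GAPPED)


@dataclass(frozen=True)
class DegronFlag:
    status: str  # "degron" | "motif-adjacent" | "outside"
    role: str | None = None

    @property
    def disrupting(self) -> bool:
        return self.status == "degron"


def flag_degron_mutation(mutation: MutationRecord, spec: DegronSpec = CTNNB1_DEGRON) -> DegronFlag:
    """Classify a mutation against a degron: critical, motif-adjacent or outside.

    The call is positional: a mutation at a critical residue is flagged with
    that residue's role, one inside the motif span but non-critical is
    ``motif-adjacent``, anything else is ``outside``.
    """
    if mutation.gene != spec.gene:
        raise ValueError(f"mutation gene {mutation.gene!r} does not match spec {spec.gene!r}")
    roles = dict(spec.critical)
    if mutation.position in roles:
        return DegronFlag(status="degron", role=roles[mutation.position])
    lo, hi = spec.span
    if lo <= mutation.position <= hi:
        return DegronFlag(status="motif-adjacent")
    return DegronFlag(status="outside")


def detect_premature_stops(
    sequence: str,
    reading_frame_offset: int = 0,
    canonical_stop: int | None = None,
) -> tuple[list[int], int]:
    """In-frame stop codons of a CDS (e.g. one retaining an intron).

    Scans non-overlapping codons starting at ``reading_frame_offset`` (0-2)
    and returns the 1-based nucleotide positions of every TAA/TAG/TGA codon
    start, plus the truncated protein length (codons preceding the first
    stop).  With ``canonical_stop`` (1-based nucleotide position of the
    annotated stop codon) only stops strictly before it are reported.
    """
    seq = str(sequence).strip().upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in "ACGT":
            raise ValueError(f"invalid nucleotide {ch!r} at position {i}")
    if reading_frame_offset not in (0, 1, 2):
        raise ValueError("reading frame offset must be 0, 1 or 2")

    stops: list[int] = []
    for start in range(reading_frame_offset, len(seq) - 2, 3):
        codon = seq[start : start + 3]
        if codon in STOP_CODONS:
            pos = start + 1
            if canonical_stop is not None and pos >= canonical_stop:
                continue
            stops.append(pos)
    if stops:
        truncation = (stops[0] - 1 - reading_frame_offset) // 3
    else:
        truncation = (len(seq) - reading_frame_offset) // 3
    return stops, truncation


def map_mutations(
    alignment: ProteinAlignment, mutations: Sequence[MutationRecord]
) -> list[dict]:
    """Map a batch of A-coordinate mutations through an alignment."""
    out = []
    for m in mutations:
        out.append(
            {
                "gene": m.gene,
                "position_a": m.position,
                "ref": m.ref,
                "alt": m.alt,
                "position_b": map_residue(alignment, m.position),
            }
        )
    return out
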
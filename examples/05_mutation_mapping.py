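"""Cross-species mutation interpretation.

Three mini-workflows: (1) map residue positions between two ortholog-like
proteins that differ by a 13-residue N-terminal insertion — the TP53-style
offset under which dog position 162 equals human position 175; (2) flag
β-catenin missense mutations against the destruction-motif spec; (3) find
premature stop codons introduced by a retained intron.
"""

from crcinvasion import (
    CTNNB1_DEGRON,
    MutationRecord,
    align_proteins,
    detect_premature_stops,
    flag_degron_mutation,
    generate_toy_protein_pair,
    map_residue,
)

# 1. ortholog residue mapping across an N-terminal insertion
dog_like, human_like, _ = generate_toy_protein_pair(
    350, insertions=[(1, 13)], n_substitutions=10, seed=5
)
aln = align_proteins(dog_like, human_like)
for pos in (162, 261):
    print(f"position {pos} in sequence A maps to {map_residue(aln, pos)} in B "
          f"(+13 N-terminal offset)")
print("with real TP53 FASTA inputs the same call translates hotspot "
      "coordinates between species")

# 2. beta-catenin degron flags: the recurrent canine hotspots vs the benign
#    dog/human difference T60S
for notation in ("S45P", "S45F", "G34E", "D32Y", "T60S"):
    mut = MutationRecord.parse(notation, "CTNNB1")
    flag = flag_degron_mutation(mut, CTNNB1_DEGRON)
    verdict = f"degron-disrupting ({flag.role})" if flag.disrupting else flag.status
    print(f"CTNNB1 {notation}: {verdict}")

# 3. premature stops from intron retention: two in-frame stops appear before
#    the canonical end of the coding sequence
cds_with_intron = "ATGGCCGCC" + "TAAGGGTAG" + "ACCGGA"
stops, truncation = detect_premature_stops(cds_with_intron, reading_frame_offset=0)
print(f"\nretained intron introduces {len(stops)} premature stop codon(s) at "
      f"nucleotide position(s) {stops}; translation truncates after "
      f"{truncation} residues")
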
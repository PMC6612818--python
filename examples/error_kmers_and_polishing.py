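"""How the error-k-mer catalogue flags a recurrent error in a singleton.

Builds two hand-made PCR families that both contain the same recurrent
G>T artifact in a minority of duplicates, learns the error-k-mer set from
their consensus calls, and polishes a singleton read carrying the same
artifact: the erroneous base is pinned exactly and its quality floored to
5, without touching the sequence.
"""

from pec.bam_io import ReadPairRecord
from pec.consensus import build_consensus
from pec.grouping import group_pairs
from pec.kmers import flag_family_kmers, merge_error_kmers
from pec.polishing import polish_read

K = 7
TRUE = "ACGTTGCAAGGCTTAACCGGATCGATCC"  # 28 bp true fragment sequence
ERR_POS, ERR_BASE = 14, "T"  # recurrent A>T artifact at position 14
MUTATED = TRUE[:ERR_POS] + ERR_BASE + TRUE[ERR_POS + 1 :]


def pair(name, seq, pos):
    return ReadPairRecord(
        pair_name=name, chrom="demo", mate1_seq=seq, mate2_seq=TRUE,
        mate1_quals=[35] * len(seq), mate2_quals=[35] * len(TRUE),
        mate1_cigar=f"{len(seq)}M", mate2_cigar=f"{len(TRUE)}M",
        mate1_pos=pos, mate2_pos=pos + 100,
        mate1_reverse=False, mate2_reverse=True,
    )


tables = []
for fam_idx, pos in enumerate((1000, 2000)):
    members = [pair(f"fam{fam_idx}:d{i}", TRUE, pos) for i in range(4)]
    members.append(pair(f"fam{fam_idx}:d4", MUTATED, pos))  # 1 of 5 carries it
    (family,) = group_pairs(members)
    cons = build_consensus(family)
    print(f"family {fam_idx}: consensus == truth: {cons.mate_seq(1) == TRUE}; "
          f"corrected {len([c for c in cons.corrected_positions if c.mate == 1])} "
          f"member base(s)")
    tables.append(flag_family_kmers(family, cons, k=K))

error_set = merge_error_kmers(tables)
print(f"error k-mer catalogue: {len(error_set)} k-mers "
      f"(windows of the artifact never seen in any consensus)\n")

singleton = pair("lonely:d0", MUTATED, 5000)
polished = polish_read(singleton, error_set)
print(f"singleton carries the artifact at position {ERR_POS}")
print(f"flagged positions: {polished.tags.get('pb1')}")
print(f"quality at {ERR_POS}: {singleton.mate1_quals[ERR_POS]} -> "
      f"{polished.mate1_quals[ERR_POS]}")
print(f"sequence unchanged: {polished.mate1_seq == singleton.mate1_seq}")
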
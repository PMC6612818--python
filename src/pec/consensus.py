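"""Per-family consensus calling (the de-duplication error-correction stage).

All read pairs in a high-depth family are assumed to be PCR copies of one
original fragment, so at every read position the most common allele among
them is taken as the true base and minority alleles as PCR errors.  Bases
the sequencer itself already distrusts (Phred below ``min_base_qual``,
default 20) neither vote nor count as PCR errors — they are left for
downstream tools to handle through their quality scores.

Because family members share unclipped 5' coordinates and (by the majority
rule below) read length, a positional majority vote is equivalent to
assembling the family and reading off the consensus path; voting keeps
every column exactly checkable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

from .bam_io import parse_cigar
from .grouping import DuplicateSet

__all__ = ["ConsensusRead", "CorrectedBase", "build_consensus", "ConsensusUndefined"]


class ConsensusUndefined(ValueError):
    """Raised when no consensus can be built (caller should fall back to
    representative selection)."""


class CorrectedBase(NamedTuple):
    """One member base identified as a PCR error and corrected."""

    member: str  # pair_name of the member carrying the error
    mate: int
    column: int  # 0-based read position
    from_base: str  # erroneous base observed in the member
    to_base: str  # consensus base


@dataclass
class ConsensusRead:
    """Consensus sequence/qualities for one family, per mate."""

    mate1_seq: str
    mate2_seq: str
    mate1_quals: list[int]
    mate2_quals: list[int]
    # per mate: list over columns of {base: eligible-voter count}
    column_counts: dict[int, list[dict[str, int]]]
    corrected_positions: list[CorrectedBase]
    voters: dict[int, list[str]] = field(default_factory=dict)  # mate -> pair_names
    excluded: dict[int, list[str]] = field(default_factory=dict)

    def mate_seq(self, mate: int) -> str:
        return self.mate1_seq if mate == 1 else self.mate2_seq

    def mate_quals(self, mate: int) -> list[int]:
        return self.mate1_quals if mate == 1 else self.mate2_quals


def _indel_signature(cigar: str) -> tuple:
    """CIGAR reduced to its indel structure (op, length, read-offset runs).

    Members whose signature matches the family's modal signature align
    column-for-column in read coordinates and may vote; others (indels the
    rest of the family lacks) are excluded — consensus does not attempt
    indel-aware multi-alignment.
    """
    sig = []
    read_off = 0
    for op, n in parse_cigar(cigar):
        if op in "ID":
            sig.append((op, n, read_off))
        if op in "MIS=X":
            read_off += n
    return tuple(sig)


def _modal(values: list) -> tuple[object, bool]:
    """(mode, unique?) of a list; ties are reported as non-unique."""
    counts = Counter(values).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return counts[0][0], False
    return counts[0][0], True


def _call_column(
    bases: list[str], quals: list[int], min_base_qual: int
) -> tuple[str, int, dict[str, int]]:
    """Call one column: (consensus base, consensus qual, eligible counts).

    Eligible voters are non-N bases with Phred >= min_base_qual.  Ties go
    to the allele with the greater summed Phred among its supporters, then
    to the lexicographically smallest base.  Columns with no eligible voter
    fall back to a plain majority over all bases, with the same tie-break.
    """
    eligible = [
        (b, q) for b, q in zip(bases, quals) if b != "N" and q >= min_base_qual
    ]
    pool = eligible if eligible else [(b, q) for b, q in zip(bases, quals) if b != "N"]
    if not pool:  # every member has N here
        return "N", 0, {}
    counts: Counter = Counter(b for b, _ in pool)
    phred_sum: dict[str, int] = {}
    phred_max: dict[str, int] = {}
    for b, q in pool:
        phred_sum[b] = phred_sum.get(b, 0) + q
        phred_max[b] = max(phred_max.get(b, 0), q)
    winner = min(counts, key=lambda b: (-counts[b], -phred_sum[b], b))
    qual = min(phred_max[winner], 93)
    return winner, qual, (dict(counts) if eligible else {})


def build_consensus(family: DuplicateSet, min_base_qual: int = 20) -> ConsensusRead:
    """Build the quality-aware majority consensus for a high-depth family.

    Raises :class:`ConsensusUndefined` when the family has no majority read
    length for a mate (the caller should route it to the representative
    path instead).  Members whose length or indel structure differs from
    the family mode are excluded from voting and listed in ``excluded``.
    """
    if family.duplicate_depth < 2:
        raise ConsensusUndefined(
            f"family {family.key} has depth {family.duplicate_depth}; "
            "consensus requires at least 2 members"
        )
    seqs: dict[int, str] = {}
    quals: dict[int, list[int]] = {}
    col_counts: dict[int, list[dict[str, int]]] = {}
    corrected: list[CorrectedBase] = []
    voters: dict[int, list[str]] = {}
    excluded: dict[int, list[str]] = {}

    for mate in (1, 2):
        lengths = [len(m.mate_seq(mate)) for m in family.members]
        mode_len, unique = _modal(lengths)
        if not unique:
            raise ConsensusUndefined(
                f"family {family.key}: no majority mate{mate} read length"
            )
        len_ok = [m for m in family.members if len(m.mate_seq(mate)) == mode_len]
        sigs = [_indel_signature(m.mate_cigar(mate)) for m in len_ok]
        mode_sig, _ = _modal(sigs)
        mate_voters = [m for m, s in zip(len_ok, sigs) if s == mode_sig]
        if len(mate_voters) < 2:
            raise ConsensusUndefined(
                f"family {family.key}: fewer than 2 alignable mate{mate} members"
            )
        voters[mate] = [m.pair_name for m in mate_voters]
        excluded[mate] = [
            m.pair_name for m in family.members if m.pair_name not in set(voters[mate])
        ]

        cons_seq: list[str] = []
        cons_qual: list[int] = []
        counts_per_col: list[dict[str, int]] = []
        for col in range(mode_len):
            bases = [m.mate_seq(mate)[col] for m in mate_voters]
            bquals = [m.mate_quals(mate)[col] for m in mate_voters]
            base, q, counts = _call_column(bases, bquals, min_base_qual)
            cons_seq.append(base)
            cons_qual.append(q)
            counts_per_col.append(counts)
            for m, b, bq in zip(mate_voters, bases, bquals):
                if b != base and b != "N" and bq >= min_base_qual:
                    corrected.append(
                        CorrectedBase(m.pair_name, mate, col, from_base=b, to_base=base)
                    )
        seqs[mate] = "".join(cons_seq)
        quals[mate] = cons_qual
        col_counts[mate] = counts_per_col

    return ConsensusRead(
        mate1_seq=seqs[1],
        mate2_seq=seqs[2],
        mate1_quals=quals[1],
        mate2_quals=quals[2],
        column_counts=col_counts,
        corrected_positions=corrected,
        voters=voters,
        excluded=excluded,
    )


def assign_consensus_quals(
    consensus_seq: str,
    voter_seqs: list[str],
    voter_quals: list[list[int]],
    min_base_qual: int = 20,
) -> list[int]:
    """Consensus base qualities: max Phred among eligible members agreeing
    with the consensus base at each column (capped at 93); columns with no
    eligible supporter take the best available supporter's quality."""
    out = []
    for col, base in enumerate(consensus_seq):
        agreeing = [
            q[col]
            for s, q in zip(voter_seqs, voter_quals)
            if s[col] == base and q[col] >= min_base_qual
        ]
        if not agreeing:
            agreeing = [q[col] for s, q in zip(voter_seqs, voter_quals) if s[col] == base]
        out.append(min(max(agreeing, default=0), 93))
    return out


def substitution_spectrum(corrected: list[CorrectedBase]) -> dict[str, int]:
    """Counts of corrected PCR errors by substitution type (true>observed)."""
    spec: Counter = Counter(f"{c.to_base}>{c.from_base}" for c in corrected)
    return dict(sorted(spec.items()))
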
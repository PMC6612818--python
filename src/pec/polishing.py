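"""Intrinsic polishing of low-depth families.

Families below the consensus depth threshold cannot be corrected by
majority vote.  For these, the read pair with the highest overall base
quality is kept as the representative molecule, and bases that look like
*systematic* errors — positions whose surrounding k-mers all appear in the
globally learnt error-k-mer catalogue — are flagged by dropping their Phred
score to a floor (default 5).  The base itself is never changed; callers
downstream simply ignore low-quality evidence, so a wrong flag costs one
read's evidence at one base rather than fabricating a new allele.

Localization: scanning a read against the error set yields maximal runs of
consecutive error k-mers; the error base must lie in every window of the
run, i.e. in the intersection of their spans.  An interior error covered by
a full run of k error k-mers is pinned to exactly one base; errors within
k-1 of a read end leave a wider (multi-base) intersection, which is flagged
conservatively in full.
"""

from __future__ import annotations

import logging
from dataclasses import replace

from .bam_io import ReadPairRecord
from .grouping import DuplicateSet
from .kmers import ErrorKmerSet

logger = logging.getLogger(__name__)

__all__ = ["select_representative", "polish_read", "flag_positions"]

DEFAULT_FLAG_QUAL = 5


def select_representative(family: DuplicateSet) -> ReadPairRecord:
    """The member with the highest summed Phred over both mates.

    Ties go to the lexicographically smallest pair name, keeping the choice
    deterministic.
    """
    return min(family.members, key=lambda m: (-m.qual_sum(), m.pair_name))


def flag_positions(seq: str, error_set: ErrorKmerSet) -> list[int]:
    """Read positions implicated by the error-k-mer catalogue.

    For each maximal run of consecutive window starts ``a..b`` whose k-mers
    are all in ``error_set``, the implicated positions are the intersection
    of the windows' spans: ``[b, a+k-1]``.  Runs longer than k windows have
    an empty intersection (no single base explains them) and flag nothing.
    """
    k = error_set.k
    if len(seq) < k:
        return []
    hits = [i for i in range(len(seq) - k + 1) if seq[i : i + k] in error_set.kmers]
    runs: list[list[int]] = []
    for i in hits:
        if runs and i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    flagged: list[int] = []
    for a, b in runs:
        if b <= a + k - 1:  # nonempty span intersection
            flagged.extend(range(b, a + k))
    return flagged


def polish_read(
    pair: ReadPairRecord,
    error_set: ErrorKmerSet,
    k: int | None = None,
    flag_qual: int = DEFAULT_FLAG_QUAL,
) -> ReadPairRecord:
    """Return a copy of ``pair`` with implicated bases' qualities floored.

    Sequences are never modified.  Qualities already below ``flag_qual``
    are left alone.  Reads shorter than k are returned unchanged with a
    warning.  The flagged positions are recorded in the record's tags
    (``pb1``/``pb2``) for provenance.
    """
    if k is not None and k != error_set.k:
        raise ValueError(f"k={k} does not match error set k={error_set.k}")
    k = error_set.k
    new = replace(pair, tags=dict(pair.tags))
    for mate in (1, 2):
        seq = pair.mate_seq(mate)
        if len(seq) < k:
            logger.warning(
                "read %s mate%d length %d < k=%d; not polished",
                pair.pair_name, mate, len(seq), k,
            )
            continue
        positions = flag_positions(seq, error_set)
        if not positions:
            continue
        quals = list(pair.mate_quals(mate))
        hit = []
        for p in positions:
            if quals[p] >= flag_qual:
                quals[p] = flag_qual
            hit.append(p)
        if mate == 1:
            new.mate1_quals = quals
        else:
            new.mate2_quals = quals
        new.tags[f"pb{mate}"] = hit
    return new
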
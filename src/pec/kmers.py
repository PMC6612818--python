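"""Trusted/untrusted k-mer bookkeeping and the global error-k-mer catalogue.

Within each high-depth family, k-mers of the consensus are *trusted*; k-mers
of member reads that span a corrected PCR-error base are *untrusted*.
Merging across families, k-mers that were untrusted somewhere but never
trusted anywhere form the *error* set — the recurrent (systematic) error
patterns the data itself exposes.  That catalogue is what intrinsic
polishing applies to low-depth reads.

Reads are stored in reference-forward orientation throughout (SAM SEQ
convention), so k-mers are compared in a single fixed orientation with no
reverse-complement canonicalization: families are coordinate-defined, and
one convention keeps trusted/untrusted comparisons exact.  The store is an
exact hash set, sized for targeted panels; a probabilistic backend would be
a drop-in extension.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .consensus import ConsensusRead
from .grouping import DuplicateSet

logger = logging.getLogger(__name__)

__all__ = ["KmerFlagTable", "ErrorKmerSet", "flag_family_kmers", "merge_error_kmers"]

DEFAULT_K = 21  # odd, standard in k-mer error-correction practice


@dataclass
class KmerFlagTable:
    """Per-family trusted/untrusted k-mer flags."""

    k: int
    trusted: set[str] = field(default_factory=set)
    untrusted: set[str] = field(default_factory=set)


@dataclass
class ErrorKmerSet:
    """k-mers untrusted in some family and trusted in none."""

    k: int
    kmers: set[str] = field(default_factory=set)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)

    def dump(self, path: str) -> None:
        with open(path, "w") as fh:
            for kmer in sorted(self.kmers):
                fh.write(kmer + "\n")

    @classmethod
    def load(cls, path: str, k: int | None = None) -> "ErrorKmerSet":
        kmers = set()
        with open(path) as fh:
            for line in fh:
                kmer = line.strip()
                if kmer:
                    kmers.add(kmer)
        if kmers:
            lengths = {len(km) for km in kmers}
            if len(lengths) > 1:
                raise ValueError(f"mixed k-mer lengths in {path}: {sorted(lengths)}")
            file_k = lengths.pop()
            if k is not None and k != file_k:
                raise ValueError(f"expected k={k}, file has k={file_k}")
            k = file_k
        if k is None:
            raise ValueError("k must be given when loading an empty set")
        return cls(k=k, kmers=kmers)


def _clean_kmers(seq: str, k: int) -> Iterable[tuple[int, str]]:
    """(start, kmer) for every A/C/G/T-only k-mer window of seq."""
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            yield i, kmer


def flag_family_kmers(
    family: DuplicateSet,
    consensus: ConsensusRead,
    k: int = DEFAULT_K,
    min_base_qual: int = 20,
) -> KmerFlagTable:
    """Flag one family's k-mers against its consensus.

    Every consensus k-mer is trusted.  Every member k-mer window spanning
    at least one corrected (PCR-error) base is untrusted.  Mismatches the
    low-quality exemption already discarded (Phred < ``min_base_qual``)
    produced no corrected positions, so their k-mers are neither trusted
    nor untrusted.  Windows containing N are skipped.  If k exceeds a
    mate's read length that mate contributes nothing (warned).
    """
    table = KmerFlagTable(k=k)
    # corrected positions per (member, mate)
    err_cols: dict[tuple[str, int], list[int]] = defaultdict(list)
    for c in consensus.corrected_positions:
        err_cols[(c.member, c.mate)].append(c.column)

    members_by_name = {m.pair_name: m for m in family.members}
    for mate in (1, 2):
        cons_seq = consensus.mate_seq(mate)
        if len(cons_seq) < k:
            logger.warning(
                "k=%d exceeds mate%d consensus length %d for family %s; skipped",
                k, mate, len(cons_seq), family.key,
            )
            continue
        for _, kmer in _clean_kmers(cons_seq, k):
            table.trusted.add(kmer)
        for name in consensus.voters.get(mate, []):
            cols = err_cols.get((name, mate))
            if not cols:
                continue
            seq = members_by_name[name].mate_seq(mate)
            for col in cols:
                lo = max(0, col - k + 1)
                hi = min(col, len(seq) - k)
                for i in range(lo, hi + 1):
                    kmer = seq[i : i + k]
                    if "N" not in kmer:
                        table.untrusted.add(kmer)
    return table


def merge_error_kmers(tables: Iterable[KmerFlagTable]) -> ErrorKmerSet:
    """Union of untrusted k-mers minus every k-mer any family trusted."""
    tables = list(tables)
    if not tables:
        return ErrorKmerSet(k=DEFAULT_K)
    ks = {t.k for t in tables}
    if len(ks) > 1:
        raise ValueError(f"tables have mixed k: {sorted(ks)}")
    k = ks.pop()
    all_trusted: set[str] = set()
    all_untrusted: set[str] = set()
    for t in tables:
        all_trusted |= t.trusted
        all_untrusted |= t.untrusted
    err = ErrorKmerSet(k=k, kmers=all_untrusted - all_trusted)
    assert not (err.kmers & all_trusted)
    return err
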
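"""BAM input/output for paired-end cfDNA reads.

Reads aligned read pairs into :class:`ReadPairRecord` domain objects and
writes corrected pairs back, preserving the input header.  Coordinates are
0-based half-open internally; pysam handles the SAM text conversion.

Duplicate grouping keys on *unclipped* 5' ends (soft-clips arithmetically
removed, as MarkDuplicates does) because clipping varies among true PCR
duplicates of one fragment.
"""

from __future__ import annotations

import logging
import os
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import pysam

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# SAM auxiliary tags written on corrected records (lowercase = local use):
#   dd:i  duplicate depth of the family the record represents
#   pb:Z  comma-separated 0-based read positions whose quality was set to
#         the polishing floor by intrinsic polishing
TAG_DUP_DEPTH = "dd"
TAG_POLISHED = "pb"


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """CIGAR string -> list of (op, length)."""
    if not cigar or cigar == "*":
        return []
    ops = _CIGAR_RE.findall(cigar)
    if sum(int(n) for n, _ in ops) == 0 or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return [(op, int(n)) for n, op in ops]


def cigar_reference_length(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR."""
    return sum(n for op, n in parse_cigar(cigar) if op in "MDN=X")


def leading_softclip(cigar: str) -> int:
    ops = parse_cigar(cigar)
    return ops[0][1] if ops and ops[0][0] == "S" else 0


def trailing_softclip(cigar: str) -> int:
    ops = parse_cigar(cigar)
    return ops[-1][1] if ops and ops[-1][0] == "S" else 0


def unclipped_start(pos: int, cigar: str) -> int:
    """Unclipped 5' coordinate of a forward-strand alignment."""
    return pos - leading_softclip(cigar)


def unclipped_end(pos: int, cigar: str) -> int:
    """Unclipped 5' coordinate (0-based, inclusive) of a reverse-strand alignment."""
    return pos + cigar_reference_length(cigar) + trailing_softclip(cigar) - 1


class DuplicateKey(NamedTuple):
    """Grouping key: chromosome, the two unclipped 5' ends, orientation class.

    ``fwd5`` is the unclipped 5' end of the forward-oriented mate and
    ``rev5`` that of the reverse-oriented mate (for FF/RR anomalies, the two
    5' ends in ascending order).  Reads from opposite fragment strands have
    different orientation classes and are never merged.
    """

    chrom: str
    fwd5: int
    rev5: int
    orientation: str  # FR, RF, FF, RR


@dataclass
class ReadPairRecord:
    """One aligned read pair; the unit of duplicate grouping.

    Mates are canonicalized so that mate1 is the forward-oriented mate of an
    FR/RF pair (the leftmost mate for FF/RR).  Sequences are stored in
    reference-forward orientation, exactly as SAM stores them.
    """

    pair_name: str
    chrom: str
    mate1_seq: str
    mate2_seq: str
    mate1_quals: list[int]
    mate2_quals: list[int]
    mate1_cigar: str
    mate2_cigar: str
    mate1_pos: int
    mate2_pos: int
    mate1_reverse: bool
    mate2_reverse: bool
    mate1_mapq: int = 60
    mate2_mapq: int = 60
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (1, 2):
            seq, quals = self.mate_seq(m), self.mate_quals(m)
            if len(seq) != len(quals):
                raise ValueError(
                    f"{self.pair_name}: mate{m} seq length {len(seq)} != "
                    f"quals length {len(quals)}"
                )
            if quals and (min(quals) < 0 or max(quals) > 93):
                raise ValueError(f"{self.pair_name}: Phred values outside [0, 93]")

    def mate_seq(self, mate: int) -> str:
        return self.mate1_seq if mate == 1 else self.mate2_seq

    def mate_quals(self, mate: int) -> list[int]:
        return self.mate1_quals if mate == 1 else self.mate2_quals

    def mate_cigar(self, mate: int) -> str:
        return self.mate1_cigar if mate == 1 else self.mate2_cigar

    def mate_pos(self, mate: int) -> int:
        return self.mate1_pos if mate == 1 else self.mate2_pos

    def mate_reverse(self, mate: int) -> bool:
        return self.mate1_reverse if mate == 1 else self.mate2_reverse

    def five_prime(self, mate: int) -> int:
        """Unclipped 5' coordinate of one mate (strand-aware)."""
        pos, cig = self.mate_pos(mate), self.mate_cigar(mate)
        return unclipped_end(pos, cig) if self.mate_reverse(mate) else unclipped_start(pos, cig)

    def duplicate_key(self) -> DuplicateKey:
        f1, f2 = self.five_prime(1), self.five_prime(2)
        r1, r2 = self.mate1_reverse, self.mate2_reverse
        if r1 != r2:
            fwd5 = f2 if r1 else f1
            rev5 = f1 if r1 else f2
            orientation = "FR" if fwd5 <= rev5 else "RF"
            return DuplicateKey(self.chrom, fwd5, rev5, orientation)
        orientation = "RR" if r1 else "FF"
        lo, hi = sorted((f1, f2))
        return DuplicateKey(self.chrom, lo, hi, orientation)

    def qual_sum(self) -> int:
        return sum(self.mate1_quals) + sum(self.mate2_quals)


def _canonical_mate_order(a: pysam.AlignedSegment, b: pysam.AlignedSegment):
    """Order two mates so the first is forward-oriented (leftmost on ties)."""
    if a.is_reverse != b.is_reverse:
        return (b, a) if a.is_reverse else (a, b)
    if (a.reference_start, a.is_read2) <= (b.reference_start, b.is_read2):
        return a, b
    return b, a


def _record_from_segments(a: pysam.AlignedSegment, b: pysam.AlignedSegment) -> ReadPairRecord:
    m1, m2 = _canonical_mate_order(a, b)
    tags: dict = {}
    if m1.has_tag(TAG_DUP_DEPTH):
        tags[TAG_DUP_DEPTH] = m1.get_tag(TAG_DUP_DEPTH)
    for mate, seg in ((1, m1), (2, m2)):
        if seg.has_tag(TAG_POLISHED):
            tags[f"{TAG_POLISHED}{mate}"] = [
                int(p) for p in str(seg.get_tag(TAG_POLISHED)).split(",") if p
            ]
    return ReadPairRecord(
        tags=tags,
        pair_name=m1.query_name,
        chrom=m1.reference_name,
        mate1_seq=m1.query_sequence,
        mate2_seq=m2.query_sequence,
        mate1_quals=list(m1.query_qualities),
        mate2_quals=list(m2.query_qualities),
        mate1_cigar=m1.cigarstring,
        mate2_cigar=m2.cigarstring,
        mate1_pos=m1.reference_start,
        mate2_pos=m2.reference_start,
        mate1_reverse=m1.is_reverse,
        mate2_reverse=m2.is_reverse,
        mate1_mapq=m1.mapping_quality,
        mate2_mapq=m2.mapping_quality,
    )


def _require_index(bam_path: str) -> None:
    for ext in (".bai", ".csi"):
        if os.path.exists(bam_path + ext):
            return
        root, _ = os.path.splitext(bam_path)
        if os.path.exists(root + ext):
            return
    raise FileNotFoundError(
        f"BAM index not found for {bam_path!r} (expected {bam_path}.bai); "
        "run 'samtools index' first"
    )


def read_pairs(
    bam_path: str,
    region: str | None = None,
    exclusions: Counter | None = None,
    orphans: list | None = None,
) -> Iterator[ReadPairRecord]:
    """Stream properly-paired primary alignments as ReadPairRecords.

    Secondary, supplementary, unmapped, QC-fail and duplicate-flagged
    records are dropped and tallied in ``exclusions``.  Pairs whose mates
    map to different chromosomes, and reads whose mate never appears
    ("orphans"), are tallied and — if ``orphans`` is a list — collected as
    raw pysam segments so callers can pass them through uncorrected.
    """
    _require_index(bam_path)
    counts = exclusions if exclusions is not None else Counter()
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        it = bam.fetch(region=region) if region else bam.fetch(until_eof=False)
        for seg in it:
            if seg.is_secondary:
                counts["secondary"] += 1
                continue
            if seg.is_supplementary:
                counts["supplementary"] += 1
                continue
            if seg.is_unmapped:
                counts["unmapped"] += 1
                continue
            if seg.is_qcfail:
                counts["qcfail"] += 1
                continue
            if seg.is_duplicate:
                counts["duplicate_flagged"] += 1
                continue
            if not seg.is_paired or seg.mate_is_unmapped:
                counts["orphan"] += 1
                if orphans is not None:
                    orphans.append(seg)
                continue
            name = seg.query_name
            other = pending.pop(name, None)
            if other is None:
                pending[name] = seg
                continue
            if other.reference_name != seg.reference_name:
                counts["discordant_chrom"] += 1
                if orphans is not None:
                    orphans.extend([other, seg])
                continue
            yield _record_from_segments(other, seg)
    counts["orphan"] += len(pending)
    if orphans is not None:
        orphans.extend(pending.values())
    if counts:
        logger.info("read_pairs exclusions: %s", dict(counts))


def load_pairs(
    bam_path: str, region: str | None = None
) -> tuple[list[ReadPairRecord], Counter, list]:
    """Eagerly read all pairs; returns (records, exclusion counts, orphans)."""
    exclusions: Counter = Counter()
    orphans: list = []
    records = list(read_pairs(bam_path, region, exclusions, orphans))
    return records, exclusions, orphans


def _segments_from_record(
    rec: ReadPairRecord, header: pysam.AlignmentHeader
) -> tuple[pysam.AlignedSegment, pysam.AlignedSegment]:
    tid = header.get_tid(rec.chrom)
    segs = []
    for mate in (1, 2):
        other = 2 if mate == 1 else 1
        s = pysam.AlignedSegment(header)
        s.query_name = rec.pair_name
        s.query_sequence = rec.mate_seq(mate)
        s.query_qualities = rec.mate_quals(mate)
        s.reference_id = tid
        s.reference_start = rec.mate_pos(mate)
        s.cigarstring = rec.mate_cigar(mate)
        s.mapping_quality = rec.mate1_mapq if mate == 1 else rec.mate2_mapq
        s.is_paired = True
        s.is_proper_pair = rec.mate1_reverse != rec.mate2_reverse
        s.is_read1 = mate == 1
        s.is_read2 = mate == 2
        s.is_reverse = rec.mate_reverse(mate)
        s.mate_is_reverse = rec.mate_reverse(other)
        s.next_reference_id = tid
        s.next_reference_start = rec.mate_pos(other)
        tags = []
        if TAG_DUP_DEPTH in rec.tags:
            tags.append((TAG_DUP_DEPTH, int(rec.tags[TAG_DUP_DEPTH]), "i"))
        polished = rec.tags.get(f"{TAG_POLISHED}{mate}")
        if polished:
            tags.append((TAG_POLISHED, ",".join(str(p) for p in polished), "Z"))
        if tags:
            s.set_tags(tags)
        segs.append(s)
    a, b = segs
    left = min(rec.mate1_pos, rec.mate2_pos)
    right = max(
        rec.mate1_pos + cigar_reference_length(rec.mate1_cigar),
        rec.mate2_pos + cigar_reference_length(rec.mate2_cigar),
    )
    tlen = right - left
    a.template_length = tlen if rec.mate1_pos <= rec.mate2_pos else -tlen
    b.template_length = -a.template_length
    return a, b


def write_pairs(
    records: Iterable[ReadPairRecord],
    header: pysam.AlignmentHeader | dict,
    bam_path: str,
    passthrough: Iterable[pysam.AlignedSegment] = (),
) -> int:
    """Write records (plus untouched pass-through segments) as a sorted,
    indexed BAM.  Returns the number of alignment records written.

    Records arriving out of coordinate order are re-sorted before the final
    file is produced.
    """
    if isinstance(header, dict):
        header = pysam.AlignmentHeader.from_dict(header)
    tmp = bam_path + ".unsorted.tmp.bam"
    n = 0
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for rec in records:
            for seg in _segments_from_record(rec, header):
                out.write(seg)
                n += 1
        for seg in passthrough:
            out.write(seg)
            n += 1
    pysam.sort("-o", bam_path, tmp)
    os.remove(tmp)
    pysam.index(bam_path)
    return n
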
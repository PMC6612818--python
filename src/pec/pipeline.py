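"""End-to-end error-correction pipeline.

Stages, in order: read pairs from BAM -> group into PCR-duplicate families
by unclipped 5' coordinates -> split at the duplicate-depth threshold ->
consensus-correct high-depth families while learning trusted/untrusted
k-mers -> merge into the global error-k-mer catalogue -> select and polish
representatives of low-depth families -> Smith-Waterman realignment ->
write one corrected pair per family, plus a machine-readable run report.

The implementation is single-process; results are invariant to input
order (grouping sorts families and members canonically), which is the
contract a parallel implementation would also have to meet.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import pysam

from . import bam_io
from .bam_io import ReadPairRecord
from .consensus import ConsensusUndefined, build_consensus, substitution_spectrum
from .grouping import DuplicateSet, depth_histogram, group_pairs, split_by_depth
from .kmers import DEFAULT_K, ErrorKmerSet, flag_family_kmers, merge_error_kmers
from .polishing import DEFAULT_FLAG_QUAL, polish_read, select_representative
from .realign import Scoring, realign_pair

logger = logging.getLogger(__name__)

__all__ = ["PecConfig", "RunReport", "run_pec"]


@dataclass
class PecConfig:
    """Tunable parameters of the correction pipeline.

    ``mode="consensus"`` is the full algorithm; ``mode="best-read"`` keeps
    the highest-quality member of *every* family with no consensus and no
    polishing — the MarkDuplicates-style baseline, useful for comparison.
    """

    min_dup_depth: int = 5
    min_base_qual: int = 20
    flag_qual: int = DEFAULT_FLAG_QUAL
    k: int = DEFAULT_K
    window_margin: int = 50
    scoring: Scoring = field(default_factory=Scoring)
    realign: bool = True
    mode: str = "consensus"  # or "best-read"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    config: dict
    n_input_pairs: int
    n_families: int
    n_output_pairs: int
    depth_histogram: dict[int, int]
    substitution_spectrum: dict[str, int]
    n_corrected_bases: int
    n_error_kmers: int
    n_polished_bases: int
    n_polished_reads: int
    exclusions: dict[str, int]
    n_passthrough: int

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _consensus_record(family: DuplicateSet, cons, depth_tag: int) -> ReadPairRecord:
    """Materialize a consensus as a read pair named after the family's
    first member, positioned at the modal voters' coordinates."""
    by_name = {m.pair_name: m for m in family.members}
    proto = {mate: by_name[cons.voters[mate][0]] for mate in (1, 2)}
    rec = ReadPairRecord(
        pair_name=family.members[0].pair_name,
        chrom=family.key.chrom,
        mate1_seq=cons.mate1_seq,
        mate2_seq=cons.mate2_seq,
        mate1_quals=cons.mate1_quals,
        mate2_quals=cons.mate2_quals,
        mate1_cigar=proto[1].mate1_cigar,
        mate2_cigar=proto[2].mate2_cigar,
        mate1_pos=proto[1].mate1_pos,
        mate2_pos=proto[2].mate2_pos,
        mate1_reverse=proto[1].mate1_reverse,
        mate2_reverse=proto[2].mate2_reverse,
        mate1_mapq=max(m.mate1_mapq for m in family.members),
        mate2_mapq=max(m.mate2_mapq for m in family.members),
        tags={bam_io.TAG_DUP_DEPTH: depth_tag},
    )
    return rec


def correct_families(
    families: list[DuplicateSet], config: PecConfig
) -> tuple[list[ReadPairRecord], dict]:
    """Core correction over grouped families (no I/O).

    Returns one output record per family plus stage statistics.  High-depth
    families yield a consensus pair; all others yield their polished
    highest-quality representative.
    """
    stats: dict = {}
    if config.mode == "best-read":
        out = []
        for fam in families:
            rep = select_representative(fam)
            rep = dataclasses.replace(rep, tags=dict(rep.tags))
            rep.tags[bam_io.TAG_DUP_DEPTH] = fam.duplicate_depth
            out.append(rep)
        stats.update(
            substitution_spectrum={}, n_corrected_bases=0, n_error_kmers=0,
            n_polished_bases=0, n_polished_reads=0,
        )
        return out, stats

    high, low = split_by_depth(families, config.min_dup_depth)
    consensus_out: list[ReadPairRecord] = []
    tables = []
    all_corrected = []
    for fam in high:
        try:
            cons = build_consensus(fam, min_base_qual=config.min_base_qual)
        except ConsensusUndefined as exc:
            logger.info("family routed to representative path: %s", exc)
            low.append(fam)
            continue
        all_corrected.extend(cons.corrected_positions)
        tables.append(
            flag_family_kmers(fam, cons, k=config.k, min_base_qual=config.min_base_qual)
        )
        consensus_out.append(_consensus_record(fam, cons, fam.duplicate_depth))

    error_set = merge_error_kmers(tables) if tables else ErrorKmerSet(k=config.k)

    polished_out: list[ReadPairRecord] = []
    n_polished_bases = 0
    n_polished_reads = 0
    for fam in low:
        rep = select_representative(fam)
        rep = dataclasses.replace(rep, tags=dict(rep.tags))
        rep.tags[bam_io.TAG_DUP_DEPTH] = fam.duplicate_depth
        rep = polish_read(rep, error_set, flag_qual=config.flag_qual)
        n_flagged = sum(len(rep.tags.get(f"pb{m}", ())) for m in (1, 2))
        if n_flagged:
            n_polished_reads += 1
            n_polished_bases += n_flagged
        polished_out.append(rep)

    out = consensus_out + polished_out
    stats.update(
        substitution_spectrum=substitution_spectrum(all_corrected),
        n_corrected_bases=len(all_corrected),
        n_error_kmers=len(error_set),
        n_polished_bases=n_polished_bases,
        n_polished_reads=n_polished_reads,
    )
    return out, stats


def run_pec(
    bam_in: str,
    ref_fasta: str,
    bam_out: str,
    config: PecConfig | None = None,
    report_path: str | None = None,
) -> RunReport:
    """Run the full pipeline on a coordinate-sorted, indexed BAM.

    Writes one corrected pair per duplicate family (orphans pass through
    untouched) and returns a :class:`RunReport`; ``report_path`` dumps it
    as JSON.
    """
    config = config or PecConfig()
    records, exclusions, orphans = bam_io.load_pairs(bam_in)
    families = group_pairs(records)
    assert sum(f.duplicate_depth for f in families) == len(records)

    out, stats = correct_families(families, config)

    if config.realign:
        with pysam.FastaFile(ref_fasta) as ref:
            out = [
                realign_pair(
                    rec, ref,
                    window_margin=config.window_margin,
                    scoring=config.scoring,
                )
                for rec in out
            ]

    with pysam.AlignmentFile(bam_in, "rb") as src:
        header = src.header.to_dict()
    header["HD"]["SO"] = "coordinate"
    n_written = bam_io.write_pairs(out, header, bam_out, passthrough=orphans)

    report = RunReport(
        config=config.to_dict(),
        n_input_pairs=len(records),
        n_families=len(families),
        n_output_pairs=len(out),
        depth_histogram=depth_histogram(families),
        substitution_spectrum=stats["substitution_spectrum"],
        n_corrected_bases=stats["n_corrected_bases"],
        n_error_kmers=stats["n_error_kmers"],
        n_polished_bases=stats["n_polished_bases"],
        n_polished_reads=stats["n_polished_reads"],
        exclusions=dict(exclusions),
        n_passthrough=len(orphans),
    )
    if report_path:
        report.to_json(report_path)
    logger.info(
        "pec: %d pairs -> %d families -> %d corrected pairs "
        "(%d error k-mers, %d polished bases, %d written records)",
        len(records), len(families), len(out),
        report.n_error_kmers, report.n_polished_bases, n_written,
    )
    return report
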
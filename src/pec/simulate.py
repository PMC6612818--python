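"""Truth-annotated cfDNA read simulator.

Generates a random reference, draws cfDNA fragments with normally
distributed lengths (defaults mu=177 bp, sigma=20 bp — typical cfDNA
library values), amplifies each fragment into a PCR-duplicate family with
geometrically distributed duplicate depth, and emits aligned paired-end
reads as a coordinate-sorted BAM plus tab-separated truth tables recording
every fragment, family, and injected error.

Three error channels are modelled:

* **PCR errors** — independent per duplicate per base at ``pcr_error_rate``,
  substitution type drawn from a spectrum enriched for G>T and C>T (the
  signature of amplification/oxidative damage); written with high Phred
  (>=30), so they are indistinguishable from real alleles by quality alone.
* **Hotspot errors** — recurrent systematic errors at fixed loci, hitting
  each duplicate independently with probability ``recurrence``; also high
  Phred.  These mimic artifact hotspots that accumulate across families and
  can masquerade as variants.
* **Sequencer errors** — independent per base at ``seq_error_rate``, always
  carrying Phred < 20 so they exercise the low-quality exemption.

Optional spike-in variants are real alleles carried by a fraction of
fragments (fragment-level, so duplicates agree and consensus preserves
them).

By default fragments are rejection-sampled to unique (start, length) so
the family partition is exactly recoverable from coordinates; set
``ensure_unique_keys=False`` to study grouping collisions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "Hotspot",
    "SpikeVariant",
    "SimConfig",
    "SimResult",
    "simulate",
    "default_config",
    "score_against_truth",
]

BASES = "ACGT"

# substitution spectrum: P(to | from), enriched for G>T and C>T
DEFAULT_SPECTRUM = {
    "A": {"C": 0.3, "G": 0.4, "T": 0.3},
    "C": {"A": 0.2, "G": 0.2, "T": 0.6},
    "G": {"A": 0.2, "C": 0.2, "T": 0.6},
    "T": {"A": 0.3, "C": 0.4, "G": 0.3},
}


@dataclass
class Hotspot:
    """A recurrent systematic error locus."""

    position: int
    to_base: str | None = None  # default: spectrum mode for the ref base
    recurrence: float = 0.05  # per-duplicate probability
    from_base: str | None = None  # must match the reference if given


@dataclass
class SpikeVariant:
    """A true variant present in a fraction of fragments."""

    position: int
    alt: str | None = None
    vaf: float = 0.05


@dataclass
class SimConfig:
    ref_length: int = 20_000
    n_fragments: int = 10_000
    frag_mu: float = 177.0
    frag_sigma: float = 20.0
    dup_depth_mean: float = 6.0  # geometric on {1, 2, ...}
    pcr_error_rate: float = 1e-3
    seq_error_rate: float = 1e-3
    hotspots: list[Hotspot] = field(default_factory=list)
    spike_variants: list[SpikeVariant] = field(default_factory=list)
    read_length: int = 100
    n_orphans: int = 0
    ensure_unique_keys: bool = True
    chrom: str = "sim1"
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("pcr_error_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for h in self.hotspots:
            if not 0.0 <= h.recurrence <= 1.0:
                raise ValueError(f"hotspot recurrence must be in [0,1]")
        for v in self.spike_variants:
            if not 0.0 <= v.vaf <= 1.0:
                raise ValueError("spike VAF must be in [0,1]")
        if self.ref_length <= 0 or self.read_length <= 0 or self.n_fragments < 0:
            raise ValueError("lengths/counts must be positive")
        if self.dup_depth_mean < 1.0:
            raise ValueError("dup_depth_mean must be >= 1")


def default_config(seed: int = 1, n_hotspots: int = 5, **overrides) -> SimConfig:
    """The default desk-scale fixture: 10^4 fragments on 20 kb, mean
    duplicate depth 6, PCR error rate 1e-3, 5 evenly spaced hotspot loci."""
    cfg = SimConfig(seed=seed, **overrides)
    step = cfg.ref_length // (n_hotspots + 1)
    cfg.hotspots = [Hotspot(position=step * (i + 1)) for i in range(n_hotspots)]
    return cfg


@dataclass
class SimResult:
    config: SimConfig
    reference: str
    fasta_path: str
    bam_path: str
    families: pd.DataFrame
    reads: pd.DataFrame
    errors: pd.DataFrame
    variants: pd.DataFrame

    @property
    def truth(self) -> dict[str, pd.DataFrame]:
        return {
            "families": self.families,
            "reads": self.reads,
            "errors": self.errors,
            "variants": self.variants,
        }


def _spectrum_mode(base: str) -> str:
    row = DEFAULT_SPECTRUM[base]
    return min(row, key=lambda b: (-row[b], b))


def _draw_substitution(base: str, rng: np.random.Generator) -> str:
    row = DEFAULT_SPECTRUM[base]
    tos = sorted(row)
    probs = np.array([row[b] for b in tos])
    return tos[rng.choice(len(tos), p=probs / probs.sum())]


def _sample_fragments(cfg: SimConfig, rng: np.random.Generator):
    """(start, length) per fragment, unique if configured."""
    min_len = cfg.read_length
    seen: set[tuple[int, int]] = set()
    out = []
    while len(out) < cfg.n_fragments:
        length = int(round(rng.normal(cfg.frag_mu, cfg.frag_sigma)))
        if length < min_len or length > cfg.ref_length:
            continue
        start = int(rng.integers(0, cfg.ref_length - length + 1))
        if cfg.ensure_unique_keys:
            if (start, length) in seen:
                continue
            seen.add((start, length))
        out.append((start, length))
    return out


def simulate(cfg: SimConfig, outdir: str) -> SimResult:
    """Run the generator; writes FASTA (+fai), BAM (+bai) and truth TSVs.

    The seed fixes the entire output byte stream: two runs with identical
    configs produce identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length

    ref = "".join(BASES[i] for i in rng.integers(0, 4, size=cfg.ref_length))

    hotspots = []
    for h in cfg.hotspots:
        ref_base = ref[h.position]
        if h.from_base is not None and h.from_base != ref_base:
            raise ValueError(
                f"hotspot at {h.position}: from_base {h.from_base} != "
                f"reference {ref_base}"
            )
        to = h.to_base or _spectrum_mode(ref_base)
        hotspots.append(Hotspot(h.position, to, h.recurrence, ref_base))

    variants = []
    for v in cfg.spike_variants:
        ref_base = ref[v.position]
        alt = v.alt or _spectrum_mode(ref_base)
        variants.append(SpikeVariant(v.position, alt, v.vaf))

    fragments = _sample_fragments(cfg, rng)
    depths = rng.geometric(1.0 / cfg.dup_depth_mean, size=len(fragments))

    fam_rows, read_rows, err_rows = [], [], []
    var_carriers = {v.position: 0 for v in variants}
    segments = []

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": cfg.chrom, "LN": cfg.ref_length}],
        }
    )

    for fid, ((start, length), depth) in enumerate(zip(fragments, depths)):
        frag = list(ref[start : start + length])
        for v in variants:
            if start <= v.position < start + length and rng.random() < v.vaf:
                frag[v.position - start] = v.alt
                var_carriers[v.position] += 1
        frag = "".join(frag)
        m_pos = {1: start, 2: start + length - rl}
        m_true = {1: frag[:rl], 2: frag[-rl:]}
        fam_rows.append(
            dict(
                family_id=fid,
                chrom=cfg.chrom,
                frag_start=start,
                frag_len=length,
                fwd5=start,
                rev5=start + length - 1,
                depth=int(depth),
                mate1_pos=m_pos[1],
                mate2_pos=m_pos[2],
                mate1_true_seq=m_true[1],
                mate2_true_seq=m_true[2],
            )
        )
        for d in range(depth):
            qname = f"F{fid:06d}:D{d:03d}"
            n_err = {"pcr": 0, "seq": 0, "hotspot": 0}
            for mate in (1, 2):
                seq = list(m_true[mate])
                quals = rng.integers(30, 41, size=rl)
                pos0 = m_pos[mate]
                # recurrent hotspot errors (high quality)
                for h in hotspots:
                    rp = h.position - pos0
                    if 0 <= rp < rl and rng.random() < h.recurrence:
                        if seq[rp] == h.from_base:
                            err_rows.append(
                                dict(qname=qname, family_id=fid, mate=mate,
                                     read_pos=rp, ref_pos=h.position, kind="hotspot",
                                     from_base=seq[rp], to_base=h.to_base)
                            )
                            seq[rp] = h.to_base
                            n_err["hotspot"] += 1
                # random PCR errors (high quality)
                n_pcr = rng.binomial(rl, cfg.pcr_error_rate)
                for rp in sorted(rng.choice(rl, size=n_pcr, replace=False)):
                    old = seq[rp]
                    if old not in BASES:
                        continue
                    new = _draw_substitution(old, rng)
                    err_rows.append(
                        dict(qname=qname, family_id=fid, mate=mate, read_pos=int(rp),
                             ref_pos=pos0 + int(rp), kind="pcr",
                             from_base=old, to_base=new)
                    )
                    seq[rp] = new
                    n_err["pcr"] += 1
                # sequencer errors (low quality, Phred < 20)
                n_seq = rng.binomial(rl, cfg.seq_error_rate)
                for rp in sorted(rng.choice(rl, size=n_seq, replace=False)):
                    old = seq[rp]
                    if old not in BASES:
                        continue
                    new = BASES[(BASES.index(old) + 1 + rng.integers(0, 3)) % 4]
                    err_rows.append(
                        dict(qname=qname, family_id=fid, mate=mate, read_pos=int(rp),
                             ref_pos=pos0 + int(rp), kind="seq",
                             from_base=old, to_base=new)
                    )
                    seq[rp] = new
                    quals[rp] = rng.integers(2, 20)
                    n_err["seq"] += 1
                seg = pysam.AlignedSegment(header)
                seg.query_name = qname
                seg.query_sequence = "".join(seq)
                seg.query_qualities = [int(q) for q in quals]
                seg.reference_id = 0
                seg.reference_start = pos0
                seg.cigarstring = f"{rl}M"
                seg.mapping_quality = 60
                seg.is_paired = True
                seg.is_proper_pair = True
                seg.is_read1 = mate == 1
                seg.is_read2 = mate == 2
                seg.is_reverse = mate == 2
                seg.mate_is_reverse = mate == 1
                seg.next_reference_id = 0
                seg.next_reference_start = m_pos[2 if mate == 1 else 1]
                tlen = length
                seg.template_length = tlen if mate == 1 else -tlen
                segments.append(seg)
            read_rows.append(
                dict(qname=qname, family_id=fid, n_pcr=n_err["pcr"],
                     n_seq=n_err["seq"], n_hotspot=n_err["hotspot"])
            )

    # orphan single-end leftovers (mate never written)
    for i in range(cfg.n_orphans):
        start = int(rng.integers(0, cfg.ref_length - rl + 1))
        seg = pysam.AlignedSegment(header)
        seg.query_name = f"ORPH{i:04d}"
        seg.query_sequence = ref[start : start + rl]
        seg.query_qualities = [35] * rl
        seg.reference_id = 0
        seg.reference_start = start
        seg.cigarstring = f"{rl}M"
        seg.mapping_quality = 60
        seg.is_paired = True
        seg.is_read1 = True
        seg.next_reference_id = 0
        seg.next_reference_start = start
        segments.append(seg)

    fasta_path = os.path.join(outdir, "ref.fa")
    with open(fasta_path, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        for i in range(0, cfg.ref_length, 70):
            fh.write(ref[i : i + 70] + "\n")
    if os.path.exists(fasta_path + ".fai"):
        os.remove(fasta_path + ".fai")
    pysam.faidx(fasta_path)

    bam_path = os.path.join(outdir, "reads.bam")
    tmp = bam_path + ".unsorted.tmp.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for seg in segments:
            bam.write(seg)
    pysam.sort("-o", bam_path, tmp)
    os.remove(tmp)
    pysam.index(bam_path)

    families = pd.DataFrame(fam_rows)
    reads = pd.DataFrame(read_rows)
    errors = pd.DataFrame(
        err_rows,
        columns=["qname", "family_id", "mate", "read_pos", "ref_pos", "kind",
                 "from_base", "to_base"],
    )
    var_df = pd.DataFrame(
        [dict(position=v.position, ref=ref[v.position], alt=v.alt,
              vaf_target=v.vaf, n_fragments=var_carriers[v.position])
         for v in variants],
        columns=["position", "ref", "alt", "vaf_target", "n_fragments"],
    )
    families.to_csv(os.path.join(outdir, "truth_families.tsv"), sep="\t", index=False)
    reads.to_csv(os.path.join(outdir, "truth_reads.tsv"), sep="\t", index=False)
    errors.to_csv(os.path.join(outdir, "truth_errors.tsv"), sep="\t", index=False)
    var_df.to_csv(os.path.join(outdir, "truth_variants.tsv"), sep="\t", index=False)

    return SimResult(
        config=cfg, reference=ref, fasta_path=fasta_path, bam_path=bam_path,
        families=families, reads=reads, errors=errors, variants=var_df,
    )


def score_against_truth(
    bam_path: str, truth: SimResult | dict, min_dup_depth: int = 5
) -> dict:
    """Score any (corrected or raw) BAM against simulator truth.

    Reports the residual per-base mismatch rate against the fragment-level
    true mate sequences, hotspot flag recall/precision on low-depth
    representatives, false flags on error-free ("k-mer-clean") low-depth
    reads, and family-count agreement.
    """
    from .bam_io import load_pairs

    tables = truth.truth if isinstance(truth, SimResult) else truth
    families = tables["families"].set_index("family_id")
    errors = tables["errors"]

    records, _, _ = load_pairs(bam_path)
    n_mismatch = 0
    n_bases = 0
    flagged: dict[tuple[str, int], set[int]] = {}
    present: set[str] = set()
    for rec in records:
        if not rec.pair_name.startswith("F"):
            continue
        fid = int(rec.pair_name.split(":")[0][1:])
        fam = families.loc[fid]
        present.add(rec.pair_name)
        for mate in (1, 2):
            true_seq = fam[f"mate{mate}_true_seq"]
            seq = rec.mate_seq(mate)
            n = min(len(seq), len(true_seq))
            n_bases += n
            n_mismatch += sum(a != b for a, b in zip(seq[:n], true_seq[:n]))
            pb = rec.tags.get(f"pb{mate}")
            if pb:
                flagged[(rec.pair_name, mate)] = set(pb)

    qname_err = errors.groupby("qname").size() if len(errors) else pd.Series(dtype=int)
    low_depth = set(families.index[families["depth"] < min_dup_depth])

    hot = errors[errors["kind"] == "hotspot"] if len(errors) else errors
    n_hot = n_hot_recalled = 0
    if len(hot):
        for _, row in hot.iterrows():
            if row["qname"] not in present or row["family_id"] not in low_depth:
                continue
            n_hot += 1
            if row["read_pos"] in flagged.get((row["qname"], row["mate"]), set()):
                n_hot_recalled += 1

    n_flags = sum(len(s) for s in flagged.values())
    # a flag is correct if it lands on any true error position of that read
    true_err_pos = set()
    if len(errors):
        true_err_pos = {
            (r["qname"], r["mate"], r["read_pos"]) for _, r in errors.iterrows()
        }
    n_flags_on_errors = sum(
        1
        for (qn, mate), poss in flagged.items()
        for p in poss
        if (qn, mate, p) in true_err_pos
    )

    clean_low = [
        qn for qn in present
        if int(qn.split(":")[0][1:]) in low_depth and qname_err.get(qn, 0) == 0
    ]
    n_false_on_clean = sum(
        len(flagged.get((qn, mate), ())) for qn in clean_low for mate in (1, 2)
    )

    return {
        "n_records": len(records),
        "n_truth_families": len(families),
        "residual_mismatch_rate": n_mismatch / n_bases if n_bases else 0.0,
        "n_mismatch": n_mismatch,
        "n_bases": n_bases,
        "hotspot_flag_recall": n_hot_recalled / n_hot if n_hot else float("nan"),
        "n_hotspot_errors_on_low_depth": n_hot,
        "n_flags": n_flags,
        "flag_precision": n_flags_on_errors / n_flags if n_flags else float("nan"),
        "n_clean_low_depth_reads": len(clean_low),
        "n_false_flags_on_clean": n_false_on_clean,
    }
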
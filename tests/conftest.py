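import pytest

from pec.bam_io import ReadPairRecord
from pec.grouping import DuplicateSet, group_pairs
from pec.simulate import default_config, simulate


def make_pair(
    name="p1",
    chrom="sim1",
    m1_seq="ACGTACGTAC",
    m2_seq="TTGGCCAATT",
    m1_qual=None,
    m2_qual=None,
    m1_pos=100,
    m2_pos=200,
    m1_cigar=None,
    m2_cigar=None,
    m1_rev=False,
    m2_rev=True,
) -> ReadPairRecord:
    """Small hand-built FR read pair with sensible defaults."""
    return ReadPairRecord(
        pair_name=name,
        chrom=chrom,
        mate1_seq=m1_seq,
        mate2_seq=m2_seq,
        mate1_quals=m1_qual if m1_qual is not None else [35] * len(m1_seq),
        mate2_quals=m2_qual if m2_qual is not None else [35] * len(m2_seq),
        mate1_cigar=m1_cigar or f"{len(m1_seq)}M",
        mate2_cigar=m2_cigar or f"{len(m2_seq)}M",
        mate1_pos=m1_pos,
        mate2_pos=m2_pos,
        mate1_reverse=m1_rev,
        mate2_reverse=m2_rev,
    )


def make_family(seqs1, seqs2=None, quals1=None, **kw) -> DuplicateSet:
    """Family of pairs differing only in mate sequences/qualities."""
    n = len(seqs1)
    seqs2 = seqs2 or ["TTGGCCAATTGG"[: len(seqs1[0])]] * n
    pairs = []
    for i in range(n):
        q1 = quals1[i] if quals1 else None
        pairs.append(
            make_pair(name=f"p{i:03d}", m1_seq=seqs1[i], m2_seq=seqs2[i],
                      m1_qual=q1, **kw)
        )
    fams = group_pairs(pairs)
    assert len(fams) == 1
    return fams[0]


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """Small simulated dataset: 300 fragments on 5 kb, 5 hotspot loci."""
    outdir = tmp_path_factory.mktemp("sim_small")
    cfg = default_config(seed=7, n_fragments=300, ref_length=5_000)
    return simulate(cfg, str(outdir))


@pytest.fixture(scope="session")
def sim_default(tmp_path_factory):
    """The default desk-scale fixture (10^4 fragments, mean depth 6,
    PCR error rate 1e-3, 5 hotspots), fixed seed."""
    outdir = tmp_path_factory.mktemp("sim_default")
    return simulate(default_config(seed=42), str(outdir))
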
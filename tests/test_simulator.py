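"""Simulator contracts: truth-table provenance, distributions, determinism."""

import hashlib

import numpy as np
import pysam
import pytest

from pec.bam_io import load_pairs
from pec.simulate import Hotspot, SimConfig, SpikeVariant, default_config, simulate


def bam_digest(path):
    with pysam.AlignmentFile(path) as f:
        return hashlib.md5("".join(s.tostring() for s in f).encode()).hexdigest()


class TestConfigValidation:
    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(pcr_error_rate=1.5)

    def test_bad_vaf_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(spike_variants=[SpikeVariant(position=10, vaf=2.0)])

    def test_hotspot_from_base_must_match_reference(self, tmp_path):
        cfg = SimConfig(seed=5, ref_length=2000, n_fragments=5)
        ref = simulate(cfg, str(tmp_path / "probe")).reference
        wrong = "A" if ref[500] != "A" else "C"
        cfg2 = SimConfig(
            seed=5, ref_length=2000, n_fragments=5,
            hotspots=[Hotspot(position=500, from_base=wrong)],
        )
        with pytest.raises(ValueError, match="from_base"):
            simulate(cfg2, str(tmp_path / "bad"))


class TestZeroNoise:
    def test_members_identical_to_fragment(self, tmp_path):
        cfg = SimConfig(seed=2, ref_length=4000, n_fragments=50,
                        pcr_error_rate=0.0, seq_error_rate=0.0)
        res = simulate(cfg, str(tmp_path))
        assert len(res.errors) == 0
        fams = res.families.set_index("family_id")
        records, _, _ = load_pairs(res.bam_path)
        for rec in records:
            fid = int(rec.pair_name.split(":")[0][1:])
            assert rec.mate1_seq == fams.loc[fid, "mate1_true_seq"]
            assert rec.mate2_seq == fams.loc[fid, "mate2_true_seq"]

    def test_reads_match_reference_exactly(self, tmp_path):
        cfg = SimConfig(seed=2, ref_length=4000, n_fragments=50,
                        pcr_error_rate=0.0, seq_error_rate=0.0)
        res = simulate(cfg, str(tmp_path))
        records, _, _ = load_pairs(res.bam_path)
        for rec in records[:20]:
            for mate in (1, 2):
                s, p = rec.mate_seq(mate), rec.mate_pos(mate)
                assert s == res.reference[p : p + len(s)]


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = dict(seed=11, ref_length=3000, n_fragments=40)
        r1 = simulate(SimConfig(**cfg), str(tmp_path / "a"))
        r2 = simulate(SimConfig(**cfg), str(tmp_path / "b"))
        assert open(r1.fasta_path).read() == open(r2.fasta_path).read()
        assert bam_digest(r1.bam_path) == bam_digest(r2.bam_path)
        for name in ("families", "reads", "errors"):
            assert r1.truth[name].equals(r2.truth[name])

    def test_different_seed_differs(self, tmp_path):
        r1 = simulate(SimConfig(seed=11, ref_length=3000, n_fragments=40),
                      str(tmp_path / "a"))
        r2 = simulate(SimConfig(seed=12, ref_length=3000, n_fragments=40),
                      str(tmp_path / "b"))
        assert r1.reference != r2.reference


class TestDistributions:
    def test_fragment_length_moments(self, sim_default):
        lens = sim_default.families["frag_len"].to_numpy()
        n = len(lens)
        assert abs(lens.mean() - 177) <= 3 * 20 / np.sqrt(n)
        # SD of the sample SD ~ sigma / sqrt(2n)
        assert abs(lens.std(ddof=1) - 20) <= 3 * 20 / np.sqrt(2 * n)

    def test_duplicate_depth_mean(self, sim_default):
        depths = sim_default.families["depth"].to_numpy()
        se = depths.std(ddof=1) / np.sqrt(len(depths))
        assert abs(depths.mean() - 6.0) <= 3 * se

    def test_pcr_error_count(self, sim_default):
        n_bases = 2 * sim_default.config.read_length * len(sim_default.reads)
        n_pcr = (sim_default.errors["kind"] == "pcr").sum()
        rate = sim_default.config.pcr_error_rate
        assert abs(n_pcr - n_bases * rate) <= 3 * np.sqrt(n_bases * rate)

    def test_seq_errors_low_quality_pcr_high(self, sim_small):
        records, _, _ = load_pairs(sim_small.bam_path)
        by_name = {r.pair_name: r for r in records}
        for _, e in sim_small.errors.iterrows():
            q = by_name[e.qname].mate_quals(e["mate"])[e.read_pos]
            if e["kind"] == "seq":
                assert q < 20
            elif e["kind"] in ("pcr", "hotspot"):
                # unless a later sequencer error hit the same base
                overlapping_seq = (
                    (sim_small.errors.qname == e.qname)
                    & (sim_small.errors["mate"] == e["mate"])
                    & (sim_small.errors.read_pos == e.read_pos)
                    & (sim_small.errors.kind == "seq")
                ).any()
                if not overlapping_seq:
                    assert q >= 30

    def test_spectrum_enriched_for_g_t_and_c_t(self, sim_default):
        pcr = sim_default.errors[sim_default.errors["kind"] == "pcr"]
        counts = pcr.groupby(["from_base", "to_base"]).size()
        assert counts[("G", "T")] > counts[("G", "A")]
        assert counts[("C", "T")] > counts[("C", "G")]


class TestProvenance:
    def test_every_read_reconstructable_from_truth(self, sim_small):
        """Applying the truth error list to the true fragment sequence
        reproduces every emitted read byte-for-byte."""
        fams = sim_small.families.set_index("family_id")
        errs = sim_small.errors.groupby(["qname", "mate"])
        records, _, _ = load_pairs(sim_small.bam_path)
        for rec in records:
            fid = int(rec.pair_name.split(":")[0][1:])
            for mate in (1, 2):
                seq = list(fams.loc[fid, f"mate{mate}_true_seq"])
                try:
                    for _, e in errs.get_group((rec.pair_name, mate)).iterrows():
                        assert seq[e.read_pos] == e.from_base
                        seq[e.read_pos] = e.to_base
                except KeyError:
                    pass
                assert "".join(seq) == rec.mate_seq(mate)

    def test_unique_keys_give_unique_coordinates(self, sim_small):
        fams = sim_small.families
        assert not fams.duplicated(subset=["frag_start", "frag_len"]).any()

    def test_hotspot_events_recorded_at_configured_loci(self, sim_default):
        hot = sim_default.errors[sim_default.errors["kind"] == "hotspot"]
        configured = {h.position for h in sim_default.config.hotspots}
        assert set(hot["ref_pos"].unique()) <= configured
        assert len(hot) > 0


def test_spike_variants_propagate_to_whole_family(tmp_path):
    cfg = SimConfig(
        seed=21, ref_length=3000, n_fragments=80, pcr_error_rate=0.0,
        seq_error_rate=0.0, dup_depth_mean=4.0,
        spike_variants=[SpikeVariant(position=1500, vaf=0.5)],
    )
    res = simulate(cfg, str(tmp_path))
    v = res.variants.iloc[0]
    assert v["n_fragments"] > 0
    records, _, _ = load_pairs(res.bam_path)
    fams = res.families.set_index("family_id")
    n_carrier_reads = 0
    for rec in records:
        fid = int(rec.pair_name.split(":")[0][1:])
        fam = fams.loc[fid]
        for mate in (1, 2):
            pos0 = fam[f"mate{mate}_pos"]
            rp = 1500 - pos0
            if 0 <= rp < cfg.read_length:
                true_base = fam[f"mate{mate}_true_seq"][rp]
                assert rec.mate_seq(mate)[rp] == true_base  # all duplicates agree
                if true_base == v["alt"] != v["ref"]:
                    n_carrier_reads += 1
    assert n_carrier_reads > 0
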
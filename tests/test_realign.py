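"""Smith-Waterman tests against an independent pure-Python DP oracle.

The oracle re-derives the affine-gap local alignment with explicit
state-tracking lists, sharing the same declared conventions (length-g gap
costs gap_open + g*gap_extend; best cell = first maximum in row-major
order; traceback prefers diagonal > up > left) but none of the
implementation.
"""

import numpy as np
import pytest

from pec.realign import Scoring, realign_pair, smith_waterman
from conftest import make_pair

NEG = float("-inf")


def sw_oracle(q, t, match=2.0, mismatch=-2.0, gap_open=-3.0, gap_ext=-1.0):
    """O(nm) affine local alignment returning (score, qs, qe, ts, te, cigar)."""
    n, m = len(q), len(t)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] + gap_ext, H[i - 1][j] + gap_open + gap_ext)
            F[i][j] = max(F[i][j - 1] + gap_ext, H[i][j - 1] + gap_open + gap_ext)
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] != "N") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return 0.0, 0, 0, 0, 0, ""
    ops = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] != "N") else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                ops.append("M")
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("I")
            if E[i][j] == H[i - 1][j] + gap_open + gap_ext:
                state = "H"
            i -= 1
        else:
            ops.append("D")
            if F[i][j] == H[i][j - 1] + gap_open + gap_ext:
                state = "H"
            j -= 1
    cigar, run = "", 0
    prev = None
    for op in reversed(ops):
        if op == prev:
            run += 1
        else:
            if prev:
                cigar += f"{run}{prev}"
            prev, run = op, 1
    if prev:
        cigar += f"{run}{prev}"
    return best, i, bi, j, bj, cigar


def cigar_score(q, t, qs, ts, cigar, sc=Scoring()):
    """Recompute an alignment score from its CIGAR (consistency check)."""
    import re

    score, qi, tj = 0.0, qs, ts
    for n, op in re.findall(r"(\d+)([MID])", cigar):
        n = int(n)
        if op == "M":
            for _ in range(n):
                score += sc.match if q[qi] == t[tj] else sc.mismatch
                qi += 1
                tj += 1
        elif op == "I":
            score += sc.gap_open + n * sc.gap_extend
            qi += n
        else:
            score += sc.gap_open + n * sc.gap_extend
            tj += n
    return score


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestSmithWaterman:
    def test_exact_substring(self):
        q = "ACGTACGTAC"
        score, qs, qe, ts, te, cig = smith_waterman(q, "TT" + q + "GGG")
        assert score == 2 * len(q)
        assert (qs, qe) == (0, len(q))
        assert (ts, te) == (2, 2 + len(q))
        assert cig == f"{len(q)}M"

    def test_single_mismatch_in_30mer(self):
        rng = np.random.default_rng(0)
        t = random_dna(rng, 30)
        q = t[:15] + ("A" if t[15] != "A" else "C") + t[16:]
        score, *_ = smith_waterman(q, t)
        assert score == 29 * 2 - 2  # 56

    def test_single_deletion_matches_oracle(self):
        rng = np.random.default_rng(1)
        t = random_dna(rng, 40)
        q = t[:20] + t[21:]  # query lacks one target base -> 1D
        got = smith_waterman(q, t)
        exp = sw_oracle(q, t)
        assert got == exp
        assert "1D" in got[5]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")
        with pytest.raises(ValueError):
            smith_waterman("ACGT", "")

    def test_equivalence_with_dp_oracle_on_random_instances(self):
        """Scores and CIGARs identical to the oracle on 500 random
        (query, target) pairs with lengths <= 80, including mutated
        substrings and unrelated sequences."""
        rng = np.random.default_rng(2024)
        for trial in range(500):
            m = int(rng.integers(5, 81))
            t = random_dna(rng, m)
            if trial % 2 == 0:
                # mutated substring of the target
                n = int(rng.integers(5, m + 1))
                s = int(rng.integers(0, m - n + 1))
                q = list(t[s : s + n])
                for _ in range(int(rng.integers(0, 4))):
                    kind = rng.integers(0, 3)
                    pos = int(rng.integers(0, len(q)))
                    if kind == 0:
                        q[pos] = "ACGT"[rng.integers(0, 4)]
                    elif kind == 1 and len(q) > 2:
                        del q[pos]
                    else:
                        q.insert(pos, "ACGT"[rng.integers(0, 4)])
                q = "".join(q)
            else:
                q = random_dna(rng, int(rng.integers(5, 81)))
            got = smith_waterman(q, t)
            exp = sw_oracle(q, t)
            assert got == exp, f"trial {trial}: {got} != {exp} ({q} vs {t})"
            # CIGAR must reproduce the score
            score, qs, qe, ts, te, cig = got
            if cig:
                assert cigar_score(q, t, qs, ts, cig) == score

    def test_score_monotone_under_flank_extension(self):
        rng = np.random.default_rng(5)
        t = random_dna(rng, 60)
        q = t[10:40]
        base, *_ = smith_waterman(q, t)
        ext, *_ = smith_waterman(t[5:45], t)
        assert ext >= base


class TestRealignPair:
    class FakeRef:
        def __init__(self, seq, name="sim1"):
            self.seq, self.references = seq, [name]

        def fetch(self, contig, start, end):
            return self.seq[start:end]

        def get_reference_length(self, contig):
            return len(self.seq)

    def test_consensus_identical_to_reference(self):
        rng = np.random.default_rng(9)
        ref = random_dna(rng, 400)
        pair = make_pair(m1_seq=ref[100:130], m2_seq=ref[200:230],
                         m1_pos=100, m2_pos=200)
        out = realign_pair(pair, self.FakeRef(ref))
        assert (out.mate1_pos, out.mate1_cigar) == (100, "30M")
        assert (out.mate2_pos, out.mate2_cigar) == (200, "30M")
        assert out.mate1_seq == pair.mate1_seq

    def test_one_base_deletion_yields_1d(self):
        rng = np.random.default_rng(10)
        ref = random_dna(rng, 400)
        seq = ref[100:115] + ref[116:131]  # 30bp read lacking ref base 115
        pair = make_pair(m1_seq=seq, m2_seq=ref[200:230], m1_pos=100, m2_pos=200)
        out = realign_pair(pair, self.FakeRef(ref))
        assert out.mate1_cigar.count("D") == 1
        assert "1D" in out.mate1_cigar
        assert out.mate1_pos == 100

    def test_window_clipped_at_chromosome_start(self):
        rng = np.random.default_rng(11)
        ref = random_dna(rng, 300)
        pair = make_pair(m1_seq=ref[0:30], m2_seq=ref[100:130], m1_pos=0, m2_pos=100)
        out = realign_pair(pair, self.FakeRef(ref), window_margin=50)
        assert out.mate1_pos == 0

    def test_missing_contig_raises(self):
        with pytest.raises(KeyError):
            realign_pair(make_pair(chrom="chrX"), self.FakeRef("ACGT" * 100))
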
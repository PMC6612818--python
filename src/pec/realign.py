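"""Smith-Waterman local realignment of corrected reads.

After de-duplication the read set is small enough that every surviving
pair can be realigned optimally (affine-gap Smith-Waterman) against a
local reference window around its original mapping, regenerating position
and CIGAR.  The dynamic program is numba-compiled; traceback prefers
diagonal over up (insertion) over left (deletion) so CIGARs are fully
deterministic.

Scoring defaults: match +2, mismatch -2, gap open -3, gap extend -1, where
a length-g gap costs ``gap_open + g * gap_extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .bam_io import ReadPairRecord, cigar_reference_length

logger = logging.getLogger(__name__)

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = ["Scoring", "smith_waterman", "realign_pair", "realign_record"]

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class Scoring:
    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -3.0
    gap_extend: float = -1.0


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_CODE.get(c, 4) for c in seq.upper()), dtype=np.int8,
                       count=len(seq))


@njit(cache=True)
def _sw_matrices(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(q), len(t)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in target (consumes query; 'I')
    F = np.full((n + 1, m + 1), NEG)  # gap in query (consumes target; 'D')
    best = 0.0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            F[i, j] = max(F[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] != 4) else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    return H, E, F, best, bi, bj


def _traceback(H, E, F, q, t, bi, bj, sc: Scoring):
    """Deterministic traceback: diagonal > up (I) > left (D)."""
    ops: list[str] = []
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            s = sc.match if (q[i - 1] == t[j - 1] and q[i - 1] != 4) else sc.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                ops.append("M")
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("I")
            if E[i, j] == H[i - 1, j] + sc.gap_open + sc.gap_extend:
                state = "H"
            i -= 1
        else:
            ops.append("D")
            if F[i, j] == H[i, j - 1] + sc.gap_open + sc.gap_extend:
                state = "H"
            j -= 1
    ops.reverse()
    return i, j, ops


def _rle_cigar(ops: list[str]) -> str:
    parts = []
    for op in ops:
        if parts and parts[-1][0] == op:
            parts[-1][1] += 1
        else:
            parts.append([op, 1])
    return "".join(f"{n}{op}" for op, n in parts)


def smith_waterman(
    query: str, target: str, scoring: Scoring = Scoring()
) -> tuple[float, int, int, int, int, str]:
    """Optimal local alignment of ``query`` against ``target``.

    Returns ``(score, query_start, query_end, target_start, target_end,
    cigar)`` with half-open coordinate intervals and a CIGAR over the
    aligned core only (no clips; M/I/D operators).  The best-scoring cell
    with the smallest (query_end, target_end) is chosen, and traceback
    prefers diagonal > up > left, so the result is deterministic.
    """
    if not query or not target:
        raise ValueError("query and target must be nonempty")
    q, t = _encode(query), _encode(target)
    H, E, F, best, bi, bj = _sw_matrices(
        q, t, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, ""
    qs, ts, ops = _traceback(H, E, F, q, t, bi, bj, scoring)
    return float(best), qs, bi, ts, bj, _rle_cigar(ops)


def realign_pair(
    pair: ReadPairRecord,
    reference,
    window_margin: int = 50,
    scoring: Scoring = Scoring(),
    min_score_frac: float = 0.5,
) -> ReadPairRecord:
    """Realign both mates of a pair within windows around their original
    mappings; returns an updated copy.

    ``reference`` is a pysam.FastaFile (or anything with ``fetch(contig,
    start, end)`` and ``get_reference_length``).  Unaligned read flanks
    are soft-clipped.  If the alignment score falls below
    ``min_score_frac * match * read_length`` the original mapping is kept
    and the event logged.
    """
    new = replace(pair, tags=dict(pair.tags))
    if pair.chrom not in getattr(reference, "references", [pair.chrom]):
        raise KeyError(f"contig {pair.chrom!r} not in reference")
    chrom_len = reference.get_reference_length(pair.chrom)
    for mate in (1, 2):
        seq = pair.mate_seq(mate)
        pos = pair.mate_pos(mate)
        ref_len = cigar_reference_length(pair.mate_cigar(mate))
        w_start = max(0, pos - window_margin)
        w_end = min(chrom_len, pos + ref_len + window_margin)
        window = reference.fetch(pair.chrom, w_start, w_end).upper()
        # fast path: read matches the reference verbatim at its original spot
        off = pos - w_start
        if len(seq) <= len(window) - off and window[off : off + len(seq)] == seq:
            new_pos, new_cigar = pos, f"{len(seq)}M"
        else:
            score, qs, qe, ts, _te, core = smith_waterman(seq, window, scoring)
            if score < min_score_frac * scoring.match * len(seq) or not core:
                logger.info(
                    "realign: %s mate%d kept original alignment (score %.1f)",
                    pair.pair_name, mate, score,
                )
                continue
            cigar = ""
            if qs > 0:
                cigar += f"{qs}S"
            cigar += core
            if qe < len(seq):
                cigar += f"{len(seq) - qe}S"
            new_pos, new_cigar = w_start + ts, cigar
        if mate == 1:
            new.mate1_pos, new.mate1_cigar = new_pos, new_cigar
        else:
            new.mate2_pos, new.mate2_cigar = new_pos, new_cigar
    return new


# Backwards-friendly alias used by the pipeline
realign_record = realign_pair
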
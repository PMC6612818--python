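"""Partition read pairs into PCR-duplicate families.

Pairs whose unclipped 5' coordinates and orientation class coincide are
assumed to be PCR copies of one original cfDNA fragment (the collision
model in :mod:`pec.collision` quantifies how often that assumption fails).
The family size is the *duplicate depth* — distinct from sequencing depth
(reads over a locus) and read depth after de-duplication.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

from .bam_io import DuplicateKey, ReadPairRecord

__all__ = ["DuplicateSet", "group_pairs", "split_by_depth"]


@dataclass
class DuplicateSet:
    """All read pairs sharing one duplicate key."""

    key: DuplicateKey
    members: list[ReadPairRecord]

    @property
    def duplicate_depth(self) -> int:
        return len(self.members)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("DuplicateSet must have at least one member")
        for m in self.members:
            if m.duplicate_key() != self.key:
                raise ValueError(
                    f"member {m.pair_name} key {m.duplicate_key()} != {self.key}"
                )


def group_pairs(pairs: Iterable[ReadPairRecord]) -> list[DuplicateSet]:
    """Group pairs by duplicate key.

    The result is a partition: every input pair lands in exactly one family
    and the sum of duplicate depths equals the input count.  Members are
    sorted by pair name and families by key, so the output is invariant
    under shuffling of the input.
    """
    by_key: dict[DuplicateKey, list[ReadPairRecord]] = defaultdict(list)
    n = 0
    for pair in pairs:
        by_key[pair.duplicate_key()].append(pair)
        n += 1
    families = []
    for key in sorted(by_key):
        members = sorted(by_key[key], key=lambda r: r.pair_name)
        families.append(DuplicateSet(key=key, members=members))
    assert sum(f.duplicate_depth for f in families) == n
    return families


def split_by_depth(
    families: list[DuplicateSet], threshold: int = 5
) -> tuple[list[DuplicateSet], list[DuplicateSet]]:
    """Split families into (depth >= threshold, depth < threshold).

    High-depth families get a consensus; the rest are routed to
    representative selection + intrinsic polishing.  A consensus over fewer
    than two reads is undefined, hence threshold >= 2.
    """
    if threshold < 2:
        raise ValueError(f"threshold must be >= 2, got {threshold}")
    high = [f for f in families if f.duplicate_depth >= threshold]
    low = [f for f in families if f.duplicate_depth < threshold]
    return high, low


def depth_histogram(families: list[DuplicateSet]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for f in families:
        hist[f.duplicate_depth] = hist.get(f.duplicate_depth, 0) + 1
    return dict(sorted(hist.items()))
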
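"""Birthday-model probability of cfDNA fragment collisions.

Barcode-free duplicate grouping assumes that two *distinct* original cfDNA
fragments essentially never share identical start and end coordinates, so
that reads with the same unclipped 5' ends can be treated as PCR copies of
one molecule.  This module quantifies that assumption.

Model
-----
Fragments of a fixed length ``L`` overlapping a locus can start at ``L``
equally likely positions; if ``M_L`` such fragments are present, the chance
that at least two share a start (hence start *and* end) is the classic
birthday-problem probability

    C_L = 1 - L! / ((L - M_L)! * L**M_L).

Fragment lengths vary, and fragments of different lengths cannot collide,
so ``M_L`` is modelled from the fold-coverage depth ``D`` and a normal
fragment-length distribution:  ``M_L = D * N(L | mu, sigma)``.  The overall
per-locus collision probability is the length-weighted average

    p = sum_L C_L * N(L | mu, sigma)

over integer lengths.  For typical cfDNA libraries (mu = 177 bp,
sigma = 20 bp) and a cfDNA depth of 300x this gives p ~ 0.05; beyond ~500x
collisions become frequent enough that barcode-free grouping is unsafe.

``M_L`` is real-valued, so the falling factorial is evaluated through the
log-gamma continuous extension, keeping ``p`` smooth in ``D`` and ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

__all__ = [
    "collision_fixed_length",
    "expected_count",
    "collision_probability",
    "depth_threshold_scan",
    "CollisionModel",
]


def collision_fixed_length(M_L: float, L: int) -> float:
    """Probability that >=2 of ``M_L`` fragments of length ``L`` collide.

    Parameters
    ----------
    M_L
        Expected number of fragments of length ``L`` at the locus.  May be
        real-valued; the falling factorial is continued via log-gamma.
    L
        Fragment length in bp (the number of distinct placements).

    Returns
    -------
    float
        ``C_L`` in [0, 1].  ``M_L <= 1`` yields 0 (a lone fragment cannot
        collide); ``M_L >= L`` yields 1 (pigeonhole).
    """
    if M_L < 0:
        raise ValueError(f"M_L must be >= 0, got {M_L}")
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if M_L <= 1.0:
        return 0.0
    if M_L >= L:
        return 1.0
    log_no_collision = gammaln(L + 1) - gammaln(L - M_L + 1) - M_L * np.log(L)
    return float(np.clip(1.0 - np.exp(log_no_collision), 0.0, 1.0))


def expected_count(D: float, mu: float, sigma: float, L: int | np.ndarray):
    """Expected number of length-``L`` fragments at a locus, D * N(L|mu,sigma)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if D < 0:
        raise ValueError(f"D must be >= 0, got {D}")
    return D * norm.pdf(L, loc=mu, scale=sigma)


def _length_grid(mu: float, sigma: float) -> np.ndarray:
    # +/- 6 sigma captures all but <1e-9 of the normal mass
    lo = max(1, int(np.floor(mu - 6.0 * sigma)))
    hi = int(np.ceil(mu + 6.0 * sigma))
    return np.arange(lo, hi + 1)


def collision_probability(D: float, mu: float, sigma: float) -> float:
    """Overall per-locus collision probability ``p`` (length-weighted C_L).

    Sums ``C_L * N(L|mu,sigma)`` over integer ``L`` within mu +/- 6 sigma.
    """
    lengths = _length_grid(mu, sigma)
    weights = norm.pdf(lengths, loc=mu, scale=sigma)
    counts = D * weights
    p = sum(
        collision_fixed_length(m, int(L)) * w
        for m, L, w in zip(counts, lengths, weights)
    )
    return float(np.clip(p, 0.0, 1.0))


def depth_threshold_scan(
    mu: float, sigma: float, depths: "list[float]"
) -> "list[tuple[float, float]]":
    """Collision probability ``p`` for each cfDNA depth in ``depths``.

    Useful for checking at what depth barcode-free grouping stops being
    safe for a given fragment-length distribution.
    """
    if len(depths) == 0:
        raise ValueError("depths must be nonempty")
    return [(D, collision_probability(D, mu, sigma)) for D in depths]


@dataclass
class CollisionModel:
    """Bundle of collision-model parameters and derived quantities.

    Attributes
    ----------
    D : float
        cfDNA depth (fold-coverage of original molecules, not reads).
    mu, sigma : float
        Mean and SD of the fragment-length normal distribution, bp.
    """

    D: float
    mu: float = 177.0
    sigma: float = 20.0
    p: float = field(init=False)

    def __post_init__(self) -> None:
        self.p = collision_probability(self.D, self.mu, self.sigma)

    def M(self, L: int) -> float:
        """Expected fragment count of length ``L`` at a locus."""
        return float(expected_count(self.D, self.mu, self.sigma, L))

    def C(self, L: int) -> float:
        """Fixed-length collision probability at length ``L``."""
        return collision_fixed_length(self.M(L), L)


def simulate_collision_probability(
    D: float,
    mu: float,
    sigma: float,
    n_loci: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo fragment-placement estimate of ``p`` with its SE.

    Per locus: draw a fragment length ``L`` from the (integer-discretized)
    normal, realize the fragment count as ``floor(M_L) + Bernoulli(frac)``
    so its mean is ``M_L``, place the fragments uniformly over the ``L``
    possible start positions and record whether any two landed together.
    Returns the collision frequency and its binomial standard error.
    """
    if rng is None:
        rng = np.random.default_rng()
    lengths = np.maximum(1, np.rint(rng.normal(mu, sigma, size=n_loci)).astype(int))
    m = expected_count(D, mu, sigma, lengths)
    counts = np.floor(m).astype(int) + (rng.random(n_loci) < (m - np.floor(m)))
    collided = 0
    for n in sorted(np.unique(counts)):
        if n < 2:
            continue
        Ls = lengths[counts == n]
        starts = np.floor(rng.random((len(Ls), n)) * Ls[:, None]).astype(np.int64)
        starts.sort(axis=1)
        collided += int((np.diff(starts, axis=1) == 0).any(axis=1).sum())
    phat = collided / n_loci
    se = float(np.sqrt(max(phat * (1 - phat), 1e-12) / n_loci))
    return phat, se
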
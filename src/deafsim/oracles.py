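"""Closed-form population-genetics expectations.

These are deterministic, infinite-population references against which the
stochastic agent-based simulator is validated: the classic recursion for a
fully selected-against ("lethal", fitness-zero) recessive allele, the
Hardy-Weinberg homozygote proportion, and the random-mating probability that
both spouses are recessive homozygotes.  Exported publicly — they are just as
useful for users sanity-checking custom scenarios.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "lethal_recessive_freq",
    "lethal_recessive_trajectory",
    "hwe_homozygote",
    "deaf_pair_probability_random",
]


def lethal_recessive_freq(q0: float, t: int) -> float:
    """Allele frequency after ``t`` generations of zero homozygote fitness.

    Iterates q <- q / (1 + q), equivalent to the closed form
    q_t = q0 / (1 + t * q0).
    """
    if not 0.0 <= q0 <= 1.0:
        raise ValueError("q0 must be in [0, 1]")
    if t < 0:
        raise ValueError("t must be >= 0")
    q = q0
    for _ in range(int(t)):
        q = q / (1.0 + q)
    return q


def lethal_recessive_trajectory(q0: float, t: int) -> np.ndarray:
    """Frequencies q_0..q_t under zero homozygote fitness (length t + 1)."""
    return np.array([lethal_recessive_freq(q0, k) for k in range(int(t) + 1)])


def hwe_homozygote(q: float) -> float:
    """Hardy-Weinberg recessive homozygote proportion, q**2."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return q * q


def deaf_pair_probability_random(hom_prop: float) -> float:
    """Probability that a random couple is homozygote x homozygote."""
    if not 0.0 <= hom_prop <= 1.0:
        raise ValueError("hom_prop must be in [0, 1]")
    return hom_prop * hom_prop
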
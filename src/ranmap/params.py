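"""Derivation of the aligner's governing parameters t, W and A.

The number of differences d between a read of length m and its true genome
locus is modelled as Binomial(m, b), where b folds together the per-base
sequencing-error and polymorphism rates (mean mb, variance mb(1-b)). The
distance budget is the mean plus c_sigma standard deviations,

    t = ceil( m*b + c_sigma * sqrt(m*b*(1-b)) ),

rounded up so the budget is conservative. The d differences cut the read
into d+1 error-free blocks; a uniformly random anchor position lands in a
block of expected length at least m/(d+1), so the minimum seed length is

    W = floor( m / max(t, 1) ),   at least 1,

rounded down so the seed filter stays permissive. Since the longest block
is hit by a random anchor within d+1 draws in expectation, the attempt
budget is A = a_multiplier * (t + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class AlignerParams:
    """Derived alignment parameters plus runtime caps."""

    b: float                # per-base error + polymorphism probability
    c_sigma: float          # std-dev multiplier in the t bound
    t: int                  # edit-distance budget
    W: int                  # minimum common-substring (seed) length
    A: int                  # maximum anchor attempts per read
    a_multiplier: int = 1
    max_hits: int = 100     # occurrence cap per search direction
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 0 or self.W < 1 or self.A < 1:
            raise ValueError(f"invalid parameters t={self.t} W={self.W} A={self.A}")


def derive_parameters(
    m: int,
    b: float,
    c_sigma: float = 4.0,
    a_multiplier: int = 1,
    max_hits: int = 100,
    rng_seed: int = 0,
    t_override: int | None = None,
    w_override: int | None = None,
    a_override: int | None = None,
) -> AlignerParams:
    """Derive (t, W, A) from read length m and error rate b.

    Explicit overrides bypass the corresponding derivation.
    """
    if m < 1:
        raise ValueError(f"read length m={m} must be >= 1")
    if not (0.0 <= b < 1.0):
        raise ValueError(f"error rate b={b} must be in [0, 1)")
    if c_sigma <= 0:
        raise ValueError(f"c_sigma={c_sigma} must be positive")
    if t_override is not None:
        t = t_override
    else:
        mu = m * b
        sigma = math.sqrt(m * b * (1.0 - b))
        t = math.ceil(mu + c_sigma * sigma)
    W = w_override if w_override is not None else max(1, m // max(t, 1))
    A = a_override if a_override is not None else a_multiplier * (t + 1)
    return AlignerParams(
        b=b,
        c_sigma=c_sigma,
        t=t,
        W=W,
        A=A,
        a_multiplier=a_multiplier,
        max_hits=max_hits,
        rng_seed=rng_seed,
    )
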
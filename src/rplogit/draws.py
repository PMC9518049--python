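"""Halton quasi-random draws for the simulated likelihood.

The Halton sequence in prime base b is the radical-inverse sequence: the
integer index written in base b with its digits mirrored about the radix
point.  Consecutive elements fill (0,1) far more evenly than pseudo-random
numbers, so averaging the mixing integral over D Halton points converges
much faster than Monte Carlo at the same D.

Draw allocation follows the usual cross-sectional convention: one long
(skipped) sequence per random term, cut into contiguous non-overlapping
blocks of D elements per record, then mapped to standard normals through
the inverse normal CDF.  Everything is a pure function of its configuration
— no RNG state — so draw sets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

DEFAULT_N_DRAWS = 1000
DEFAULT_SKIP = 10


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n % 2 == 0:
        return n == 2
    f = 3
    while f * f <= n:
        if n % f == 0:
            return False
        f += 2
    return True


def _primes(count: int) -> list[int]:
    out, n = [], 2
    while len(out) < count:
        if _is_prime(n):
            out.append(n)
        n += 1
    return out


def halton_sequence(base: int, count: int, skip: int = 0) -> np.ndarray:
    """Elements skip+1 .. skip+count of the radical-inverse sequence in `base`.

    The index-0 element (which is exactly 0) is never produced, so every
    value lies strictly in (0, 1).
    """
    if not _is_prime(base):
        raise ValueError(f"Halton base must be prime, got {base}")
    if count < 1:
        raise ValueError("count must be >= 1")
    if skip < 0:
        raise ValueError("skip must be >= 0")
    idx = np.arange(skip + 1, skip + count + 1, dtype=np.int64)
    out = np.zeros(count)
    denom = 1.0
    while idx.any():
        denom *= base
        out += (idx % base) / denom
        idx //= base
    return out


def _scramble_digits(base: int, count: int, skip: int, seed: int) -> np.ndarray:
    """Deterministic digit-permutation scramble (one random permutation per base).

    Useful for high-dimensional specs where large-prime Halton sequences are
    strongly correlated in their early digits.
    """
    rng = np.random.RandomState(seed % (2**31))
    perm = rng.permutation(base)
    # keep digit 0 -> 0 so trailing zeros stay zero
    perm = np.concatenate(([0], perm[perm != 0]))
    idx = np.arange(skip + 1, skip + count + 1, dtype=np.int64)
    out = np.zeros(count)
    denom = 1.0
    while idx.any():
        denom *= base
        out += perm[idx % base] / denom
        idx //= base
    # digit-0 fixing can yield exact zeros for indices that are powers of base
    out[out == 0.0] = 0.5 / denom
    return out


@dataclass
class DrawSet:
    """Standard-normal quasi-random deviates, indexed (record, term, draw)."""

    draws: np.ndarray                # (n_records, n_terms, n_draws)
    n_draws: int
    primes: dict[str, int]           # random-term variable -> prime base
    skip: int
    scramble: bool = False

    @property
    def n_records(self) -> int:
        return self.draws.shape[0]

    def for_term(self, k: int) -> np.ndarray:
        """The (n_records, n_draws) block of term k."""
        return self.draws[:, k, :]


def make_draws(
    n_records: int,
    random_terms: list[str],
    n_draws: int = DEFAULT_N_DRAWS,
    skip: int = DEFAULT_SKIP,
    scramble: bool = False,
    scramble_seed: int = 0,
) -> DrawSet:
    """Build the normal draw array for a model's random terms.

    Each random term gets its own prime base (2, 3, 5, ... in term order,
    extended automatically; a prime is never reused).  Record n's block is
    sequence elements skip + n*D + 1 .. skip + (n+1)*D.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    bases = _primes(len(random_terms))
    draws = np.empty((n_records, len(random_terms), n_draws))
    for k, base in enumerate(bases):
        if scramble:
            seq = _scramble_digits(base, n_records * n_draws, skip, scramble_seed + k)
        else:
            seq = halton_sequence(base, n_records * n_draws, skip)
        draws[:, k, :] = ndtri(seq).reshape(n_records, n_draws)
    return DrawSet(
        draws=draws,
        n_draws=n_draws,
        primes=dict(zip(random_terms, bases)),
        skip=skip,
        scramble=scramble,
    )
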
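"""Counter-seeded xoroshiro128+ random streams.

Every photon owns an independent stream derived from ``(global_seed,
photon_index)`` through a splitmix64 scrambler, so a photon's entire
trajectory — launch sampling included — is a pure function of those two
integers.  That is what makes detected-photon replay and split/merge
execution across workers exactly reproducible: worker boundaries do not
change any photon's stream.

The state lives in a 2-element ``uint64`` array so the generator can be
used from numba-compiled kernels and from Python through
:class:`PhotonRNG` with identical output.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["PhotonRNG", "make_state", "rand_uniform", "rand_open"]

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = x + _GOLDEN
    z = x
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    return x, z ^ (z >> _U64(31))


@njit(cache=True)
def seed_state(state, seed, index):
    """Initialize *state* (uint64[2]) for photon *index* under *seed*."""
    x = _U64(seed) * _MIX1 + _U64(index) * _GOLDEN + _U64(1)
    x, s0 = _splitmix64(x)
    x, s1 = _splitmix64(x)
    if s0 == _U64(0) and s1 == _U64(0):
        s1 = _GOLDEN
    state[0] = s0
    state[1] = s1


@njit(cache=True, inline="always")
def _rotl(x, k):
    return (x << _U64(k)) | (x >> _U64(64 - k))


@njit(cache=True, inline="always")
def next_u64(state):
    s0 = state[0]
    s1 = state[1]
    result = s0 + s1
    s1 ^= s0
    state[0] = _rotl(s0, 55) ^ s1 ^ (s1 << _U64(14))
    state[1] = _rotl(s1, 36)
    return result


@njit(cache=True, inline="always")
def rand_uniform(state):
    """Uniform double in (0, 1] — safe as the argument of log()."""
    return (float(next_u64(state) >> _U64(11)) + 1.0) * (2.0 ** -53)


@njit(cache=True, inline="always")
def rand_open(state):
    """Uniform double in [0, 1)."""
    return float(next_u64(state) >> _U64(11)) * (2.0 ** -53)


def make_state(seed: int, index: int = 0) -> np.ndarray:
    state = np.empty(2, dtype=np.uint64)
    seed_state(state, seed, index)
    return state


class PhotonRNG:
    """Python-side view of one photon stream (shares code with the kernel)."""

    def __init__(self, seed: int, index: int = 0):
        self.state = make_state(seed, index)

    def uniform(self) -> float:
        """Draw from (0, 1]."""
        return rand_uniform(self.state)

    def uniform_open(self) -> float:
        """Draw from [0, 1)."""
        return rand_open(self.state)
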
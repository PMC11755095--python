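"""Deterministic hierarchical seed derivation.

Every stochastic task in a run (a replicate, a genome, a contig, the final
shuffle) draws from a generator derived from the master seed plus a stable
scope key, so per-contig simulation is reproducible regardless of execution
order or thread scheduling.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31


def stable_key(token: str | int) -> int:
    """Map a scope token (string id or integer) to a stable 31-bit integer."""
    if isinstance(token, (int, np.integer)):
        return int(token) % _MOD
    digest = hashlib.sha256(str(token).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % _MOD


def _seed_sequence(master: int, scope: tuple) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        int(master) % _MOD, spawn_key=tuple(stable_key(t) for t in scope)
    )


def child_seed(master: int, *scope: str | int) -> int:
    """A 31-bit child seed for the given scope, stable across platforms."""
    return int(_seed_sequence(master, scope).generate_state(1, np.uint32)[0]) % _MOD


def rng_for(master: int, *scope: str | int) -> np.random.Generator:
    """Generator seeded for the given scope (independent across scopes)."""
    return np.random.default_rng(_seed_sequence(master, scope))
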
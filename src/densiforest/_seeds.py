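"""Deterministic seed splitting.

All randomness in the package flows from one integer seed. Independent
streams for sub-tasks are derived with :class:`numpy.random.SeedSequence`
spawn keys (a counter-based splitting rule), so any stage can be regenerated
in isolation without consuming another stage's stream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["split_rng", "split_seed"]

# stable stage labels -> spawn-key integers
_STAGE_KEYS = {
    "phylogeny": 1,
    "traits": 2,
    "landscape": 3,
    "plots": 4,
    "records": 5,
    "ensemble": 6,
    "drivers": 7,
    "misc": 8,
}


def _key_of(token: int | str) -> int:
    if isinstance(token, str):
        try:
            return _STAGE_KEYS[token]
        except KeyError:
            # stable fallback for ad-hoc labels
            return sum(token.encode()) % (2**16)
    return int(token)


def split_rng(seed: int, *tokens: int | str) -> np.random.Generator:
    """Return a Generator on an independent stream keyed by ``tokens``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key_of(t) for t in tokens))
    return np.random.Generator(np.random.PCG64(ss))


def split_seed(seed: int, *tokens: int | str) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key_of(t) for t in tokens))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
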
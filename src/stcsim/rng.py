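"""Named, independent RNG streams derived from one root seed.

Each feature of the simulation (assembly, invaders, mutants, ...) draws from
its own stream so that toggling one feature does not shift the draws of
another.  Streams are identified by a fixed name -> index table; adding new
names at the end preserves all existing streams.
"""

from __future__ import annotations

import numpy as np

# Fixed registry: never reorder, only append.
_STREAMS = {
    "assembly": 0,
    "invaders": 1,
    "mutants": 2,
    "fitness": 3,
    "init": 4,
    "theory": 5,
    "scratch": 6,
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named generator for a root seed (deterministic)."""
    try:
        idx = _STREAMS[name]
    except KeyError:
        raise KeyError(
            f"unknown RNG stream {name!r}; known: {sorted(_STREAMS)}"
        ) from None
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
    return np.random.Generator(np.random.PCG64(ss))


def streams(seed: int) -> dict:
    """All named generators for a root seed."""
    return {name: stream(seed, name) for name in _STREAMS}
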
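"""Named random-number substreams derived from one master seed.

A single master seed spawns independent, named streams (connectivity,
background, target selection, initial conditions, weight randomization) so
that whole runs are bit-identical under one seed while any one source of
randomness can be varied in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

#: Reserved stream names used across the package.
CONNECTIVITY = "connectivity"
BACKGROUND = "background"
TARGETS = "targets"
INIT = "init"
WEIGHTS = "weights"


def stream_key(name: str) -> int:
    """Stable 31-bit integer key for a stream name."""
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def substream(master_seed: int, name: str, *extra: int) -> np.random.Generator:
    """Generator for the named substream of *master_seed*.

    ``extra`` integers (e.g. a per-epoch tag) further split the stream.
    """
    key = (stream_key(name),) + tuple(int(e) & 0x7FFFFFFF for e in extra)
    return np.random.default_rng(
        np.random.SeedSequence(int(master_seed), spawn_key=key)
    )
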
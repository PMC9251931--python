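"""Portable counter-based random streams.

Every stochastic draw in the simulator comes from a Philox generator whose
128-bit key is a BLAKE2 hash of a structured key (seed plus string context
parts). Streams are therefore independent, order-free and replayable: a test
oracle can reconstruct exactly the draws a particular transcript or sample
received without running the simulator.
"""

from __future__ import annotations

import hashlib

import numpy as np

_SEP = b"\x1f"


def stream_key(seed: int, *parts: object) -> int:
    """128-bit Philox key derived from (seed, *parts)."""
    h = hashlib.blake2b(digest_size=16)
    h.update(str(int(seed)).encode())
    for p in parts:
        h.update(_SEP)
        h.update(str(p).encode())
    return int.from_bytes(h.digest(), "little")


def substream(seed: int, *parts: object) -> np.random.Generator:
    """Independent Generator for the context named by ``parts``."""
    return np.random.Generator(np.random.Philox(key=stream_key(seed, *parts)))
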
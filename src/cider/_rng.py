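"""Deterministic random-stream derivation.

One user-facing seed per run; every stage derives its own independent
generator from (seed, fixed string label, optional indices), so adding a
stage or reordering calls never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng"]


def spawn_rng(seed: int, *labels) -> np.random.Generator:
    """A generator keyed by ``seed`` and a sequence of stage labels.

    String labels are hashed (CRC-32); integer labels pass through.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            entropy.append(zlib.crc32(lab.encode()))
        else:
            entropy.append(int(lab) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))
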
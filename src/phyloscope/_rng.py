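"""Labeled random substreams.

Every stochastic operation derives its generator from the master seed plus a
stable string label, so adding or reordering pipeline stages never perturbs
the random draws of other stages.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for ``label`` derived deterministically from ``seed``."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
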
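"""Named, independent random substreams derived from one master seed.

Every stochastic artifact in the pipeline (labels, noise, clouds, sample
points, the classifier) draws from its own stream keyed by a stable name, so
adding a new draw somewhere never perturbs existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_int(key: object) -> int:
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for stream ``keys`` under master ``seed``.

    Streams with different key tuples are statistically independent; the same
    (seed, keys) pair always yields the identical stream.
    """
    entropy = [int(seed)] + [_key_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
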
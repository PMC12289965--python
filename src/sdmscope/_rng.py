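"""Named, reproducible random substreams.

All stochastic code in the package derives its generator from a single
integer seed plus a tuple of names, so that modules are independently
reproducible and replays are bit-identical.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a path of names.

    Different name paths give statistically independent streams; the same
    (seed, names) pair always returns an identically-seeded generator.
    """
    tag = "/".join(str(n) for n in names)
    digest = hashlib.sha256(tag.encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    ss = np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *words])
    return np.random.default_rng(ss)
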
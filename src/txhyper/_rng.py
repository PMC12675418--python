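"""Stage-keyed random substreams.

All stochastic stages derive an independent generator from one global integer
seed plus a stage name, so that any stage can be re-run in isolation and
reproduce its draws exactly.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for *stage* derived deterministically from *seed*."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
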
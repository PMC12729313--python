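"""Deterministic per-stage seed derivation.

Every stochastic stage draws its seed from the global seed plus a stable
hash of its stage name, so inserting a new stage never reshuffles the
randomness of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable 31-bit seed for a named pipeline stage."""
    return int(np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
               .generate_state(1)[0] % (2 ** 31))


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))
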
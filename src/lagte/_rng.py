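"""Named random substreams derived from one global seed.

Every stochastic component (simulation, embedding shuffles, surrogate
shifts, tie-break jitter) draws from its own named child stream, so adding
replicates or toggling one component never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names) -> np.random.Generator:
    """Generator for the child stream identified by ``names``.

    The spawn key is derived from stable CRC32 hashes of the name parts,
    kept below 2**31.
    """
    key = tuple(zlib.crc32(str(n).encode()) % (2 ** 31) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
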
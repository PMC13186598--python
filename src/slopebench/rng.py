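"""Seed-substream policy shared by all simulation drivers.

One master seed parameterizes an experiment; every condition (grid point,
population, bootstrap block) gets an independent PRNG substream keyed by
``SeedSequence([master, experiment_tag, *condition_key])``, where the
condition key encodes the condition's own parameters (not its position in
a grid).  Consequences:

* results for a condition do not depend on grid order or grid size;
* re-running with more iterations leaves earlier iterations unchanged,
  because each condition draws its arrays in C order from one stream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream", "child_seed", "key_from_float"]


def _nonneg(parts: tuple[int, ...]) -> list[int]:
    out = []
    for p in parts:
        q = int(p)
        if q < 0:
            raise ValueError(f"substream key parts must be non-negative, got {q}")
        out.append(q)
    return out


def substream(master_seed: int, *key: int) -> np.random.Generator:
    """Independent Generator for the condition identified by ``key``."""
    return np.random.default_rng(np.random.SeedSequence(_nonneg((master_seed, *key))))


def child_seed(master_seed: int, *key: int) -> int:
    """Derived integer seed (< 2**31) for APIs that take a plain seed."""
    ss = np.random.SeedSequence(_nonneg((master_seed, *key)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


def key_from_float(value: float, scale: int = 1000, offset: int = 10_000) -> int:
    """Map a bounded float parameter (e.g. a correlation or noise SD) to a
    non-negative integer key, at ``1/scale`` resolution."""
    return int(round(value * scale)) + offset
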
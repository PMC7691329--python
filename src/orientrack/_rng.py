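"""Reproducible random number generation.

All stochastic operations in the package take an explicit integer seed and
build their generator here. The bit generator is Philox, a counter-based
generator whose streams are identical across platforms and word sizes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_from_seed", "spawn"]


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Philox-backed Generator for ``seed``.

    Passing an existing Generator returns it unchanged so functions can be
    composed without re-seeding; ``None`` draws entropy from the OS.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.Philox(seed))


def spawn(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    """Split ``rng`` into ``n`` independent child generators."""
    return [np.random.Generator(bg) for bg in rng.bit_generator.spawn(n)]
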
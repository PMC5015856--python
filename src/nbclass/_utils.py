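"""Seed derivation and logging helpers.

All randomness in the package flows from one integer seed. Child seeds for
independent components (repeats, folds, per-node searches) are derived with
``numpy.random.SeedSequence`` so streams never collide, and are folded back
into the 31-bit range accepted by scikit-learn's ``random_state``.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("nbclass")


def child_seed(seed: int, *keys: int) -> int:
    """Derive a deterministic 31-bit child seed from ``seed`` and stream keys."""
    ss = np.random.SeedSequence([int(seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))
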
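"""Small shared helpers: Hamming distance, random DNA, seeded RNG plumbing."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generators deterministically derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]
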
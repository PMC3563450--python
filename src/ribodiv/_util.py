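"""Small shared helpers: rounding, sequence utilities, RNG plumbing."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (0.85 -> 0.9, 1.25 -> 1.3).

    Uses the shortest decimal repr of ``x`` so that quotients printed as
    e.g. 0.85 round on their decimal value, not their binary neighbour.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random nucleotide string with expected GC content ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=length, p=p))


def homopolymer_runs(seq: str) -> list[tuple[int, int, str]]:
    """Maximal runs of identical bases as (start0, length, base)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append((i, j - i, seq[i]))
        i = j
    return runs


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
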
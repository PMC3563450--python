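"""Platform-specific read simulation with known ground truth.

Three error regimes are modelled after the sequencing chemistries used for
rDNA amplicon work:

* 454 pyrosequencing — 350-450 bp reads with indel errors concentrated in
  homopolymeric tracts (per-run indel probability growing with run length)
  plus a low substitution rate;
* Illumina — short fixed-length reads with substitution-dominated errors;
* Sanger — full-length, near-error-free clone sequences.

No published per-base error rates exist for the amplicon datasets this
emulates; the defaults below are adjustable parameters, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import BASES, as_rng, homopolymer_runs, reverse_complement
from .amplicon import RibotypePanel

ORIGINS = ("five_prime", "three_prime", "both", "uniform")


@dataclass(frozen=True)
class PlatformErrorModel:
    """Error and read-length model for one sequencing platform.

    ``homopolymer_indel_p`` scales the per-run indel probability
    p·(k−1) for a homopolymer of length k, so single bases never gain
    indel errors and long runs are increasingly error-prone.
    ``read_length`` is either a fixed int or an inclusive (lo, hi) range
    sampled uniformly; None means full-length reads.
    """

    name: str
    sub_rate: float
    homopolymer_indel_p: float = 0.0
    read_length: int | tuple[int, int] | None = None
    paired: bool = False
    origin: str = "both"

    def __post_init__(self):
        if not 0 <= self.sub_rate <= 1:
            raise ValueError("sub_rate must be in [0,1]")
        if not 0 <= self.homopolymer_indel_p <= 1:
            raise ValueError("homopolymer_indel_p must be in [0,1]")
        if self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}")
        if self.name == "sanger" and (self.sub_rate > 1e-4 or self.homopolymer_indel_p > 0):
            raise ValueError("sanger model must have sub_rate <= 1e-4 and no indels")

    def indel_rate(self, run_length: int) -> float:
        """Per-run indel probability for a homopolymer of ``run_length``."""
        return min(1.0, self.homopolymer_indel_p * max(0, run_length - 1))

    def sample_length(self, rng: np.random.Generator, full: int) -> int:
        if self.read_length is None:
            return full
        if isinstance(self.read_length, int):
            return min(self.read_length, full)
        lo, hi = self.read_length
        return min(int(rng.integers(lo, hi + 1)), full)


def model_454(**overrides) -> PlatformErrorModel:
    """454-like: 350-450 bp reads, homopolymer-biased indels."""
    params = dict(
        name="454",
        sub_rate=0.0005,
        homopolymer_indel_p=0.005,
        read_length=(350, 450),
        origin="both",
    )
    params.update(overrides)
    return PlatformErrorModel(**params)


def model_illumina(**overrides) -> PlatformErrorModel:
    """Illumina-like: short reads, substitution-dominated errors."""
    params = dict(
        name="illumina",
        sub_rate=0.003,
        homopolymer_indel_p=0.0002,
        read_length=100,
        origin="uniform",
    )
    params.update(overrides)
    return PlatformErrorModel(**params)


def model_sanger(**overrides) -> PlatformErrorModel:
    """Sanger-like: full-length clones, near-error-free."""
    params = dict(name="sanger", sub_rate=1e-5, read_length=None, origin="five_prime")
    params.update(overrides)
    return PlatformErrorModel(**params)


def corrupt_sequence(seq: str, model: PlatformErrorModel, rng: np.random.Generator) -> str:
    """Apply platform errors to one read template."""
    chars = np.array(list(seq))
    if model.sub_rate > 0:
        hits = np.flatnonzero(rng.random(len(chars)) < model.sub_rate)
        for i in hits:
            chars[i] = rng.choice([b for b in BASES if b != chars[i]])
    out = "".join(chars)
    if model.homopolymer_indel_p > 0:
        edits = []  # (run_start0, run_len, insert?)
        for start, length, _ in homopolymer_runs(out):
            if rng.random() < model.indel_rate(length):
                edits.append((start, length, rng.random() < 0.5))
        for start, length, insert in reversed(edits):
            if insert:
                out = out[:start] + out[start] + out[start:]
            else:
                out = out[:start] + out[start + 1 :]
    return out


def simulate_reads(
    panel: RibotypePanel,
    model: PlatformErrorModel,
    n_reads: int,
    seed: int,
    origin: str | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw reads from a ribotype panel under a platform error model.

    Each read samples a source ribotype at its panel frequency, takes a
    platform-length window, and is then corrupted under the error model.
    Amplicon-style reads anchor at the 5' or 3' end (3'-end reads are
    reverse-complemented, as sequenced from the opposite primer); the
    ``uniform`` origin emulates genomic shotgun reads with uniformly
    placed windows on a random strand.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)``
    pairs and ``truth`` records the source ribotype and orientation of
    every read. Deterministic for a fixed seed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    origin = origin or model.origin
    if origin not in ORIGINS:
        raise ValueError(f"origin must be one of {ORIGINS}")
    rng = as_rng(seed)
    sources = rng.choice(len(panel.variants), size=n_reads, p=panel.frequencies)
    sequences = panel.sequences()
    ids = panel.ids
    reads, rows = [], []
    for i, src in enumerate(sources):
        full = sequences[src]
        length = model.sample_length(rng, len(full))
        if origin == "both":
            side = "five_prime" if rng.random() < 0.5 else "three_prime"
        else:
            side = origin
        if side == "five_prime":
            window = full[:length]
            strand = "+"
        elif side == "three_prime":
            window = reverse_complement(full[-length:])
            strand = "-"
        else:  # uniform: shotgun-style window on a random strand
            start = int(rng.integers(0, len(full) - length + 1))
            window = full[start : start + length]
            strand = "+"
            if rng.random() < 0.5:
                window = reverse_complement(window)
                strand = "-"
        read_id = f"read_{i:05d}"
        reads.append((read_id, corrupt_sequence(window, model, rng)))
        rows.append((read_id, ids[src], strand))
    truth = pd.DataFrame(rows, columns=["read_id", "ribotype_id", "strand"])
    return reads, truth


def simulate_clones(
    panel: RibotypePanel,
    n_clones: int,
    seed: int,
    model: PlatformErrorModel | None = None,
) -> list[tuple[str, str]]:
    """Sanger-style clone set: full-length near-error-free amplicons."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    model = model or model_sanger()
    reads, _ = simulate_reads(panel, model, n_clones, seed, origin="five_prime")
    return [(rid.replace("read", "clone"), seq) for rid, seq in reads]
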
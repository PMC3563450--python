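"""Reference amplicon templates and ribotype panels.

The study system is a ~650 bp rDNA amplicon spanning the 3' end of the 18S
gene (313 bp), the full ITS1 (240±2 bp) and part of the 5.8S gene. A
:class:`UnitTemplate` carries the sequence with those annotated spans; a
:class:`RibotypePanel` is a set of sequence variants (ribotypes) of the
template at known genomic frequencies, the ground truth for simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import BASES, as_rng, random_sequence
from .profiles import DEL, INS, SUB, Variant, VariantProfile, apply_profile

REGIONS = ("18S", "ITS1", "5.8S")

DEFAULT_LENGTHS = (313, 240, 97)  # 18S segment, ITS1, 5.8S segment


@dataclass(frozen=True)
class UnitTemplate:
    """Reference amplicon with 1-based closed-interval region spans.

    Coordinates are always on the coding strand; spans are ordered
    18S < ITS1 < 5.8S and jointly cover the sequence.
    """

    id: str
    sequence: str
    span_18S: tuple[int, int]
    span_ITS1: tuple[int, int]
    span_58S: tuple[int, int]
    strand: str = "coding"

    def __post_init__(self):
        spans = (self.span_18S, self.span_ITS1, self.span_58S)
        if self.span_18S[0] != 1 or self.span_58S[1] != len(self.sequence):
            raise ValueError("spans must jointly cover the sequence")
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if a > b or c != b + 1:
                raise ValueError("spans must be ordered, disjoint and contiguous")
        if set(self.sequence) - set(BASES):
            raise ValueError("template sequence must be over {A,C,G,T}")
        if self.strand not in ("coding", "noncoding"):
            raise ValueError("strand must be coding or noncoding")

    def __len__(self):
        return len(self.sequence)

    @property
    def spans(self) -> dict[str, tuple[int, int]]:
        return {"18S": self.span_18S, "ITS1": self.span_ITS1, "5.8S": self.span_58S}

    def region_of(self, position: int) -> str:
        for name, (a, b) in self.spans.items():
            if a <= position <= b:
                return name
        raise ValueError(f"position {position} outside template")

    def region_sequence(self, region: str) -> str:
        a, b = self.spans[region]
        return self.sequence[a - 1 : b]

    def region_start(self, region: str) -> int:
        return self.spans[region][0]


def build_reference(
    seed: int,
    gc: float = 0.5,
    lengths: tuple[int, int, int] = DEFAULT_LENGTHS,
    id: str = "amplicon_ref",
) -> UnitTemplate:
    """Random amplicon template with the standard 18S/ITS1/5.8S layout.

    Deterministic for a fixed seed. ``gc`` is the expected GC fraction of
    the generated sequence; region lengths default to 313/240/97 bp.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    if any(l <= 0 for l in lengths):
        raise ValueError("all region lengths must be positive")
    rng = as_rng(seed)
    l18, lits, l58 = lengths
    seq = random_sequence(rng, l18 + lits + l58, gc)
    return UnitTemplate(
        id=id,
        sequence=seq,
        span_18S=(1, l18),
        span_ITS1=(l18 + 1, l18 + lits),
        span_58S=(l18 + lits + 1, l18 + lits + l58),
    )


@dataclass(frozen=True)
class RibotypePanel:
    """Ribotypes of one template with genomic frequencies summing to 1."""

    template: UnitTemplate
    variants: tuple[tuple[VariantProfile, float], ...]

    def __post_init__(self):
        freqs = [f for _, f in self.variants]
        if not self.variants:
            raise ValueError("panel must contain at least one ribotype")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1 (got {sum(freqs)})")
        if any(f < 0 for f in freqs):
            raise ValueError("frequencies must be non-negative")
        profiles = [p for p, _ in self.variants]
        if len(set(profiles)) != len(profiles):
            raise ValueError("ribotype profiles must be pairwise distinct")
        n = len(self.template)
        for p in profiles:
            for v in p:
                if not (0 <= v.position <= n):
                    raise ValueError(f"variant position {v.position} outside template")

    @property
    def profiles(self) -> list[VariantProfile]:
        return [p for p, _ in self.variants]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, f in self.variants])

    @property
    def ids(self) -> list[str]:
        return [f"RT{i}" for i in range(len(self.variants))]

    def sequence_of(self, index: int) -> str:
        return apply_profile(self.template.sequence, self.variants[index][0])

    def sequences(self) -> list[str]:
        return [self.sequence_of(i) for i in range(len(self.variants))]


def derive_ribotypes(
    template: UnitTemplate,
    spec: list[tuple[str, int, int, float]],
    seed: int,
) -> RibotypePanel:
    """Draw a panel of distinct ribotypes with prescribed mutation counts.

    Each spec entry ``(region, n_subs, n_indels, frequency)`` yields one
    profile with exactly that many substitutions and single-base indels,
    all confined to the named region. Typical panels differ by 1-3
    substitutions per 240 bp of ITS1.
    """
    rng = as_rng(seed)
    total = sum(f for *_, f in spec)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {total})")
    entries = []
    seen = set()
    for region, n_subs, n_indels, freq in spec:
        a, b = template.spans[region]
        width = b - a + 1
        if n_subs + n_indels > width:
            raise ValueError(f"{n_subs + n_indels} events do not fit in {region}")
        for _ in range(1000):
            positions = rng.choice(np.arange(a, b + 1), size=n_subs + n_indels, replace=False)
            variants = []
            for pos in positions[:n_subs]:
                pos = int(pos)
                ref = template.sequence[pos - 1]
                alt = str(rng.choice([x for x in BASES if x != ref]))
                variants.append(Variant(pos, SUB, ref=ref, alt=alt, region=region))
            for pos in positions[n_subs:]:
                pos = int(pos)
                if rng.random() < 0.5:
                    variants.append(
                        Variant(pos, DEL, ref=template.sequence[pos - 1], region=region)
                    )
                else:
                    variants.append(
                        Variant(pos, INS, alt=str(rng.choice(list(BASES))), region=region)
                    )
            profile = VariantProfile(variants)
            if profile not in seen:
                break
        else:  # pragma: no cover - only reachable for pathological specs
            raise RuntimeError("could not draw a distinct profile")
        seen.add(profile)
        entries.append((profile, freq))
    return RibotypePanel(template=template, variants=tuple(entries))
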
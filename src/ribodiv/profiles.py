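"""Variant profiles: the sequence identity of a ribotype.

A ribotype is defined operationally by its list of differences from the
reference amplicon — substitutions, insertions and deletions on 1-based
reference coordinates. The bracket notation used in reports follows the
convention common in rDNA cluster tables: ``[57:C>T]`` is a substitution,
``[49:50>G]`` an insertion of G between positions 49 and 50, ``[57:AC>-]``
a deletion of AC starting at 57, and ``[-]`` the reference itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

SUB = "sub"
INS = "ins"
DEL = "del"

_KIND_ORDER = {SUB: 0, DEL: 1, INS: 2}


@dataclass(frozen=True)
class Variant:
    """One mutation event on reference coordinates.

    ``position`` is 1-based; for insertions it is the reference base
    immediately 5' of the inserted sequence (0 allowed for an insertion
    before the first base). ``ref`` is empty for insertions, ``alt`` empty
    for deletions. ``region`` names the amplicon segment the event falls in.
    """

    position: int
    kind: str
    ref: str = ""
    alt: str = ""
    region: str = ""

    def __post_init__(self):
        if self.kind not in (SUB, INS, DEL):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == SUB and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("substitution alleles must be single bases")
        if self.kind == SUB and self.ref == self.alt:
            raise ValueError("substitution alleles must differ")
        if self.kind == INS and (self.ref or not self.alt):
            raise ValueError("insertion has empty ref and non-empty alt")
        if self.kind == DEL and (self.alt or not self.ref):
            raise ValueError("deletion has non-empty ref and empty alt")

    @property
    def sort_key(self):
        return (self.position, _KIND_ORDER[self.kind], self.ref, self.alt)

    def region_position(self, region_start: int) -> int:
        """Position relative to a region start (1-based within region)."""
        return self.position - region_start + 1

    def notation(self, region_start: int = 1) -> str:
        p = self.region_position(region_start)
        if self.kind == SUB:
            return f"[{p}:{self.ref}>{self.alt}]"
        if self.kind == INS:
            return f"[{p}:{p + 1}>{self.alt}]"
        return f"[{p}:{self.ref}>-]"


class VariantProfile(tuple):
    """Ordered, hashable collection of :class:`Variant` events.

    The empty profile denotes the reference ribotype. No two variants may
    share (position, kind).
    """

    def __new__(cls, variants: Iterable[Variant] = ()):
        ordered = tuple(sorted(variants, key=lambda v: v.sort_key))
        seen = set()
        for v in ordered:
            key = (v.position, v.kind)
            if key in seen:
                raise ValueError(f"duplicate variant at {key}")
            seen.add(key)
        return super().__new__(cls, ordered)

    @property
    def substitutions(self) -> "VariantProfile":
        return VariantProfile(v for v in self if v.kind == SUB)

    @property
    def indels(self) -> "VariantProfile":
        return VariantProfile(v for v in self if v.kind != SUB)

    def notation(self, region_start: int = 1) -> str:
        if not self:
            return "[-]"
        return "".join(v.notation(region_start) for v in self)

    def __repr__(self):
        return f"VariantProfile({self.notation()})"


_TOKEN = re.compile(r"\[([^\[\]]+)\]")


def parse_profile(text: str) -> VariantProfile:
    """Parse bracket notation back into a profile (region tags are lost)."""
    variants = []
    for tok in _TOKEN.findall(text):
        if tok == "-":
            continue
        pos_part, _, change = tok.partition(":")
        ref, _, alt = change.partition(">")
        if ":" in pos_part:
            raise ValueError(f"malformed token [{tok}]")
        if ref and alt == "-":
            variants.append(Variant(int(pos_part), DEL, ref=ref))
        elif ">" in change and ref.isdigit():
            # insertion written as [p:p+1>SEQ]
            variants.append(Variant(int(pos_part), INS, alt=alt))
        else:
            variants.append(Variant(int(pos_part), SUB, ref=ref, alt=alt))
    return VariantProfile(variants)


def apply_profile(sequence: str, profile: VariantProfile) -> str:
    """Apply a profile to a reference sequence, returning the variant sequence.

    Events are applied right-to-left so earlier coordinates stay valid.
    """
    seq = list(sequence)
    for v in sorted(profile, key=lambda v: v.sort_key, reverse=True):
        i = v.position - 1
        if v.kind == SUB:
            if i < 0 or i >= len(sequence):
                raise ValueError(f"substitution position {v.position} out of range")
            if sequence[i] != v.ref:
                raise ValueError(
                    f"reference mismatch at {v.position}: template has "
                    f"{sequence[i]}, variant expects {v.ref}"
                )
            seq[i] = v.alt
        elif v.kind == DEL:
            if i < 0 or i + len(v.ref) > len(sequence):
                raise ValueError(f"deletion at {v.position} out of range")
            if sequence[i : i + len(v.ref)] != v.ref:
                raise ValueError(f"reference mismatch for deletion at {v.position}")
            del seq[i : i + len(v.ref)]
        else:  # insertion after position
            if v.position < 0 or v.position > len(sequence):
                raise ValueError(f"insertion anchor {v.position} out of range")
            seq[i + 1 : i + 1] = list(v.alt)
    return "".join(seq)
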
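"""Per-position variant calling and platform diagnostics.

Covers the Illumina-style branch of the analysis: pileups over the
reference amplicon, SNP/DIP calling with coverage and minor-frequency
gates (defaults: coverage >= 4, frequency >= 0.01, at most 1000 calls),
polymorphic-site accounting, the mutation spectrum, and the per-platform
substitution/indel read ratio that exposes pyrosequencing indel artefacts.

All printed percentages round half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._util import BASES, complement_base, round_half_away
from .align import AlignmentResult
from .amplicon import UnitTemplate
from .profiles import SUB, VariantProfile

_BASE_INDEX = {b: i for i, b in enumerate(BASES + "N")}


@dataclass
class Pileup:
    """Per-reference-position allele tallies from mapped reads.

    ``base_counts[pos-1, i]`` counts base ``"ACGTN"[i]`` observed at the
    1-based reference position; ``ins_counts``/``del_counts`` count indel
    events anchored at / covering each position. Coverage at a position is
    the sum of its A/C/G/T counts.
    """

    template: UnitTemplate
    base_counts: np.ndarray
    ins_counts: np.ndarray
    del_counts: np.ndarray

    def coverage(self) -> np.ndarray:
        return self.base_counts[:, :4].sum(axis=1)


def build_pileup(mapped: list[AlignmentResult], template: UnitTemplate) -> Pileup:
    """Tally aligned columns into a pileup.

    Matched/mismatched columns add one base count; a run of deleted
    reference positions adds one deletion event to each covered position;
    an insertion run adds one event at its 5' anchor position.
    """
    n = len(template)
    base_counts = np.zeros((n, 5), dtype=np.int64)
    ins_counts = np.zeros(n, dtype=np.int64)
    del_counts = np.zeros(n, dtype=np.int64)
    for aln in mapped:
        read = aln.read_seq
        last_ref = None
        in_insertion = False
        for r, q in aln.aligned_pairs:
            if r is not None and q is not None:
                base_counts[r - 1, _BASE_INDEX[read[q - 1]]] += 1
                last_ref = r
                in_insertion = False
            elif q is None:
                del_counts[r - 1] += 1
                last_ref = r
                in_insertion = False
            else:
                if not in_insertion and last_ref is not None:
                    ins_counts[last_ref - 1] += 1
                in_insertion = True
    return Pileup(template, base_counts, ins_counts, del_counts)


@dataclass(frozen=True)
class SiteCall:
    """A called variant site with the thresholds it passed."""

    position: int
    ref_allele: str
    alt_allele: str
    alt_frequency: float
    coverage: int
    kind: str  # "SNP" | "DIP"


def call_variants(
    pileup: Pileup,
    min_coverage: int = 4,
    min_frequency: float = 0.01,
    max_variants: int = 1000,
) -> list[SiteCall]:
    """Call SNP and DIP sites from a pileup.

    A site is called iff coverage >= ``min_coverage`` and the most
    frequent non-reference allele (or indel event) reaches
    ``min_frequency``. At most ``max_variants`` calls are kept, by
    descending frequency then position.
    """
    if min_coverage <= 0 or min_frequency <= 0 or max_variants <= 0:
        raise ValueError("thresholds must be positive")
    ref = pileup.template.sequence
    coverage = pileup.coverage()
    calls: list[SiteCall] = []
    for pos0 in range(len(ref)):
        cov = int(coverage[pos0])
        if cov < min_coverage:
            continue
        ref_base = ref[pos0]
        counts = pileup.base_counts[pos0]
        best_alt, best_n = None, 0
        for b in BASES:
            if b == ref_base:
                continue
            nb = int(counts[_BASE_INDEX[b]])
            if nb > best_n:
                best_alt, best_n = b, nb
        if best_alt is not None and best_n / cov >= min_frequency:
            calls.append(
                SiteCall(pos0 + 1, ref_base, best_alt, best_n / cov, cov, "SNP")
            )
        n_ins = int(pileup.ins_counts[pos0])
        if n_ins / cov >= min_frequency:
            calls.append(SiteCall(pos0 + 1, "", "ins", n_ins / cov, cov, "DIP"))
        n_del = int(pileup.del_counts[pos0])
        if n_del / cov >= min_frequency:
            calls.append(SiteCall(pos0 + 1, ref_base, "del", n_del / cov, cov, "DIP"))
    calls.sort(key=lambda c: (-c.alt_frequency, c.position))
    return calls[:max_variants]


def polymorphic_fraction(calls: list[SiteCall], region_length: int) -> tuple[int, int]:
    """Distinct polymorphic positions and their integer percentage of the
    region (e.g. 140/240 -> (140, 58))."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    count = len({c.position for c in calls})
    return count, int(round_half_away(100 * count / region_length))


DEFAULT_ABUNDANCE_EDGES = (0.01, 0.02, 0.05, 0.10, 0.15, 1.0)


def snp_abundance_histogram(
    calls: list[SiteCall],
    bin_edges: tuple[float, ...] = DEFAULT_ABUNDANCE_EDGES,
) -> list[int]:
    """Bin SNP alternate-allele frequencies into abundance categories.

    Only SNPs strictly exceeding the lowest edge (1% by default) are
    counted; bins are half-open on the left, (low, high].
    """
    if list(bin_edges) != sorted(bin_edges) or len(set(bin_edges)) != len(bin_edges):
        raise ValueError("bin edges must be strictly increasing")
    counts = [0] * (len(bin_edges) - 1)
    for c in calls:
        if c.kind != "SNP" or c.alt_frequency <= bin_edges[0]:
            continue
        for i in range(len(counts)):
            if bin_edges[i] < c.alt_frequency <= bin_edges[i + 1]:
                counts[i] += 1
                break
    return counts


@dataclass
class MutationSpectrum:
    directed: dict[str, int]
    collapsed: dict[str, int]
    top_class: str | None

    @property
    def total(self) -> int:
        return sum(self.directed.values())


def _collapsed_class(ref: str, alt: str) -> str:
    """Strand-collapsed class label, pyrimidine reference first
    (e.g. C>T and G>A both map to 'C:G>T:A')."""
    if ref in "AG":
        ref, alt = complement_base(ref), complement_base(alt)
    return f"{ref}:{complement_base(ref)}>{alt}:{complement_base(alt)}"


def mutation_spectrum(profiles: list[VariantProfile]) -> MutationSpectrum:
    """Count substitution events across read profiles, per directed type
    (12) and per strand-collapsed class (6)."""
    directed = {f"{a}>{b}": 0 for a in BASES for b in BASES if a != b}
    collapsed: dict[str, int] = {}
    for prof in profiles:
        for v in prof:
            if v.kind != SUB:
                continue
            directed[f"{v.ref}>{v.alt}"] += 1
            cls = _collapsed_class(v.ref, v.alt)
            collapsed[cls] = collapsed.get(cls, 0) + 1
    top = max(collapsed, key=lambda k: (collapsed[k], k)) if collapsed else None
    return MutationSpectrum(directed=directed, collapsed=collapsed, top_class=top)


@dataclass(frozen=True)
class SubIndelRatio:
    n_reads_with_subs: int
    n_reads_with_indels: int
    ratio: float  # rounded to 1 decimal; inf when no indel-bearing reads

    @property
    def defined(self) -> bool:
        return math.isfinite(self.ratio)


def sub_indel_ratio(profiles: list[VariantProfile]) -> SubIndelRatio:
    """Reads carrying substitutions vs reads carrying indels.

    A read counts in both tallies if it carries both kinds of event. A
    low ratio is the signature of homopolymer indel artefacts in
    pyrosequencing data; substitution-dominated platforms give high ratios.
    """
    n_sub = sum(1 for p in profiles if any(v.kind == SUB for v in p))
    n_indel = sum(1 for p in profiles if any(v.kind != SUB for v in p))
    if n_indel == 0:
        return SubIndelRatio(n_sub, 0, math.inf)
    return SubIndelRatio(n_sub, n_indel, round_half_away(n_sub / n_indel, 1))


def divergence_percent(n_subs: int, length: int) -> float:
    """Percent divergence, one decimal (3 subs / 240 bp -> 1.3)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= n_subs <= length:
        raise ValueError("n_subs must lie in [0, length]")
    return round_half_away(100 * n_subs / length, 1)


def coverage_estimate(reads_mapped: int, copies_per_1c: int) -> float:
    """Per-unit coverage: mapped reads / rDNA copies per 1C, one decimal."""
    if copies_per_1c <= 0:
        raise ValueError("copies_per_1c must be positive")
    return round_half_away(reads_mapped / copies_per_1c, 1)
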
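"""Stochastic simulator of concerted evolution in tandem rDNA arrays.

The genome is a set of loci, each an ordered array of rDNA units. A unit
carries two infinite-alleles haplotype labels: a genic allele (the 18S-like
coding part, allele 0 = functional ancestral state) and a spacer allele
(the ITS-like non-coding part). Each generation:

1. every unit mutates its genic / spacer allele to a fresh label with
   probability ``mu_genic`` / ``mu_spacer``;
2. a Poisson(``c_intra`` + ``c_inter``) number of gene-conversion events
   occur; each picks a recipient unit uniformly and a donor from the same
   locus (probability proportional to ``c_intra``) or a different locus
   (proportional to ``c_inter``), and overwrites the recipient's whole
   unit with the donor's;
3. donors carrying a genic mutation are rejected with probability ``s``
   (purifying selection against amplifying defective coding copies).

Locus duplication and orphan-seeded expansion are explicit operations.
This is the minimal copy-paste homogenisation mechanism; rates are free
parameters with no claim of quantitative fit to any genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import as_rng

GENIC, SPACER = 0, 1
ANCESTRAL = 0


@dataclass(frozen=True)
class SimParams:
    """Rates of the homogenisation model (all per generation).

    ``mu_*`` are per-unit mutation probabilities; ``c_intra``/``c_inter``
    are expected counts of within-/between-locus conversion events;
    ``s`` in [0,1] is the rejection probability for genic-mutant donors;
    ``expansion_rate`` is the expected number of unit copies added per
    generation while a founder locus expands.
    """

    mu_genic: float = 0.0
    mu_spacer: float = 0.0
    c_intra: float = 1.0
    c_inter: float = 0.0
    s: float = 0.0
    expansion_rate: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("mu_genic", "mu_spacer", "s"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.c_intra < 0 or self.c_inter < 0:
            raise ValueError("conversion rates must be non-negative")
        if self.expansion_rate <= 0:
            raise ValueError("expansion_rate must be positive")


@dataclass
class GenomeState:
    """Loci as (n_units, 2) integer arrays of [genic, spacer] allele ids."""

    loci: list[np.ndarray]
    generation: int = 0
    next_allele: int = 1

    def __post_init__(self):
        self.loci = [np.asarray(l, dtype=np.int64).reshape(-1, 2) for l in self.loci]

    @property
    def n_units(self) -> int:
        return sum(len(l) for l in self.loci)

    def copy(self) -> "GenomeState":
        return GenomeState(
            loci=[l.copy() for l in self.loci],
            generation=self.generation,
            next_allele=self.next_allele,
        )

    @classmethod
    def uniform(cls, units_per_locus: list[int]) -> "GenomeState":
        """All units ancestral: one locus array per requested size."""
        return cls(loci=[np.zeros((n, 2), dtype=np.int64) for n in units_per_locus])

    @classmethod
    def maximally_diverse(cls, n_units: int) -> "GenomeState":
        """Single locus in which every unit has a unique spacer allele."""
        arr = np.zeros((n_units, 2), dtype=np.int64)
        arr[:, SPACER] = np.arange(n_units)
        return cls(loci=[arr], next_allele=n_units)


def step(state: GenomeState, params: SimParams, rng: np.random.Generator) -> GenomeState:
    """Advance the genome by one generation (mutation, then conversion)."""
    new = state.copy()
    for locus in new.loci:
        for channel, mu in ((GENIC, params.mu_genic), (SPACER, params.mu_spacer)):
            if mu <= 0:
                continue
            hits = np.flatnonzero(rng.random(len(locus)) < mu)
            for i in hits:
                locus[i, channel] = new.next_allele
                new.next_allele += 1

    total_rate = params.c_intra + params.c_inter
    n_events = rng.poisson(total_rate) if total_rate > 0 else 0
    sizes = [len(l) for l in new.loci]
    offsets = np.cumsum([0] + sizes)
    n_total = offsets[-1]
    multi_locus = len(new.loci) > 1
    for _ in range(n_events):
        flat_r = int(rng.integers(n_total))
        li = int(np.searchsorted(offsets, flat_r, side="right") - 1)
        ri = flat_r - offsets[li]
        if multi_locus and total_rate > 0:
            intra = rng.random() < params.c_intra / total_rate
        else:
            intra = True
        if intra:
            if sizes[li] < 2:
                continue
            di = int(rng.integers(sizes[li] - 1))
            if di >= ri:
                di += 1
            donor = new.loci[li][di]
        else:
            others = [j for j in range(len(new.loci)) if j != li and sizes[j] > 0]
            if not others:
                continue
            lj = others[int(rng.integers(len(others)))]
            donor = new.loci[lj][int(rng.integers(sizes[lj]))]
        if donor[GENIC] != ANCESTRAL and rng.random() < params.s:
            continue  # selection rejects genic-mutant donors
        new.loci[li][ri] = donor
    new.generation += 1
    return new


def evolve(
    state: GenomeState,
    params: SimParams,
    n_generations: int,
    rng: np.random.Generator,
) -> GenomeState:
    for _ in range(n_generations):
        state = step(state, params, rng)
    return state


def duplicate_locus(state: GenomeState, locus_index: int) -> GenomeState:
    """Whole-locus duplication: append an identical copy as a new locus."""
    if not state.loci or not 0 <= locus_index < len(state.loci):
        raise IndexError(f"no locus {locus_index}")
    new = state.copy()
    new.loci.append(new.loci[locus_index].copy())
    return new


def seed_orphan_and_expand(
    state: GenomeState,
    source_unit: tuple[int, int],
    target_size: int,
    params: SimParams,
    rng: np.random.Generator,
) -> GenomeState:
    """Found a new locus from one orphaned unit and expand it by copying.

    Each generation adds Poisson(``expansion_rate``) unit copies (each
    duplicating a random current member of the new locus) until the locus
    reaches ``target_size``; the result is monomorphic for the founder
    haplotype. The generation counter advances by the expansion time.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    li, ui = source_unit
    founder = state.loci[li][ui].copy()
    new = state.copy()
    locus = [founder]
    while len(locus) < target_size:
        n_new = int(rng.poisson(params.expansion_rate))
        for _ in range(min(n_new, target_size - len(locus))):
            locus.append(locus[int(rng.integers(len(locus)))].copy())
        new.generation += 1
    new.loci.append(np.array(locus, dtype=np.int64).reshape(-1, 2))
    return new


def run_until_homogenised(
    n_units: int,
    params: SimParams,
    cap: int = 10**6,
    seed: int | np.random.Generator | None = None,
) -> int | None:
    """Generations for a maximally diverse single locus to fix one ribotype.

    Pure homogenisation: mutation must be switched off. Uses the embedded
    event chain of :func:`step` (uniform recipient, uniform other donor,
    Poisson(``c_intra``) events per generation), so the returned time is
    distributed exactly as a step-by-step run. Returns ``None`` when the
    cap is hit (censored).
    """
    if params.mu_genic != 0 or params.mu_spacer != 0:
        raise ValueError("homogenisation time is measured with mutation off")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if n_units == 1:
        return 0
    rng = as_rng(params.seed if seed is None else seed)
    alleles = np.arange(n_units)
    counts = np.ones(n_units, dtype=np.int64)
    n_distinct = n_units
    generation = 0
    block = 1024
    while generation < cap:
        events = rng.poisson(params.c_intra, size=min(block, cap - generation))
        for k in events:
            generation += 1
            for _ in range(int(k)):
                r = int(rng.integers(n_units))
                d = int(rng.integers(n_units - 1))
                if d >= r:
                    d += 1
                old, new_allele = alleles[r], alleles[d]
                if old == new_allele:
                    continue
                alleles[r] = new_allele
                counts[old] -= 1
                counts[new_allele] += 1
                if counts[old] == 0:
                    n_distinct -= 1
            if n_distinct == 1:
                return generation
    return None


@dataclass(frozen=True)
class DiversityMetrics:
    """Ribotype diversity summary of a genome state.

    A ribotype is a distinct (genic, spacer) haplotype. ``*_minor_units``
    count units whose genic / spacer allele differs from the genome-wide
    modal allele of that channel — the analogue of reads outside the major
    cluster; ``*_alleles`` count distinct segregating alleles.
    """

    ribotypes_per_locus: tuple[int, ...]
    genome_ribotypes: int
    major_fraction: float
    genic_alleles: int
    spacer_alleles: int
    genic_minor_units: int
    spacer_minor_units: int


def diversity_metrics(state: GenomeState) -> DiversityMetrics:
    all_units = np.vstack(state.loci)
    per_locus = tuple(len(np.unique(l, axis=0)) for l in state.loci)
    haplotypes, counts = np.unique(all_units, axis=0, return_counts=True)
    n = len(all_units)

    def channel_stats(col):
        vals, cnts = np.unique(all_units[:, col], return_counts=True)
        return len(vals), int(n - cnts.max())

    genic_alleles, genic_minor = channel_stats(GENIC)
    spacer_alleles, spacer_minor = channel_stats(SPACER)
    return DiversityMetrics(
        ribotypes_per_locus=per_locus,
        genome_ribotypes=len(haplotypes),
        major_fraction=float(counts.max() / n),
        genic_alleles=genic_alleles,
        spacer_alleles=spacer_alleles,
        genic_minor_units=genic_minor,
        spacer_minor_units=spacer_minor,
    )
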
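"""Local alignment of amplicon reads and per-read variant extraction.

Reads are aligned to the reference amplicon with the Smith-Waterman
algorithm (affine gaps, both orientations tried), filtered by an explicit
mutation-count cap and a percent-identity floor, and converted into
variant profiles — the substrate for ribotype clustering.

A run of g adjacent gap columns counts as ONE mutation event (one indel of
length g). Indels are left-aligned on the reference so that equivalent
placements inside homopolymer runs collapse to a single representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice
from typing import Iterable

from Bio import Align

from ._util import reverse_complement
from .amplicon import UnitTemplate
from .profiles import DEL, INS, SUB, Variant, VariantProfile

READ_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; a gap of length g costs |gap_open| + g·|gap_extend|."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        # Biopython charges open_gap_score for the first gap base, so fold
        # one extension into it to get cost open + g*extend for length g.
        a.open_gap_score = self.gap_open + self.gap_extend
        a.extend_gap_score = self.gap_extend
        return a


DEFAULT_SCORING = ScoringScheme()


@dataclass
class AlignmentResult:
    """One local alignment of a read against the reference.

    ``aligned_pairs`` holds one entry per alignment column as 1-based
    ``(ref_pos, read_pos)`` with ``None`` marking a gap; positions refer to
    the oriented read sequence stored in ``read_seq``. ``n_mutations``
    counts substitution events plus gap runs (not gap columns).
    """

    read_id: str
    ref_interval: tuple[int, int]
    aligned_pairs: list[tuple[int | None, int | None]]
    score: float
    identity: float
    n_mutations: int
    strand: str = "+"
    read_seq: str = ""


def _columns(alignment) -> list[tuple[int | None, int | None]]:
    """Expand biopython aligned blocks into per-column (ref0, read0) pairs."""
    tblocks, qblocks = alignment.aligned
    cols: list[tuple[int | None, int | None]] = []
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            for r in range(prev_t, ts):  # deletion in read
                cols.append((r, None))
            for q in range(prev_q, qs):  # insertion in read
                cols.append((None, q))
        cols.extend((ts + k, qs + k) for k in range(te - ts))
        prev_t, prev_q = te, qe
    return cols


def _gap_runs(cols) -> int:
    runs = 0
    prev_gap = None  # "ref" / "read" / None
    for r, q in cols:
        gap = "read" if r is None else ("ref" if q is None else None)
        if gap is not None and gap != prev_gap:
            runs += 1
        prev_gap = gap
    return runs


def smith_waterman(
    read: str,
    ref: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    read_id: str = "read",
    strand: str = "+",
) -> AlignmentResult:
    """Maximal-scoring local alignment of ``read`` against ``ref``.

    Among co-optimal alignments, ties are broken by earliest reference
    start, then fewest gap runs (deterministic output).
    """
    if not read or not ref:
        raise ValueError("sequences must be non-empty")
    if set(read) - READ_ALPHABET or set(ref) - READ_ALPHABET:
        raise ValueError("sequences must be over {A,C,G,T,N}")
    alignments = scoring.aligner().align(ref, read)
    candidates = list(islice(alignments, 8))
    if not candidates:
        raise ValueError("no local alignment found")
    if len(candidates) == 1:
        best = candidates[0]
    else:
        # earliest reference start first; gap runs only to break remaining ties
        def start_of(aln):
            tblocks = aln.aligned[0]
            return tblocks[0][0] if len(tblocks) else 0

        min_start = min(start_of(a) for a in candidates)
        tied = [a for a in candidates if start_of(a) == min_start]
        best = min(tied, key=lambda a: _gap_runs(_columns(a)))
    cols = _columns(best)
    if not cols:
        raise ValueError("empty local alignment")
    matches = mismatches = 0
    for r, q in cols:
        if r is not None and q is not None:
            if ref[r] == read[q] and read[q] != "N":
                matches += 1
            else:
                mismatches += 1
    # mutation events: mismatch columns involving real bases + gap runs
    sub_events = sum(
        1
        for r, q in cols
        if r is not None and q is not None and ref[r] != read[q] and read[q] != "N"
    )
    n_mut = sub_events + _gap_runs(cols)
    ref_cols = [r for r, _ in cols if r is not None]
    pairs = [
        (r + 1 if r is not None else None, q + 1 if q is not None else None)
        for r, q in cols
    ]
    return AlignmentResult(
        read_id=read_id,
        ref_interval=(ref_cols[0] + 1, ref_cols[-1] + 1),
        aligned_pairs=pairs,
        score=float(alignments.score),
        identity=matches / len(cols),
        n_mutations=n_mut,
        strand=strand,
        read_seq=read,
    )


@dataclass(frozen=True)
class RejectedRead:
    read_id: str
    reason: str


def map_reads(
    reads: Iterable[tuple[str, str]],
    template: UnitTemplate,
    max_mutations: int = 10,
    min_identity: float = 0.90,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> tuple[list[AlignmentResult], list[RejectedRead]]:
    """Align reads to the template in both orientations and filter.

    Every input read lands in exactly one of the two outputs. Reads with
    more than ``max_mutations`` substitution/indel events, or identity
    below ``min_identity``, are rejected with a reason; malformed records
    are rejected, never silently dropped.
    """
    mapped: list[AlignmentResult] = []
    rejected: list[RejectedRead] = []
    for read_id, seq in reads:
        seq = (seq or "").upper()
        if not seq or set(seq) - READ_ALPHABET:
            rejected.append(RejectedRead(read_id, "unreadable"))
            continue
        # score both orientations without traceback, then align the winner
        # (forward wins ties)
        aligner = scoring.aligner()
        rc = reverse_complement(seq)
        s_fwd = aligner.score(template.sequence, seq)
        s_rev = aligner.score(template.sequence, rc)
        oriented, strand = (seq, "+") if s_fwd >= s_rev else (rc, "-")
        try:
            best = smith_waterman(oriented, template.sequence, scoring, read_id, strand)
        except ValueError:
            rejected.append(RejectedRead(read_id, "no_alignment"))
            continue
        if best.n_mutations > max_mutations:
            rejected.append(RejectedRead(read_id, "max_mutations"))
        elif best.identity < min_identity:
            rejected.append(RejectedRead(read_id, "min_identity"))
        else:
            mapped.append(best)
    return mapped, rejected


def _left_normalise(ref: str, variant: Variant) -> Variant:
    """Shift an indel to its leftmost equivalent placement on the reference."""
    if variant.kind == DEL:
        pos, allele = variant.position, variant.ref
        while pos > 1 and ref[pos - 2] == allele[-1]:
            allele = ref[pos - 2] + allele[:-1]
            pos -= 1
        return Variant(pos, DEL, ref=allele, region=variant.region)
    if variant.kind == INS:
        pos, allele = variant.position, variant.alt
        while pos >= 1 and ref[pos - 1] == allele[-1]:
            allele = ref[pos - 1] + allele[:-1]
            pos -= 1
        return Variant(pos, INS, alt=allele, region=variant.region)
    return variant


def extract_profile(alignment: AlignmentResult, template: UnitTemplate) -> VariantProfile:
    """Convert an alignment into a variant profile on template coordinates.

    Adjacent gap columns merge into single indel events; indels are
    left-aligned; columns containing N never become variants. Regions are
    assigned from the template spans (insertions by their anchor base).
    """
    ref = template.sequence
    read = alignment.read_seq
    variants: list[Variant] = []
    pending_kind = None
    pending_pos = 0
    pending_seq = ""
    last_ref = None

    def flush():
        nonlocal pending_kind, pending_seq
        if pending_kind == DEL:
            v = Variant(pending_pos, DEL, ref=pending_seq)
        elif pending_kind == INS and pending_seq:
            v = Variant(max(pending_pos, 0), INS, alt=pending_seq)
        else:
            v = None
        if v is not None:
            v = _left_normalise(ref, v)
            region = template.region_of(max(v.position, 1))
            variants.append(
                Variant(v.position, v.kind, ref=v.ref, alt=v.alt, region=region)
            )
        pending_kind, pending_seq = None, ""

    for r, q in alignment.aligned_pairs:
        if r is not None and q is not None:
            if pending_kind:
                flush()
            last_ref = r
            rb, qb = ref[r - 1], read[q - 1]
            if qb != rb and qb != "N":
                variants.append(
                    Variant(r, SUB, ref=rb, alt=qb, region=template.region_of(r))
                )
        elif q is None:  # deletion in read
            if pending_kind != DEL:
                if pending_kind:
                    flush()
                pending_kind, pending_pos, pending_seq = DEL, r, ""
            pending_seq += ref[r - 1]
            last_ref = r
        else:  # insertion in read
            base = read[q - 1]
            if pending_kind != INS:
                if pending_kind:
                    flush()
                pending_kind, pending_pos, pending_seq = INS, last_ref or 0, ""
            if base != "N":
                pending_seq += base
    if pending_kind:
        flush()
    return VariantProfile(variants)
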
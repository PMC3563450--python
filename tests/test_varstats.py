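"""Pileup construction, SNP/DIP calling and platform diagnostics."""

import math

import numpy as np
import pytest

from ribodiv import (
    build_pileup,
    call_variants,
    coverage_estimate,
    divergence_percent,
    map_reads,
    mutation_spectrum,
    polymorphic_fraction,
    snp_abundance_histogram,
    sub_indel_ratio,
)
from ribodiv.profiles import DEL, INS, SUB, Variant, VariantProfile
from ribodiv.varstats import Pileup, SiteCall


def make_pileup(template, base_rows):
    """Pileup with given per-position (A,C,G,T,N) count rows."""
    n = len(template)
    base_counts = np.zeros((n, 5), dtype=np.int64)
    for pos, row in base_rows.items():
        base_counts[pos - 1] = row
    return Pileup(
        template=template,
        base_counts=base_counts,
        ins_counts=np.zeros(n, dtype=np.int64),
        del_counts=np.zeros(n, dtype=np.int64),
    )


class TestBuildPileup:
    def test_perfect_reads_give_uniform_coverage(self, template):
        reads = [(f"r{i}", template.sequence) for i in range(10)]
        mapped, _ = map_reads(reads, template)
        pileup = build_pileup(mapped, template)
        assert (pileup.coverage() == 10).all()
        ref_idx = ["ACGTN".index(b) for b in template.sequence]
        alt = pileup.base_counts[:, :4].sum(axis=1) - np.array(
            [pileup.base_counts[i, j] for i, j in enumerate(ref_idx)]
        )
        assert (alt == 0).all()

    def test_minor_substitution_tally(self, template):
        pos = 370  # inside ITS1
        ref_base = template.sequence[pos - 1]
        alt_base = "T" if ref_base != "T" else "A"
        variant = list(template.sequence)
        variant[pos - 1] = alt_base
        reads = [(f"ref{i}", template.sequence) for i in range(8)] + [
            (f"alt{i}", "".join(variant)) for i in range(2)
        ]
        mapped, _ = map_reads(reads, template)
        pileup = build_pileup(mapped, template)
        assert pileup.base_counts[pos - 1, "ACGTN".index(alt_base)] == 2
        assert pileup.base_counts[pos - 1, "ACGTN".index(ref_base)] == 8

    def test_empty_input_gives_zero_pileup(self, template):
        pileup = build_pileup([], template)
        assert pileup.coverage().sum() == 0


class TestCallVariants:
    def test_coverage_gate_below_four(self, template):
        ref = template.sequence[0]
        alt = "C" if ref != "C" else "G"
        row = [0] * 5
        row["ACGTN".index(ref)] = 2
        row["ACGTN".index(alt)] = 1
        pileup = make_pileup(template, {1: row})
        assert call_variants(pileup) == []

    def test_frequency_boundaries_at_one_percent(self, template):
        ref = template.sequence[0]
        alt = "C" if ref != "C" else "G"

        def calls_for(cov, alt_n):
            row = [0] * 5
            row["ACGTN".index(ref)] = cov - alt_n
            row["ACGTN".index(alt)] = alt_n
            return call_variants(make_pileup(template, {1: row}))

        called = calls_for(400, 4)  # exactly 0.01 -> called
        assert len(called) == 1 and called[0].alt_frequency == pytest.approx(0.01)
        assert calls_for(1000, 9) == []  # 0.009 -> below threshold

    def test_calling_is_monotone_in_thresholds(self, template, mapped_454):
        _, _, mapped, _ = mapped_454
        pileup = build_pileup(mapped, template)
        strict = call_variants(pileup, min_coverage=10, min_frequency=0.05)
        loose = call_variants(pileup, min_coverage=4, min_frequency=0.01)
        strict_keys = {(c.position, c.kind, c.alt_allele) for c in strict}
        loose_keys = {(c.position, c.kind, c.alt_allele) for c in loose}
        assert strict_keys <= loose_keys

    def test_recovers_known_minor_frequency(self, template, panel3):
        # a 1-substitution ribotype at f=0.20: its SNP call frequency should
        # sit within 3 binomial sd of the truth at the observed coverage
        from ribodiv.simulate import PlatformErrorModel, simulate_reads

        zero = PlatformErrorModel(name="sanger", sub_rate=0.0)
        reads, _ = simulate_reads(panel3, zero, 300, seed=21, origin="five_prime")
        mapped, _ = map_reads(reads, template)
        pileup = build_pileup(mapped, template)
        calls = call_variants(pileup)
        v = panel3.profiles[1][0]
        hit = [c for c in calls if c.position == v.position and c.kind == "SNP"]
        assert len(hit) == 1
        f, cov = 0.20, hit[0].coverage
        assert abs(hit[0].alt_frequency - f) <= 3 * math.sqrt(f * (1 - f) / cov)

    def test_max_variants_keeps_highest_frequencies(self, template):
        rows = {}
        for pos, alt_n in [(1, 30), (2, 20), (3, 10)]:
            ref = template.sequence[pos - 1]
            alt = "C" if ref != "C" else "G"
            row = [0] * 5
            row["ACGTN".index(ref)] = 100 - alt_n
            row["ACGTN".index(alt)] = alt_n
            rows[pos] = row
        calls = call_variants(make_pileup(template, rows), max_variants=2)
        assert [c.position for c in calls] == [1, 2]


class TestPolymorphicFraction:
    @pytest.mark.parametrize("n_sites, expected_pct", [(140, 58), (154, 64), (0, 0)])
    def test_site_percentages_over_240bp(self, n_sites, expected_pct):
        calls = [
            SiteCall(i + 1, "A", "G", 0.02, 500, "SNP") for i in range(n_sites)
        ]
        assert polymorphic_fraction(calls, 240) == (n_sites, expected_pct)

    def test_duplicate_positions_counted_once(self):
        calls = [
            SiteCall(5, "A", "G", 0.02, 500, "SNP"),
            SiteCall(5, "A", "", 0.02, 500, "DIP"),
        ]
        assert polymorphic_fraction(calls, 240)[0] == 1


class TestAbundanceHistogram:
    def test_major_snp_at_15_5_percent_falls_in_top_bin(self):
        calls = [SiteCall(57, "C", "T", 0.155, 500, "SNP")]
        assert snp_abundance_histogram(calls) == [0, 0, 0, 0, 1]

    def test_exactly_one_percent_excluded(self):
        calls = [SiteCall(57, "C", "T", 0.01, 500, "SNP")]
        assert sum(snp_abundance_histogram(calls)) == 0

    def test_empty_calls_give_zero_bins(self):
        assert snp_abundance_histogram([]) == [0, 0, 0, 0, 0]

    def test_unordered_edges_rejected(self):
        with pytest.raises(ValueError):
            snp_abundance_histogram([], bin_edges=(0.01, 0.5, 0.1))


class TestMutationSpectrum:
    def test_deamination_class_collapses_ct_with_ga(self):
        profiles = (
            [VariantProfile([Variant(1, SUB, ref="C", alt="T")])] * 3
            + [VariantProfile([Variant(2, SUB, ref="G", alt="A")])] * 2
            + [VariantProfile([Variant(3, SUB, ref="A", alt="G")])]
        )
        spec = mutation_spectrum(profiles)
        assert spec.collapsed["C:G>T:A"] == 5
        assert spec.top_class == "C:G>T:A"
        assert spec.total == 6

    def test_empty_input_gives_zero_spectrum(self):
        spec = mutation_spectrum([])
        assert spec.total == 0 and spec.top_class is None

    def test_deamination_biased_reads_recover_top_class(self, template):
        # C->T errors at 5x the rate of other substitutions
        rng = np.random.default_rng(17)
        profiles = []
        for _ in range(200):
            variants = []
            pos = 1
            for _ in range(rng.integers(1, 3)):
                pos += int(rng.integers(5, 20))
                if rng.random() < 5 / 8:
                    variants.append(Variant(pos, SUB, ref="C", alt="T"))
                else:
                    variants.append(Variant(pos, SUB, ref="A", alt="C"))
            profiles.append(VariantProfile(variants))
        assert mutation_spectrum(profiles).top_class == "C:G>T:A"


class TestSubIndelRatio:
    def test_published_count_arithmetic(self):
        profiles = [VariantProfile([Variant(1, SUB, ref="A", alt="G")])] * 800 + [
            VariantProfile([Variant(2, DEL, ref="C")])
        ] * 680
        r = sub_indel_ratio(profiles)
        assert (r.n_reads_with_subs, r.n_reads_with_indels, r.ratio) == (800, 680, 1.2)

    def test_read_with_both_kinds_counts_in_both(self):
        both = VariantProfile(
            [Variant(1, SUB, ref="A", alt="G"), Variant(5, INS, alt="T")]
        )
        r = sub_indel_ratio([both, both])
        assert (r.n_reads_with_subs, r.n_reads_with_indels, r.ratio) == (2, 2, 1.0)

    def test_no_indels_flagged_as_infinite(self):
        r = sub_indel_ratio([VariantProfile([Variant(1, SUB, ref="A", alt="G")])])
        assert not r.defined and math.isinf(r.ratio)


class TestArithmetic:
    @pytest.mark.parametrize(
        "n_subs, length, expected", [(3, 240, 1.3), (1, 240, 0.4), (0, 240, 0.0)]
    )
    def test_divergence_percent(self, n_subs, length, expected):
        assert divergence_percent(n_subs, length) == expected

    @pytest.mark.parametrize(
        "reads, copies, expected",
        [(2308, 1500, 1.5), (2657, 5100, 0.5), (1190, 1400, 0.9), (0, 1000, 0.0)],
    )
    def test_coverage_estimate(self, reads, copies, expected):
        assert coverage_estimate(reads, copies) == expected

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            divergence_percent(1, 0)
        with pytest.raises(ValueError):
            coverage_estimate(100, 0)
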
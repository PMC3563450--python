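"""End-to-end orchestration: simulate -> map -> cluster -> variants -> phylogeny.

The pipeline runs per species: a ribotype panel is simulated (or reads are
loaded), reads are mapped to the reference amplicon, region-spanning reads
are clustered into ribotypes, variant statistics are computed, and major
ribotypes from all species feed a joint NJ tree. The summary mirrors the
columns of a 454 amplicon survey: reads mapped, per-unit coverage, and
cluster counts at each filtering stage. Identical seeds give identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import align, cluster, phylo, varstats
from .amplicon import DEFAULT_LENGTHS, UnitTemplate, build_reference, derive_ribotypes
from .io import (
    read_reads,
    write_fasta,
    write_fastq,
    write_template,
    write_tsv,
    write_vcf_like,
)
from .profiles import VariantProfile
from .simulate import model_454, model_illumina, model_sanger, simulate_reads

PLATFORMS = {"454": model_454, "illumina": model_illumina, "sanger": model_sanger}


class PipelineError(RuntimeError):
    """Configuration or stage-dependency failure, tagged with the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SpeciesConfig:
    """One species' input: either a panel to simulate or a reads file."""

    name: str
    panel_spec: list[tuple[str, int, int, float]] | None = None
    reads_path: str | None = None
    n_reads: int = 2000
    platform: str = "454"
    origin: str | None = None
    copies_per_1c: int | None = None
    n_loci: int | None = None


@dataclass
class RunConfig:
    """Pipeline settings; threshold defaults are the published values
    (max 10 mutations/read, 5% major-ribotype cut-off, coverage >= 4,
    minor frequency >= 0.01, at most 1000 variants, 500 bootstrap
    replicates)."""

    species: list[SpeciesConfig]
    seed: int = 1
    template_seed: int = 1
    gc: float = 0.5
    lengths: tuple[int, int, int] = DEFAULT_LENGTHS
    region: str = "ITS1"
    do_simulate: bool = True
    do_map: bool = True
    do_cluster: bool = True
    do_variants: bool = True
    do_phylogeny: bool = True
    max_mutations: int = 10
    min_identity: float = 0.90
    major_threshold: float = 0.05
    min_coverage: int = 4
    min_frequency: float = 0.01
    max_variants: int = 1000
    bootstrap_n: int = 500
    outdir: str | None = None


def _check_dependencies(config: RunConfig) -> None:
    have_reads = config.do_simulate or all(s.reads_path for s in config.species)
    if config.do_map and not have_reads:
        raise PipelineError("map", "mapping requires simulated reads or reads_path inputs")
    if config.do_cluster and not config.do_map:
        raise PipelineError("cluster", "clustering requires the mapping stage")
    if config.do_variants and not config.do_map:
        raise PipelineError("variants", "variant calling requires the mapping stage")
    if config.do_phylogeny and not config.do_cluster:
        raise PipelineError("phylogeny", "phylogeny requires the clustering stage")


def spans_region(aln: align.AlignmentResult, template: UnitTemplate, region: str) -> bool:
    a, b = template.spans[region]
    return aln.ref_interval[0] <= a and aln.ref_interval[1] >= b


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and return a JSON-serialisable report."""
    _check_dependencies(config)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    template = build_reference(config.template_seed, gc=config.gc, lengths=config.lengths)
    if outdir:
        write_template(template, outdir / "reference.fasta")
    report: dict = {
        "parameters": {
            "seed": config.seed,
            "region": config.region,
            "max_mutations": config.max_mutations,
            "min_identity": config.min_identity,
            "major_threshold": config.major_threshold,
            "min_coverage": config.min_coverage,
            "min_frequency": config.min_frequency,
            "max_variants": config.max_variants,
            "bootstrap_n": config.bootstrap_n,
        },
        "species": {},
    }
    region_start = template.region_start(config.region)
    all_major: list[tuple[str, str]] = []  # (label, consensus sequence)

    for idx, sp in enumerate(config.species):
        row: dict = {}
        if config.do_simulate:
            if sp.panel_spec is None:
                raise PipelineError("simulate", f"{sp.name}: no panel_spec given")
            panel = derive_ribotypes(template, sp.panel_spec, seed=config.seed + 1000 * idx)
            model = PLATFORMS[sp.platform]()
            reads, truth = simulate_reads(
                panel, model, sp.n_reads, seed=config.seed + 1000 * idx + 1,
                origin=sp.origin,
            )
            row["n_reads"] = len(reads)
            if outdir:
                write_fastq(reads, outdir / f"{sp.name}.reads.fastq")
                write_tsv(truth, outdir / f"{sp.name}.truth.tsv")
        elif sp.reads_path:
            reads = read_reads(sp.reads_path)
            row["n_reads"] = len(reads)
        else:
            report["species"][sp.name] = row
            continue

        if not config.do_map:
            report["species"][sp.name] = row
            continue
        mapped, rejected = align.map_reads(
            reads, template,
            max_mutations=config.max_mutations, min_identity=config.min_identity,
        )
        row["reads_mapped"] = len(mapped)
        row["reads_rejected"] = len(rejected)
        if sp.copies_per_1c:
            row["coverage"] = varstats.coverage_estimate(len(mapped), sp.copies_per_1c)

        if config.do_cluster:
            spanning = [a for a in mapped if spans_region(a, template, config.region)]
            row["reads_spanning_region"] = len(spanning)
            profiles = [
                (
                    a.read_id,
                    VariantProfile(
                        v
                        for v in align.extract_profile(a, template)
                        if v.region == config.region
                    ),
                )
                for a in spanning
            ]
            raw = cluster.cluster_by_profile(profiles, config.region, species=sp.name)
            merged = cluster.merge_indel_clusters(raw)
            filtered = cluster.drop_singletons(merged)
            row["clusters_raw"] = len(raw)
            row["clusters_merged"] = len(merged)
            row["clusters_filtered"] = len(filtered)
            majors = (
                cluster.call_major(filtered, config.major_threshold) if len(filtered) else []
            )
            row["major_ribotypes"] = [p.notation(region_start) for p in majors]
            if len(filtered) == 0:
                row["note"] = "all clusters were singletons"
            for j, p in enumerate(majors):
                label = f"{sp.name}_RT{j}"
                all_major.append((label, cluster.consensus_sequence(template, p)))
            if outdir:
                write_tsv(
                    cluster.cluster_report(filtered, template),
                    outdir / f"{sp.name}.clusters.tsv",
                )

        if config.do_variants:
            pileup = varstats.build_pileup(mapped, template)
            calls = varstats.call_variants(
                pileup,
                min_coverage=config.min_coverage,
                min_frequency=config.min_frequency,
                max_variants=config.max_variants,
            )
            a, b = template.spans[config.region]
            region_calls = [c for c in calls if a <= c.position <= b]
            n_poly, pct = varstats.polymorphic_fraction(region_calls, b - a + 1)
            row["polymorphic_sites"] = n_poly
            row["polymorphic_percent"] = pct
            read_profiles = [align.extract_profile(m, template) for m in mapped]
            ratio = varstats.sub_indel_ratio(read_profiles)
            row["reads_with_subs"] = ratio.n_reads_with_subs
            row["reads_with_indels"] = ratio.n_reads_with_indels
            row["sub_indel_ratio"] = ratio.ratio if ratio.defined else None
            spectrum = varstats.mutation_spectrum(read_profiles)
            row["top_substitution_class"] = spectrum.top_class
            if outdir:
                write_vcf_like(calls, template, outdir / f"{sp.name}.variants.vcf")
        report["species"][sp.name] = row

    if config.do_phylogeny and len(all_major) >= 3:
        tree, support = phylo.bootstrap_support(
            all_major, n_replicates=config.bootstrap_n, seed=config.seed,
        )
        newick = str(tree)
        report["tree_newick"] = newick.strip()
        report["bootstrap_supports"] = sorted(support.values())
        if outdir:
            (outdir / "ribotypes.nwk").write_text(newick)
            write_fasta(all_major, outdir / "major_ribotypes.fasta")

    loci_records = [
        (sp.name, sp.n_loci, len(report["species"][sp.name].get("major_ribotypes", [])))
        for sp in config.species
        if sp.n_loci is not None and "major_ribotypes" in report["species"].get(sp.name, {})
    ]
    if len(loci_records) >= 3:
        table, rho = phylo.locus_diversity_summary(loci_records)
        report["locus_diversity_rho"] = rho
        report["locus_diversity_n"] = len(loci_records)

    if outdir:
        (outdir / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (outdir / "run.log").write_text(_human_report(report))
    return report


def _human_report(report: dict) -> str:
    lines = ["ribodiv pipeline report", "=" * 24, "", "Parameters:"]
    for k, v in sorted(report["parameters"].items()):
        lines.append(f"  {k} = {v}")
    lines.append("")
    for name, row in report["species"].items():
        lines.append(f"Species {name}:")
        for k, v in row.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    if "locus_diversity_rho" in report:
        lines.append(
            f"Locus number vs ribotype diversity: Spearman rho = "
            f"{report['locus_diversity_rho']:.3f} (n = {report['locus_diversity_n']})"
        )
    return "\n".join(lines) + "\n"
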
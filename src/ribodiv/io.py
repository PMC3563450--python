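"""Reading and writing the standard formats used by the pipeline.

FASTA/FASTQ go through Bio.SeqIO; tables are TSV via pandas; variant
calls can be emitted as a minimal VCF-style text table. FASTQ quality
strings are constant placeholders — the analysis never uses qualities.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import UnitTemplate, derive_ribotypes
from .varstats import SiteCall

PLACEHOLDER_QUALITY = 40


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    records = []
    for name, s in reads:
        rec = SeqRecord(Seq(s), id=name, description="")
        rec.letter_annotations["phred_quality"] = [PLACEHOLDER_QUALITY] * len(s)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")]


def read_reads(path) -> list[tuple[str, str]]:
    """Load reads from FASTA or FASTQ, judged by extension."""
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return read_fastq(path)
    return read_fasta(path)


def write_template(template: UnitTemplate, path) -> None:
    """Template FASTA with the region spans recorded in the description."""
    spans = ";".join(f"{k}={a}..{b}" for k, (a, b) in template.spans.items())
    rec = SeqRecord(Seq(template.sequence), id=template.id, description=spans)
    SeqIO.write([rec], str(path), "fasta")


def read_template(path) -> UnitTemplate:
    """Load a template FASTA written by :func:`write_template`."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    spans = {}
    for part in rec.description.split()[-1].split(";"):
        name, _, rng = part.partition("=")
        a, _, b = rng.partition("..")
        spans[name] = (int(a), int(b))
    return UnitTemplate(
        id=rec.id,
        sequence=str(rec.seq).upper(),
        span_18S=spans["18S"],
        span_ITS1=spans["ITS1"],
        span_58S=spans["5.8S"],
    )


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def write_vcf_like(calls: list[SiteCall], template: UnitTemplate, path) -> None:
    """Minimal VCF-style variant table (one line per called site)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={template.id},length={len(template)}>",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage">',
        '##INFO=<ID=KIND,Number=1,Type=String,Description="SNP or DIP">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        ref = c.ref_allele or "."
        alt = c.alt_allele or "."
        info = f"AF={c.alt_frequency:.4f};DP={c.coverage};KIND={c.kind}"
        lines.append(f"{template.id}\t{c.position}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_panel_config(path, template: UnitTemplate):
    """Ribotype panel from a YAML/JSON config.

    Expected shape::

        seed: 7
        ribotypes:
          - {region: ITS1, n_subs: 0, n_indels: 0, frequency: 0.70}
          - {region: ITS1, n_subs: 1, n_indels: 0, frequency: 0.20}
          - {region: ITS1, n_subs: 3, n_indels: 0, frequency: 0.10}
    """
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    spec = [
        (r["region"], int(r.get("n_subs", 0)), int(r.get("n_indels", 0)), float(r["frequency"]))
        for r in cfg["ribotypes"]
    ]
    return derive_ribotypes(template, spec, seed=int(cfg.get("seed", 0)))
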
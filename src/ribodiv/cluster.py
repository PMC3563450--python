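"""Ribotype clustering of mapped reads by variant profile.

Reads sharing an identical variant profile form a cluster. Because
pyrosequencing indel artefacts inflate the raw cluster count, clusters are
then re-keyed on substitutions only (indel differences merged away) and
single-read clusters are dropped as probable PCR/sequencing artefacts.
The surviving clusters, ranked by abundance, are the ribotypes of the
sample; those at or above a representation threshold (5% by default) are
the major ribotypes used for phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .amplicon import UnitTemplate
from .profiles import VariantProfile, apply_profile

STAGES = ("raw", "merged", "filtered")


@dataclass(frozen=True)
class ReadCluster:
    profile: VariantProfile
    members: tuple[str, ...]
    count: int

    def __post_init__(self):
        if self.count != len(self.members) or self.count < 1:
            raise ValueError("cluster count must equal its membership size (>= 1)")


@dataclass(frozen=True)
class ClusterTable:
    species: str
    region: str
    clusters: tuple[ReadCluster, ...]
    total_reads: int
    stage: str

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        profiles = [c.profile for c in self.clusters]
        if len(set(profiles)) != len(profiles):
            raise ValueError("cluster profiles must be unique within a table")
        if self.stage in ("raw", "merged"):
            if sum(c.count for c in self.clusters) != self.total_reads:
                raise ValueError("cluster counts must sum to total_reads")

    def __len__(self):
        return len(self.clusters)

    def counts(self) -> dict[VariantProfile, int]:
        return {c.profile: c.count for c in self.clusters}


def _sorted(clusters: Iterable[ReadCluster]) -> tuple[ReadCluster, ...]:
    return tuple(
        sorted(clusters, key=lambda c: (-c.count, c.profile.notation()))
    )


def cluster_by_profile(
    profiles: Iterable[tuple[str, VariantProfile]],
    region: str,
    species: str = "",
) -> ClusterTable:
    """Group reads by identical variant profile (stage ``raw``).

    Substitutions AND indels both distinguish clusters at this stage.
    ``profiles`` yields ``(read_id, profile)`` pairs already restricted to
    the region of interest.
    """
    groups: dict[VariantProfile, list[str]] = {}
    total = 0
    for read_id, profile in profiles:
        groups.setdefault(profile, []).append(read_id)
        total += 1
    clusters = [
        ReadCluster(profile=p, members=tuple(ids), count=len(ids))
        for p, ids in groups.items()
    ]
    return ClusterTable(
        species=species, region=region, clusters=_sorted(clusters),
        total_reads=total, stage="raw",
    )


def merge_indel_clusters(table: ClusterTable) -> ClusterTable:
    """Re-key clusters on substitutions only (stage ``merged``).

    Reads from indel-bearing clusters are redistributed to the cluster
    carrying the same substitution profile; reads whose profile is pure
    indel join the reference cluster. Read totals are conserved.
    """
    if table.stage != "raw":
        raise ValueError("merge_indel_clusters expects a raw table")
    groups: dict[VariantProfile, list[str]] = {}
    for c in table.clusters:
        groups.setdefault(c.profile.substitutions, []).extend(c.members)
    clusters = [
        ReadCluster(profile=p, members=tuple(ids), count=len(ids))
        for p, ids in groups.items()
    ]
    return replace(table, clusters=_sorted(clusters), stage="merged")


def drop_singletons(table: ClusterTable) -> ClusterTable:
    """Remove single-read clusters (stage ``filtered``)."""
    if table.stage != "merged":
        raise ValueError("drop_singletons expects a merged table")
    kept = [c for c in table.clusters if c.count > 1]
    return replace(
        table,
        clusters=_sorted(kept),
        total_reads=sum(c.count for c in kept),
        stage="filtered",
    )


def abundance(table: ClusterTable) -> list[tuple[VariantProfile, float]]:
    """Per-cluster read fractions, sorted descending (ties by profile)."""
    total = sum(c.count for c in table.clusters)
    if total == 0:
        raise ValueError("cannot compute abundances of an empty table")
    return [(c.profile, c.count / total) for c in _sorted(table.clusters)]


def call_major(table: ClusterTable, threshold: float = 0.05) -> list[VariantProfile]:
    """Profiles whose abundance is >= ``threshold`` (5% default; 3% is the
    common screening alternative)."""
    return [p for p, f in abundance(table) if f >= threshold]


def consensus_sequence(template: UnitTemplate, profile: VariantProfile) -> str:
    """Sequence of the ribotype defined by ``profile`` on ``template``."""
    return apply_profile(template.sequence, profile)


def cluster_report(table: ClusterTable, template: UnitTemplate | None = None) -> pd.DataFrame:
    """Tabular view mirroring published cluster lists: id, profile in
    bracket notation (region-relative when a template is given), read
    count and percentage."""
    region_start = 1
    if template is not None and table.region in template.spans:
        region_start = template.region_start(table.region)
    total = sum(c.count for c in table.clusters)
    rows = []
    for i, c in enumerate(_sorted(table.clusters)):
        rows.append(
            {
                "cluster_id": f"{table.region}_C{i:03d}",
                "profile": c.profile.notation(region_start),
                "count": c.count,
                "percent": 100 * c.count / total if total else 0.0,
                "stage": table.stage,
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "profile", "count", "percent", "stage"])
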
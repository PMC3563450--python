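"""Recover ribotypes from noisy reads by SNP-profile clustering.

Maps 454-like reads back to the reference (Smith-Waterman, max 10
mutations per read), groups ITS1-spanning reads by their variant profile,
then merges indel-only differences and drops singleton clusters — the
two filters that collapse pyrosequencing artefact clusters. The surviving
abundances estimate the true ribotype frequencies.
"""

from ribodiv import (
    abundance,
    build_reference,
    call_major,
    cluster_by_profile,
    derive_ribotypes,
    drop_singletons,
    extract_profile,
    map_reads,
    merge_indel_clusters,
    model_454,
    simulate_reads,
)
from ribodiv.pipeline import spans_region
from ribodiv.profiles import VariantProfile

template = build_reference(seed=1)
panel = derive_ribotypes(
    template,
    [("ITS1", 0, 0, 0.70), ("ITS1", 1, 0, 0.20), ("ITS1", 3, 0, 0.10)],
    seed=7,
)
reads, _ = simulate_reads(panel, model_454(), 1000, seed=3, origin="three_prime")
mapped, rejected = map_reads(reads, template)
print(f"mapped {len(mapped)} / {len(reads)} reads ({len(rejected)} rejected)")

profiles = [
    (a.read_id,
     VariantProfile(v for v in extract_profile(a, template) if v.region == "ITS1"))
    for a in mapped
    if spans_region(a, template, "ITS1")
]
raw = cluster_by_profile(profiles, "ITS1")
filtered = drop_singletons(merge_indel_clusters(raw))
print(f"clusters: {len(raw)} raw -> {len(filtered)} after indel-merge + singleton filter")

start = template.region_start("ITS1")
print("top clusters (profile, % of retained reads):")
for profile, frac in abundance(filtered)[:4]:
    print(f"  {profile.notation(start):40s} {100 * frac:5.1f}%")
majors = call_major(filtered, threshold=0.05)
print(f"major ribotypes at the 5% rule: {len(majors)} (truth: 3)")
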
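"""Composition-based core: shared OTUs with low SDRA.

The composition method keeps the shared OTUs whose standard deviation of
relative abundance (SDRA) across the group's samples falls strictly below
a threshold (default 0.01 on the percent scale) — taxa present everywhere
at nearly identical proportions.
"""

from rhizocore import composition_core, fixture_lineages, fixture_sample_table

table = fixture_sample_table("table3")  # W-forecrop composition candidates
core = composition_core(
    table,
    "W",
    sd_threshold=0.01,
    threshold_scale="percent",
    taxonomy=fixture_lineages("table3"),
)

print(f"{'OTU':8s} {'taxonomy':24s} mean RA (%)   SDRA")
for m in core.members:
    print(f"{m.otu_id:8s} {m.taxonomy:24s} {m.mean_ra:.4f}      {m.sd_ra:.4f}")
print(f"{len(core)} of 10 candidates retained; total {core.total_core_abundance:.4f}%")

# 8 of the 10 shared candidates pass the 0.01 SDRA cut; the two most
# abundant (Hyphomicrobiaceae OTU1, Nitrospira OTU3) are too variable
# across samples to count as composition-core members.
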
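"""Membership-based ("top-10") core from the bundled reference community.

Expands the bundled W-forecrop summary table into a 4-sample community,
ranks the OTUs shared by all four samples by mean relative abundance and
keeps the top 10.
"""

from rhizocore import fixture_lineages, fixture_sample_table, membership_core

table = fixture_sample_table("table1")  # 4 wheat-forecrop rhizosphere samples
core = membership_core(table, "W", top_n=10, taxonomy=fixture_lineages("table1"))

print(f"{'OTU':8s} {'taxonomy':24s} mean RA (%)")
for m in core.members:
    print(f"{m.otu_id:8s} {m.taxonomy:24s} {m.mean_ra:.4f}")
print(f"total core abundance: {core.total_core_abundance:.4f}%")

# The top-10 shared OTUs jointly make up ~0.198% of the community: the
# membership core is ubiquitous but individually rare.
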
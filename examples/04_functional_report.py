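"""Summarize regulated proteins by functional category.

Runs the differential pipeline on a synthetic experiment, assigns each
protein a functional group from a user-style accession->group map, and
prints the per-category counts and the headline totals table (Total /
Up-regulated / Down-regulated / Absent / Absent-baseline per contrast).
"""

from spotdiff import report, synthdata

gels, truths = synthdata.generate_experiment(
    synthdata.SyntheticConfig(n_proteins=100, seed=1)
)
comparisons, proteins = report.analyze_experiment(gels, use_spot_ids=True)

# toy annotation: spread the synthetic proteins over the 13 categories
annotation = {
    p.accession: report.DEFAULT_GROUPS[i % len(report.DEFAULT_GROUPS)]
    for i, p in enumerate(proteins)
}
annotated = report.assign_groups(proteins, annotation)

print("headline counts per stage contrast:")
print(report.overall_summary(annotated))
print("\nper-category table, P7 vs P90:")
print(report.summarize(annotated, "P7"))
# rel_freq is each category's share of all regulated proteins at that stage.
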
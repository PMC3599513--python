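"""Stage-resolved expression of a synthetic cohort.

Computes RPKM from planted stage-structured counts, the per-category
temporal specificity scores (1 - H/log2 N), and the late-stage
peak-enrichment chi-square between orphan and clade-specific genes.
"""

from lineagescan.cohort import CohortConfig, classify_cohort, generate_cohort
from lineagescan.expression import (
    SampleInfo,
    compute_rpkm,
    late_stage_enrichment,
    peak_stage,
    specificity_contrast,
    specificity_scores,
)

cohort = generate_cohort(CohortConfig(seed=1))
calls = classify_cohort(cohort)

samples = [
    SampleInfo(r.sample_id, r.stage, r.hours_post_fertilization,
               r.stage_class, r.total_valid_reads)
    for r in cohort.sample_meta.itertuples()
]
exon_lengths = {g: m.exon_union_length() for g, m in cohort.models.items()}
rpkm = compute_rpkm(cohort.counts, exon_lengths, samples)

scores = specificity_scores(rpkm)
contrast = specificity_contrast(scores, calls)
print("mean temporal specificity per category (0 = uniform, 1 = one stage):")
for cat, m in sorted(contrast.means.items()):
    print(f"  {cat:<8} {m:.3f}")
print(f"ANOVA across categories: F = {contrast.f_statistic:.1f}, "
      f"p = {contrast.p_value:.3g}")

stage_class = dict(zip(cohort.sample_meta["stage"],
                       cohort.sample_meta["stage_class"]))
peaks = {g: peak_stage(rpkm.loc[g]) for g in rpkm.index}
enr = late_stage_enrichment(peaks, calls, stage_class, "ORPHAN", "CTSG")
print(f"\nlate-stage peaks: orphans {enr['late_1']}/{enr['n_1']} "
      f"({enr['percent_1']:.1f}%) vs clade-specific {enr['late_2']}/{enr['n_2']} "
      f"({enr['percent_2']:.1f}%); chi2 = {enr['chi2']:.2f}, "
      f"p = {enr['p_value']:.3f}")
# Lineage-specific genes are planted stage-restricted (conserved genes
# uniform), so their specificity means sit near 1 and the ANOVA is
# decisive; the late-peak contrast reflects the planted late bias.
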
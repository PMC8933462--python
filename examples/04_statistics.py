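"""The repeated-measures statistical stage on a synthetic cohort.

Runs a cohort, then the full statistics pipeline: Shapiro-Wilk routing
into Friedman + Wilcoxon signed-rank (non-normal metrics, e.g. the
discrete signal strength) or repeated-measures ANOVA (flow metrics), each
with Bonferroni-corrected pairwise comparisons, plus pooled Pearson
correlations of signal strength against every flow metric.  Expect the
CC flow-deficit correlation to be strongly negative on both devices.
"""

from octaquant import analyze_cohort, run_cohort

cohort = run_cohort(n_subjects=6, seed=5)
analysis = analyze_cohort(cohort.means)

print("omnibus tests (one row per device/slab/metric):")
cols = ["device_model", "slab", "metric", "test", "omnibus_p"]
print(analysis.table1[cols].to_string(index=False))

print("\ncorrelations of signal strength with each flow metric:")
cols = ["device_model", "slab", "metric", "r", "p_value", "slope"]
print(analysis.table2[cols].round(4).to_string(index=False))
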
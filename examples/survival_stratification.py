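"""Percentile-union expression stratification and survival comparison.

Generates a 40-patient metastatic cohort whose hazard depends on a
hidden High label, stratifies by the 75%-quantile union over the
SRC/FYN/YES1 panel, and compares the groups with Kaplan-Meier medians,
the log-rank test and the O/E hazard ratio.
"""

from chemoresist import (
    RunConfig, StratificationRule, gen_survival, km_fit, km_median,
    logrank_test, stratify,
)

config = RunConfig(seed=11)
expr, cohort, truth = gen_survival(config, n=40, hr=3.2)

rule = StratificationRule(["SRC", "FYN", "YES1"], q=config.quantile_q)
labels = stratify(expr, rule)
cohort = cohort.with_group(labels)
n_high = int((labels == "High").sum())
print(f"stratification: {n_high}/40 samples High "
      f"(>{rule.q:.0%} quantile in >= 1 of {rule.genes})")

curves = km_fit(cohort)
for group, curve in sorted(curves.items()):
    med = km_median(curve)
    print(f"  {group}: n={curve.n}, median disease-free interval = "
          f"{'undefined' if med is None else f'{med:.1f} months'}")

res = logrank_test(cohort, group_order=("Low", "High"))
print(f"log-rank: chi2 = {res.chi_square:.2f}, p = {res.p_value:.4f}, "
      f"O/E hazard ratio (High vs Low) = {res.hazard_ratio:.2f}")
print("An HR above 1 with a small p says the High-expression group progresses"
      " to metastasis faster; the O/E ratio understates large true ratios when"
      " nearly all patients have events.")
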
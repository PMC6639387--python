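"""Correlation analysis of biomarkers against MMSE, age and education.

Simulates a cohort, computes Pearson correlations by sex with Bonferroni
adjustment, compares the female and male coefficients (Fisher Z + Zou CI),
and compares two dependent correlations sharing the MMSE (Meng Z).
"""

from eegslow import (
    CohortSimParams,
    fisher_z_independent,
    meng_z_dependent,
    partial_pearson,
    pearson_ci,
    simulate_cohort,
)

table, _ = simulate_cohort(CohortSimParams(n_subjects=496, seed=12), eeg=False)
male, female = table[table.sex == 0], table[table.sex == 1]

print("Pearson r of MDF with MMSE total (95% CI, Bonferroni m=3):")
for name, grp in (("total", table), ("male", male), ("female", female)):
    r = pearson_ci(grp["mdf"], grp["mmse_total"], bonferroni_m=3)
    print(f"  {name:6s} r={r.estimate:+.3f}  CI=({r.ci_low:+.3f}, {r.ci_high:+.3f})"
          f"  p={r.p:.2e}  n={r.n}")

rf = pearson_ci(female["mdf"], female["mmse_total"])
rm = pearson_ci(male["mdf"], male["mmse_total"])
comp = fisher_z_independent(rf.estimate, rf.n, rm.estimate, rm.n)
print(f"female - male difference: {comp.delta:+.3f} "
      f"(Zou CI {comp.ci_low:+.3f} to {comp.ci_high:+.3f}, p={comp.p:.3f})")
print("  -> a CI covering 0 means no sex difference in the correlation")

r_mdf = pearson_ci(table["mdf"], table["mmse_total"]).estimate
r_pf = pearson_ci(table["pf"], table["mmse_total"]).estimate
r_mdf_pf = pearson_ci(table["mdf"], table["pf"]).estimate
meng = meng_z_dependent(r_mdf, r_pf, r_mdf_pf, len(table))
print(f"MDF vs PF as MMSE correlates (Meng Z): z={meng.z:+.2f} p={meng.p:.3f}")

part = partial_pearson(table["mdf"], table["mmse_total"],
                       covariates=table[["sex", "age", "edu"]].to_numpy())
print(f"partial r(MDF, MMSE | sex, age, edu) = {part.estimate:+.3f} "
      "(association left after demographics)")
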
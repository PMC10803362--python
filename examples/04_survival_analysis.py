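"""Density cut-off scan, selection, Cox hazard ratio and necrosis cross-tab.

A synthetic cohort is generated under a proportional-hazards model in
which patients at or above a planted density cut-off of 400 cells/mm²
have a 4.5-fold event hazard. The scan tests every 50/mm² cut-off with
log-rank tests on both endpoints (DSS, MFS) and selects, among cut-offs
significant on both, the one that best balances group sizes.
"""

from viadens.survival import (
    compare_distributions, cox_univariate, crosstab_necrosis, cutoff_scan,
    select_cutoff, stratify,
)
from viadens.synthdata import CohortSpec, generate_cohort

cohort = generate_cohort(
    CohortSpec(n_patients=200, true_cutoff=400.0, hazard_ratio_high=4.5, seed=2)
)
rows = cutoff_scan(cohort, step=50.0, min_group=5)
significant = [r.cutoff for r in rows
               if r.evaluable and r.p_dss < 0.05 and r.p_mfs < 0.05]
selected = select_cutoff(rows, alpha=0.05)
print(f"scanned {len(rows)} cut-offs; significant on both endpoints: "
      f"{significant[0]:.0f}-{significant[-1]:.0f}/mm²")
print(f"selected cut-off (balance rule): {selected:.0f}/mm² "
      f"(planted truth: 400/mm²)")

high = stratify(cohort, selected)
for endpoint in ("dss", "mfs"):
    cox = cox_univariate(cohort[f"{endpoint}_months"],
                         cohort[f"{endpoint}_event"], high)
    print(f"{endpoint.upper()}: HR={cox.hr:.2f} "
          f"(95% CI {cox.ci_low:.2f}-{cox.ci_high:.2f}, p={cox.p:.2e})")

xt = crosstab_necrosis(cohort, selected, necrosis_threshold=90.0)
print(f"necrosis cross-tab: low/good={xt.n_low_good} high/good={xt.n_high_good} "
      f"low/poor={xt.n_low_poor} high/poor={xt.n_high_poor}; "
      f"discordance among poor-necrosis cases: {100*xt.discordance_fraction:.1f}%")

p = compare_distributions(
    cohort.density_per_mm2[:10].tolist(), cohort.density_per_mm2[10:20].tolist()
)
print(f"rank-sum p between two density subsamples: {p:.3f}")
print("-> the high-density group carries the planted excess hazard; the "
      "density call disagrees with dichotomized necrosis in a large share "
      "of poor-necrosis cases, mirroring how the two readouts can diverge")
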
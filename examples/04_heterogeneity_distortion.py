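"""How latent heterogeneity inflates random-effect correlations.

A cohort containing a small, rapidly progressing subgroup violates the
homogeneous-population assumption of the bivariate mixed model.  Because the
progressive subjects sit low on both outcomes and decline fast on both, the
unadjusted fit absorbs the group contrast into the random-effect covariance
and reports strongly inflated intercept and slope correlations — the
generating values here are only 0.146 and 0.111.

We run a small version of the mixing-fraction scenario (the full protocol
uses 150-500 replicates; see scripts/acceptance.py) and then show that adding
the group label as an intercept-and-slope covariate removes the distortion.
"""

from dataclasses import replace

import pandas as pd

from bivlmm import (
    LongitudinalDataset,
    fit_blmm,
    glaucoma_presets,
    re_correlations,
    run_scenario,
    simulate_dataset,
)

res = run_scenario("A", levels=[0.0, 0.05, 0.20], n_replicates=20, seed=123)
print("fraction progressive -> mean fitted correlations (20 replicates):")
print("  level   rho_intercept   rho_slope")
for r in res.results:
    print(f"  {r.level:5.2f}   {r.rho_intercept_mean:13.3f}   {r.rho_slope_mean:9.3f}")

spec = replace(glaucoma_presets(), p_progressive=0.20, group_assignment="fixed")
data, labels = simulate_dataset(spec, seed=9)
cov = pd.DataFrame({"group": labels.astype(float)},
                   index=pd.Index(data.subjects, name="subject_id"))
data = LongitudinalDataset.from_frames(data.obs, "Y1", "Y2", covariates=cov)

naive = fit_blmm(data, covariate_names=[], compute_se=False)
adjusted = fit_blmm(data, covariate_names=["group"],
                    slope_covariate_names=["group"], compute_se=False)

n, a = re_correlations(naive.re_cov), re_correlations(adjusted.re_cov)
print(f"\none 20%-progressive dataset:")
print(f"  unadjusted fit: rho_intercept {n.rho_intercept:.3f}, rho_slope {n.rho_slope:.3f}")
print(f"  group-adjusted: rho_intercept {a.rho_intercept:.3f}, rho_slope {a.rho_slope:.3f}")
print("modeling the known subgroup removes the upward distortion (one dataset "
      "is noisy; the replicate averages above are the reliable summary).")
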
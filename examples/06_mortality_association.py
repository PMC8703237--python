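"""Associate surrogates with all-cause mortality in family-clustered data.

Plants survival times with a hazard ratio of 1.6 per unit of one phenotype,
fits per-term Cox models with Huber sandwich standard errors clustered by
family, applies BH correction per stratum, and runs the stepwise AIC search.
"""

import warnings

import numpy as np

import metabosurr as ms

cfg = ms.demo_config(seed=6, n_cohorts=4, cohort_size=400)
ds, truth = ms.generate_dataset(cfg)
ds = ms.plant_survival(ds, {"planted_auc90": np.log(1.6)}, censor_rate=0.2,
                       n_families=120, seed=7, frailty_variance=0.3,
                       truth=truth)

terms = ["planted_auc90", "planted_auc50"]
assocs = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for term in terms:
        assocs.append(ms.cox_association(ds.df, term,
                                         covariates=["age", "sex"],
                                         cluster_col="family_id",
                                         per_sd=False))
    ms.stratified_fdr(assocs)
    trace = ms.stepwise_cox(ds.df, candidates=terms,
                            fixed_covariates=["age", "sex"],
                            cluster_col="family_id")

for a in assocs:
    print(f"{a.term}: HR {a.hazard_ratio:.2f} "
          f"[{a.ci_low:.2f}, {a.ci_high:.2f}], robust p {a.p:.2g}, "
          f"FDR {a.fdr:.2g}, significant={a.significant}")
print("stepwise kept:", trace.selected,
      f"(final AIC {trace.final_aic:.1f}, {len(trace.steps)} steps)")
# The planted-hazard term keeps an HR near 1.6 (slightly attenuated by the
# shared family frailty) and survives both BH and the AIC search; the null
# term does not.
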
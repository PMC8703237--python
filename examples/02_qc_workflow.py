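"""Quality control on a corrupted marker table.

Injects missing cells, zeros and >5-SD outliers into a clean dataset, runs
the three sample filters, NIPALS imputation and z-scaling, and checks the
removals against the exact injection mask.
"""

import metabosurr as ms

cfg = ms.demo_config(seed=2, n_cohorts=4, cohort_size=250)
ds, _ = ms.generate_dataset(cfg)
corrupted, mask = ms.inject_artifacts(ds, missing_rate=0.001,
                                      zero_rate=0.0005, outlier_rate=0.0005,
                                      seed=3)

kept, report = ms.run_qc(corrupted, cfg.panel)
print(f"input {report.n_input} -> kept {report.n_kept}")
print(f"  removed: {report.n_removed_missing} missing, "
      f"{report.n_removed_zero} zero, {report.n_removed_outlier} outlier")
print(f"  injected artifact samples: {len(mask.samples('missing'))} missing, "
      f"{len(mask.samples('zero'))} zero, "
      f"{len(mask.samples('outlier'))} outlier")
# The missing/zero removals match the injected samples exactly; the outlier
# rule also trims the natural log-normal tail, so its count exceeds the
# injected outliers.
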
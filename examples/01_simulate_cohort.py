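"""Generate a synthetic two-arm chemotherapy cohort and inspect its shape.

The generator draws proportional-hazards survival times (PFS and OS, in
months) for an intraperitoneal (IP) and an intravenous-only (IV) arm,
expression for two correlated platforms, and registry-style missingness.
"""

from routesurv import simulate

cohort = simulate.make_fixture("tcga_like", seed=7)
clin = cohort.clinical

print(f"cases: {len(clin)} ({(clin.route == 'IP').sum()} IP, {(clin.route == 'IV').sum()} IV)")
print(f"microarray: {cohort.microarray.values.shape[0]} genes x "
      f"{cohort.microarray.values.shape[1]} samples")
print(f"rnaseq:     {cohort.rnaseq.values.shape[0]} genes x "
      f"{cohort.rnaseq.values.shape[1]} samples (subset of microarray cases)")
print(f"PFS observed event fraction: {clin.pfs_event.dropna().astype(bool).mean():.2f}")
print(f"missing OS outcomes: {clin.os_months.isna().mean():.1%}")
print("planted truth:", cohort.truth["predictive_genes"])
# The truth block records the generating coefficients, so downstream
# stages can be scored against what was actually simulated.
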
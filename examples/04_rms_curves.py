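"""Restricted-mean-survival curves over normalized relative expression.

For one gene and one arm, a univariate Cox model of the endpoint on the
relative expression quantile q in [0, 1] is integrated to tau = 60 months,
giving expected event-free months as a function of where a tumor sits in
the cohort's expression distribution, with bootstrap 95% bands.
"""

from routesurv import rms_perm, simulate
from routesurv.cohort import truncate_survival

cohort = simulate.make_fixture("predictive_gene_demo", seed=11)
clin = truncate_survival(cohort.clinical)

gene = "PRED_IV1"  # planted: harmful with expression in the IV arm only
raw = cohort.microarray.values.loc[gene, clin.case_id]
q = rms_perm.normalize_relative_expression(raw.to_numpy(), index=clin.case_id.to_numpy())

for arm in ("IP", "IV"):
    curve = rms_perm.rms_curve(clin, q, gene, arm, "PFS",
                               grid_resolution=5, n_bootstrap=100, seed=3)
    print(f"{arm} arm, PFS RMS (months) at q = 0, 0.25, 0.5, 0.75, 1:")
    for qq, r, lo, hi in zip(curve.grid, curve.rms, curve.ci_lower, curve.ci_upper):
        print(f"  q={qq:.2f}: {r:5.1f}  [{lo:.1f}, {hi:.1f}]")
# The IV curve should fall with q (high expressors progress sooner under
# IV), while the IP curve stays roughly flat - the signature of a
# route-specific (predictive) gene.
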
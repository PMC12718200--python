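"""Quantify agreement between the three indices.

Continuous totals are compared with Spearman rank correlation; tertile
classifications with weighted kappa (linear disagreement weights).  WCRF and
EHLI share several components (BMI, activity, alcohol, meat, sugary drinks),
so they should agree far more strongly than either does with the diet-only
MDS.
"""

from dietlife import apply_exclusion_cascade, make_exclusion_fixture, pairwise_agreement
from dietlife.report import _score_samples

cohort = make_exclusion_fixture(157, 6, 1, 3, seed=11)
_, diet_only, diet_lifestyle = apply_exclusion_cascade(cohort)
_, scored_dl = _score_samples(diet_only, diet_lifestyle)

table = pairwise_agreement(
    scored_dl[["mds_total", "wcrf_total", "ehli_total"]].rename(
        columns=lambda c: c.removesuffix("_total")),
    scored_dl[["mds_tertile", "wcrf_tertile", "ehli_tertile"]].rename(
        columns=lambda c: c.removesuffix("_tertile")))

for _, r in table.iterrows():
    print(f"{r['pair']:10s} Spearman rho = {r.spearman_rho:5.2f} "
          f"(p = {r.spearman_p:.2g}); weighted kappa = {r.weighted_kappa:5.2f} "
          f"(p = {r.kappa_p:.2g}); n = {r.n}")
print("\nrho near 1 = same participant ordering; kappa near 1 = same "
      "tertile classifications beyond chance")
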
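"""Apply the energy/demographics/activity exclusion cascade.

A fixture of 157 questionnaire completers is built with exactly 6
energy-implausible records (outside 2568-17031 kJ/d), 1 missing a baseline
demographic field and 3 missing physical activity.  The cascade removes them
in that order, producing the diet-only (n=150) and diet+lifestyle (n=147)
analytic samples.
"""

from dietlife import (
    KJ_PER_KCAL,
    apply_exclusion_cascade,
    compute_energy_bounds,
    make_exclusion_fixture,
)

cohort = make_exclusion_fixture(157, 6, 1, 3, seed=11)
lo, hi = compute_energy_bounds(cohort, mode="fixed")
print(f"plausibility window: {lo:.0f}-{hi:.0f} kJ/d "
      f"(~{lo / KJ_PER_KCAL:.0f}-{hi / KJ_PER_KCAL:.0f} kcal/d)")

report, diet_only, diet_lifestyle = apply_exclusion_cascade(cohort, (lo, hi))
print(f"questionnaire completers: {report.n_ffq_complete}")
print(f"excluded - energy: {report.n_excluded_energy}, demographics: "
      f"{report.n_excluded_demog}, activity: {report.n_excluded_pa}")
print(f"diet-only analytic sample: {report.n_diet_only}")
print(f"diet+lifestyle analytic sample: {report.n_diet_lifestyle}")
# each excluded record carries one primary reason (first failing criterion)
print(f"per-record reasons: {report.reasons}")
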
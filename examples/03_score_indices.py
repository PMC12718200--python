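"""Score the three diet/lifestyle quality indices and assign tertiles.

MDS components are scored 0/1 against cohort-internal medians (so it must
be computed on the analytic sample); WCRF/AICR (modified, 6 components) and
EHLI (9 components) grade each behaviour 1 / 0.5 / 0 against fixed
cut-points.  Tertile 3 of each total flags "good" overall quality.
"""

from dietlife import (
    apply_exclusion_cascade,
    assign_tertiles,
    compute_ehli,
    compute_mds,
    compute_wcrf_modified,
    make_exclusion_fixture,
)

cohort = make_exclusion_fixture(157, 6, 1, 3, seed=11)
_, diet_only, diet_lifestyle = apply_exclusion_cascade(cohort)

mds = compute_mds(diet_only)
wcrf = compute_wcrf_modified(diet_lifestyle)
ehli = compute_ehli(diet_lifestyle)

for name, scores, total_col, rng in (("MDS", mds, "mds_total", "0-9"),
                                     ("WCRF/AICR", wcrf, "wcrf_total", "0-6"),
                                     ("EHLI", ehli, "ehli_total", "0-9")):
    totals = scores[total_col]
    tert = assign_tertiles(totals)
    good = tert["good_quality"].mean()
    print(f"{name:10s} (range {rng}): mean {totals.mean():.1f} "
          f"(SD {totals.std(ddof=1):.1f}); good quality (tertile 3): {good:.1%}")

# component-level adherence = scoring the component maximum
adherent = mds.filter(like="_adherent").mean().round(3)
print("\nMDS component adherence proportions:")
print(adherent.to_string())
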
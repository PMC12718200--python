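"""Fit the full per-SD association grid and tier the evidence.

Each of 3 index exposures is z-standardised and regressed against 17
outcomes with per-index covariate sets (BMI/activity/smoking omitted where
the index already embeds them).  Glycemic outcomes are modelled on the log
scale and exponentiated, so those estimates are multiplicative per-SD
effects.  Evidence tiers use a Bonferroni family of 3 x 17 = 51
comparisons: strong means p < 0.05/51 ~ 0.001, nominal means p < 0.05.
"""

import numpy as np
import pandas as pd

from dietlife import (
    EffectSpec,
    apply_exclusion_cascade,
    make_exclusion_fixture,
    plant_effects,
    run_model_grid,
    score_outcomes,
)
from dietlife.report import _score_samples

cohort = make_exclusion_fixture(157, 6, 1, 3, seed=11)
_, diet_only, diet_lifestyle = apply_exclusion_cascade(cohort)
scored_do, scored_dl = _score_samples(diet_only, diet_lifestyle)
frames = []
for frame in (scored_do, scored_dl):
    panel = score_outcomes(frame)
    frame = pd.concat(
        [frame, panel[panel.columns.difference(frame.columns)]], axis=1)
    frame["comorbidity_cat"] = np.where(frame.comorbidity_count >= 1, "1+", "0")
    frames.append(frame)
scored_do, scored_dl = frames

# plant a known multiplicative effect: each SD of EHLI lowers HOMA-IR by 8%
scored_dl = plant_effects(scored_dl, EffectSpec(
    exposure="ehli_total", outcome="homa_ir", beta_per_sd=np.log(0.92),
    noise_sd=0.0, log_outcome=True), seed=3)

grid = run_model_grid(scored_do, scored_dl, alpha=0.05, family=51)
print(f"grid cells: {len(grid)} (fitted {int((~grid.skipped).sum())}, "
      f"structurally skipped {int(grid.skipped.sum())})")
print(f"Bonferroni threshold: 0.05/51 = {0.05 / 51:.5f}")

row = grid[(grid.exposure == "ehli") & (grid.outcome == "homa_ir")].iloc[0]
print(f"\nplanted EHLI->HOMA-IR effect recovered: Exp(beta) = "
      f"{row.estimate:.2f} (planted 0.92), tier = {row.tier}")

print("\nstrongest associations in this synthetic run:")
fitted = grid[~grid.skipped].nsmallest(3, "p_value")
for _, r in fitted.iterrows():
    scale = "Exp(beta)" if r.log_outcome else "beta"
    print(f"  {r.exposure:5s} -> {r.outcome:15s} {scale} = {r.estimate:6.3f} "
          f"[{r.ci_low:.3f}, {r.ci_high:.3f}] p = {r.p_value:.3g} ({r.tier}), "
          f"n = {r.n_used}")
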
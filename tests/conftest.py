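import numpy as np
import pandas as pd
import pytest

from dietlife import apply_exclusion_cascade, make_exclusion_fixture, score_outcomes
from dietlife.report import _score_samples


@pytest.fixture(scope="session")
def fixture_cohort() -> pd.DataFrame:
    """157-record cohort with 6 energy-implausible, 1 demographics-missing
    and 3 activity-missing records planted on disjoint rows."""
    return make_exclusion_fixture(157, 6, 1, 3, seed=11)


@pytest.fixture(scope="session")
def analytic_samples(fixture_cohort):
    """Scored diet-only and diet+lifestyle analytic samples with outcomes."""
    _, diet_only, diet_lifestyle = apply_exclusion_cascade(fixture_cohort)
    scored_do, scored_dl = _score_samples(diet_only, diet_lifestyle)
    out = []
    for frame in (scored_do, scored_dl):
        panel = score_outcomes(frame)
        merged = pd.concat(
            [frame, panel.drop(columns=[c for c in panel if c in frame])], axis=1)
        merged["comorbidity_cat"] = np.where(
            merged["comorbidity_count"] >= 1, "1+", "0")
        out.append(merged)
    return tuple(out)
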
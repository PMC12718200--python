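"""Composite index scoring: MDS medians, WCRF/EHLI cut-points, tertiles."""

import numpy as np
import pandas as pd
import pytest

from dietlife import (
    CutpointConfig,
    assign_tertiles,
    compute_ehli,
    compute_mds,
    compute_wcrf_modified,
)
from dietlife.indices import EHLI_COMPONENTS, MDS_COMPONENTS, WCRF_COMPONENTS


def lifestyle_record(**overrides) -> pd.DataFrame:
    """One-row frame with every column the WCRF/EHLI scorers need."""
    row = {
        "bmi": 47.0, "physical_activity": 0.0, "energy_density": 2.0,
        "sugary_drinks": 300.0, "fruit_nuts": 100.0, "vegetables": 80.0,
        "legumes": 5.0, "fiber": 10.0, "red_meat": 120.0,
        "processed_meat": 40.0, "alcohol": 30.0, "smoking": "current",
        "whole_grains": 20.0, "dairy": 900.0,
    }
    row.update(overrides)
    return pd.DataFrame([row])


FULL_WCRF = dict(bmi=22.0, physical_activity=300.0, energy_density=1.0,
                 sugary_drinks=0.0, fruit_nuts=250.0, vegetables=200.0,
                 legumes=30.0, fiber=35.0, red_meat=0.0, processed_meat=0.0,
                 alcohol=0.0)
FULL_EHLI = dict(FULL_WCRF, smoking="never", whole_grains=150.0, dairy=300.0)


# --- MDS ---------------------------------------------------------------------

def _mds_oracle(frame: pd.DataFrame) -> list[float]:
    """Exhaustive hand-style recomputation: medians and comparisons in plain
    Python, independent of the vectorised implementation."""

    def median(vals):
        s = sorted(vals)
        n = len(s)
        return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2

    ratios = [m / s for m, s in zip(frame["mufa"], frame["sfa"])]
    meats = [r + p for r, p in zip(frame["red_meat"], frame["processed_meat"])]
    med = {c: median(frame[c]) for c in
           ["fruit_nuts", "vegetables", "cereals", "legumes", "fish_seafood", "dairy"]}
    med["ratio"], med["meat"] = median(ratios), median(meats)
    totals = []
    for i in range(len(frame)):
        t = 0
        for c in ["fruit_nuts", "vegetables", "cereals", "legumes", "fish_seafood"]:
            t += frame[c].iloc[i] >= med[c]
        t += ratios[i] >= med["ratio"]
        t += frame["dairy"].iloc[i] < med["dairy"]
        t += meats[i] < med["meat"]
        t += 5 <= frame["alcohol"].iloc[i] < 25
        totals.append(float(t))
    return totals


def test_mds_matches_brute_force_oracle_on_toy_cohort():
    toy = pd.DataFrame({
        "fruit_nuts": [100, 200, 150, 50], "vegetables": [300, 100, 200, 250],
        "cereals": [120, 180, 90, 200], "legumes": [10, 40, 25, 5],
        "fish_seafood": [20, 60, 35, 10], "mufa": [25, 40, 30, 20],
        "sfa": [35, 25, 30, 40], "dairy": [200, 500, 350, 150],
        "red_meat": [60, 120, 80, 40], "processed_meat": [20, 50, 10, 30],
        "alcohol": [0.0, 10.0, 30.0, 5.0],
    })
    scored = compute_mds(toy)
    assert list(scored["mds_total"]) == _mds_oracle(toy)


@pytest.mark.parametrize("grams,score", [(0.0, 0), (4.9, 0), (5.0, 1),
                                         (10.0, 1), (24.9, 1), (25.0, 0), (40.0, 0)])
def test_mds_alcohol_window_half_open(grams, score):
    toy = pd.DataFrame({
        "fruit_nuts": [1, 2], "vegetables": [1, 2], "cereals": [1, 2],
        "legumes": [1, 2], "fish_seafood": [1, 2], "mufa": [1, 2],
        "sfa": [1, 1], "dairy": [1, 2], "red_meat": [1, 2],
        "processed_meat": [0, 0], "alcohol": [grams, 0.0],
    })
    assert compute_mds(toy)["mds_alcohol"].iloc[0] == score


def test_mds_at_median_scores_one_for_beneficial_components():
    """A participant exactly at the median of all six beneficial components,
    above median for dairy and meat, and a non-drinker totals 6."""
    toy = pd.DataFrame({
        "fruit_nuts": [100, 100, 100], "vegetables": [50, 50, 50],
        "cereals": [80, 80, 80], "legumes": [10, 10, 10],
        "fish_seafood": [30, 30, 30], "mufa": [30, 30, 30], "sfa": [30, 30, 30],
        "dairy": [400, 200, 100], "red_meat": [150, 50, 20],
        "processed_meat": [0, 0, 0], "alcohol": [0.0, 10.0, 10.0],
    })
    assert compute_mds(toy)["mds_total"].iloc[0] == 6.0


def test_mds_median_shift_invariance():
    """Adding a constant to every participant's value for one component moves
    the median equally, so all component scores are unchanged."""
    rng = np.random.default_rng(0)
    toy = pd.DataFrame({c: rng.lognormal(4, 0.5, 30) for c in
                        ["fruit_nuts", "vegetables", "cereals", "legumes",
                         "fish_seafood", "mufa", "sfa", "dairy",
                         "red_meat", "processed_meat"]})
    toy["alcohol"] = rng.uniform(0, 30, 30)
    before = compute_mds(toy)
    shifted = toy.copy()
    shifted["vegetables"] = shifted["vegetables"] + 123.4
    after = compute_mds(shifted)
    comp_cols = [f"mds_{c}" for c in MDS_COMPONENTS]
    pd.testing.assert_frame_equal(before[comp_cols], after[comp_cols])


def test_mds_monotone_in_beneficial_component():
    rng = np.random.default_rng(1)
    toy = pd.DataFrame({c: rng.lognormal(4, 0.5, 20) for c in
                        ["fruit_nuts", "vegetables", "cereals", "legumes",
                         "fish_seafood", "mufa", "sfa", "dairy",
                         "red_meat", "processed_meat"]})
    toy["alcohol"] = 0.0
    base_total = compute_mds(toy)["mds_total"]
    bumped = toy.copy()
    bumped.loc[bumped.index[0], "fish_seafood"] *= 10
    # medians shift, but the bumped record's own total cannot decrease
    assert compute_mds(bumped)["mds_total"].iloc[0] >= base_total.iloc[0] - 1e-12


def test_mds_zero_sfa_treated_as_infinite_ratio():
    toy = pd.DataFrame({
        "fruit_nuts": [1, 1], "vegetables": [1, 1], "cereals": [1, 1],
        "legumes": [1, 1], "fish_seafood": [1, 1],
        "mufa": [30.0, 20.0], "sfa": [0.0, 20.0],
        "dairy": [1, 2], "red_meat": [1, 2], "processed_meat": [0, 0],
        "alcohol": [0.0, 0.0],
    })
    assert compute_mds(toy)["mds_mufa_sfa_ratio"].iloc[0] == 1.0


# --- WCRF / EHLI -------------------------------------------------------------

def test_wcrf_theoretical_maximum_and_floor():
    assert compute_wcrf_modified(lifestyle_record(**FULL_WCRF))["wcrf_total"].iloc[0] == 6.0
    assert compute_wcrf_modified(lifestyle_record())["wcrf_total"].iloc[0] == 0.0


@pytest.mark.parametrize("bmi", [30.0, 35.0, 47.5, 60.0])
def test_wcrf_bmi_component_zero_for_obese_range(bmi):
    scored = compute_wcrf_modified(lifestyle_record(bmi=bmi))
    assert scored["wcrf_bmi"].iloc[0] == 0.0


@pytest.mark.parametrize("pa,expected", [(150.0, 1.0), (149.0, 0.5),
                                         (75.0, 0.5), (74.0, 0.0)])
def test_wcrf_activity_grading(pa, expected):
    scored = compute_wcrf_modified(lifestyle_record(physical_activity=pa))
    assert scored["wcrf_physical_activity"].iloc[0] == expected


def test_wcrf_missing_activity_flags_unscoreable_not_dropped():
    rec = lifestyle_record(physical_activity=np.nan)
    scored = compute_wcrf_modified(rec)
    assert len(scored) == 1
    assert not scored["wcrf_scoreable"].iloc[0]
    assert np.isnan(scored["wcrf_total"].iloc[0])


def test_ehli_maximum_floor_and_smoking():
    assert compute_ehli(lifestyle_record(**FULL_EHLI))["ehli_total"].iloc[0] == 9.0
    assert compute_ehli(lifestyle_record())["ehli_total"].iloc[0] == 0.0
    never = compute_ehli(lifestyle_record(smoking="never"))
    current = compute_ehli(lifestyle_record(smoking="current"))
    former = compute_ehli(lifestyle_record(smoking="former"))
    assert never["ehli_smoking"].iloc[0] == 1.0
    assert former["ehli_smoking"].iloc[0] == 0.5
    assert current["ehli_smoking"].iloc[0] == 0.0


def test_reducing_meat_never_lowers_wcrf_or_ehli():
    for red, proc in [(120.0, 40.0), (80.0, 10.0), (10.0, 2.0), (0.0, 0.0)]:
        high = lifestyle_record(red_meat=red, processed_meat=proc)
        lower = lifestyle_record(red_meat=red / 2, processed_meat=proc / 2)
        assert (compute_wcrf_modified(lower)["wcrf_total"].iloc[0]
                >= compute_wcrf_modified(high)["wcrf_total"].iloc[0])
        assert (compute_ehli(lower)["ehli_total"].iloc[0]
                >= compute_ehli(high)["ehli_total"].iloc[0])


def test_score_bounds_on_random_inputs():
    rng = np.random.default_rng(42)
    n = 500
    frame = pd.DataFrame({
        "bmi": rng.uniform(15, 70, n), "physical_activity": rng.uniform(0, 600, n),
        "energy_density": rng.uniform(0.3, 4, n), "sugary_drinks": rng.uniform(0, 800, n),
        "fruit_nuts": rng.uniform(0, 600, n), "vegetables": rng.uniform(0, 600, n),
        "legumes": rng.uniform(0, 100, n), "fiber": rng.uniform(0, 60, n),
        "red_meat": rng.uniform(0, 300, n), "processed_meat": rng.uniform(0, 150, n),
        "alcohol": rng.uniform(0, 80, n),
        "smoking": rng.choice(["never", "former", "current"], n),
        "whole_grains": rng.uniform(0, 300, n), "dairy": rng.uniform(0, 1200, n),
        "cereals": rng.uniform(0, 400, n), "fish_seafood": rng.uniform(0, 150, n),
        "mufa": rng.uniform(1, 80, n), "sfa": rng.uniform(1, 80, n),
    })
    wcrf = compute_wcrf_modified(frame)
    ehli = compute_ehli(frame)
    mds = compute_mds(frame)
    assert wcrf["wcrf_total"].between(0, 6).all()
    assert ehli["ehli_total"].between(0, 9).all()
    assert mds["mds_total"].between(0, 9).all()
    allowed = {0.0, 0.5, 1.0}
    for c in WCRF_COMPONENTS:
        assert set(wcrf[f"wcrf_{c}"].unique()) <= allowed
    for c in EHLI_COMPONENTS:
        assert set(ehli[f"ehli_{c}"].unique()) <= allowed


def test_cutpoint_config_round_trips(tmp_path):
    cfg = CutpointConfig.default()
    path = tmp_path / "cutpoints.json"
    cfg.to_json(path)
    assert CutpointConfig.from_json(path).table == cfg.table


# --- tertiles ----------------------------------------------------------------

def _tertile_oracle(values):
    """Independent enumeration: manual linear-interpolated quantiles and the
    ties-to-lower rule."""
    s = sorted(values)
    n = len(s)

    def quantile(p):
        pos = (n - 1) * p
        lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
        return s[lo] + frac * (s[min(lo + 1, n - 1)] - s[lo])

    q1, q2 = quantile(1 / 3), quantile(2 / 3)
    return [1 if v <= q1 else 2 if v <= q2 else 3 for v in values]


def test_tertiles_symmetric_case():
    totals = pd.Series(range(1, 10))
    labels = assign_tertiles(totals)["tertile"]
    assert list(labels.value_counts().sort_index()) == [3, 3, 3]


def test_tertiles_boundary_ties_go_to_lower_tertile():
    values = [2, 2, 2, 2, 3, 3, 5, 5, 5, 7, 7, 9]
    labels = assign_tertiles(pd.Series(values))["tertile"]
    assert list(labels) == _tertile_oracle(values)


def test_tertiles_good_quality_is_top_tertile():
    totals = pd.Series([1, 2, 3, 4, 5, 6, 7, 8, 9])
    out = assign_tertiles(totals)
    assert out.loc[out["tertile"] == 3, "good_quality"].all()
    assert not out.loc[out["tertile"] < 3, "good_quality"].any()


def test_tertiles_all_identical_warns_single_group():
    with pytest.warns(UserWarning):
        out = assign_tertiles(pd.Series([4.0] * 10))
    assert (out["tertile"] == 1).all()


def test_tertiles_require_three_records():
    with pytest.raises(ValueError):
        assign_tertiles(pd.Series([1.0, 2.0]))
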
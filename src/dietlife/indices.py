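"""Composite diet and lifestyle quality indices.

Three indices are computed per participant:

* **MDS** (Mediterranean diet score) — nine components, each 0/1 against the
  cohort median (beneficial components score 1 at/above the median, dairy
  and meat score 1 below it; alcohol scores 1 inside a moderate ethanol
  window).  Total 0–9.
* **Modified WCRF/AICR score** — adherence to six cancer-prevention
  recommendations (body fatness, physical activity, energy-dense food &
  sugary drinks, plant foods, red/processed meat, alcohol), each scored
  1 / 0.5 / 0 for low / moderate / high-risk behaviour.  The salt,
  supplement and breastfeeding recommendations are not scored, so the total
  runs 0–6.
* **EHLI** (Extended Healthy Lifestyle Index) — nine components (smoking,
  alcohol, physical activity, BMI, fruit & vegetables, weight-gain-promoting
  drinks, red/processed meat, unprocessed grains/legumes, dairy), each
  0 / 0.5 / 1.  Total 0–9.

All WCRF/EHLI thresholds live in :class:`CutpointConfig`, so alternative
cut-point tables can be dropped in from JSON without code changes.
Component-level adherence means scoring the component's maximum.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MDS_ALCOHOL_WINDOW: tuple[float, float] = (5.0, 25.0)  # g ethanol/d, [lo, hi)

MDS_COMPONENTS = [
    "fruit_nuts", "vegetables", "cereals", "legumes", "fish_seafood",
    "mufa_sfa_ratio", "dairy", "meat", "alcohol",
]
WCRF_COMPONENTS = [
    "bmi", "physical_activity", "energy_dense_food", "plant_foods",
    "red_processed_meat", "alcohol",
]
EHLI_COMPONENTS = [
    "smoking", "alcohol", "physical_activity", "bmi", "fruit_vegetables",
    "sugary_drinks", "red_processed_meat", "grains_legumes", "dairy",
]


def _default_cutpoints() -> dict:
    return {
        "wcrf": {
            # body fatness: healthy BMI full, overweight partial, obese/underweight none
            "bmi_full": [18.5, 25.0], "bmi_partial": [25.0, 30.0],
            # min/wk moderate-or-vigorous activity
            "activity_full_min": 150.0, "activity_partial_min": 75.0,
            # energy-dense food (kcal/g) & sugary drinks (g/d): worst subcomponent governs
            "energy_density_full": 1.25, "energy_density_partial": 1.75,
            "sugary_drinks_full": 0.0, "sugary_drinks_partial": 250.0,
            # plant foods: fruit+veg+legumes g/d and fibre g/d, worst governs
            "plant_gd_full": 400.0, "plant_gd_partial": 200.0,
            "fiber_full": 30.0, "fiber_partial": 15.0,
            # red meat g/wk gate plus processed meat g/wk grading
            "red_meat_wk_max": 510.0,
            "processed_wk_full": 21.0, "processed_wk_partial": 100.0,
            # ethanol g/d: abstention full, up to ~1 drink partial
            "alcohol_full": 0.0, "alcohol_partial": 14.0,
        },
        "ehli": {
            "bmi_full": [18.5, 25.0], "bmi_partial": [25.0, 30.0],
            "activity_full_min": 150.0, "activity_partial_min": 75.0,
            "fruit_veg_full": 400.0, "fruit_veg_partial": 200.0,
            "sugary_drinks_full": 0.0, "sugary_drinks_partial": 250.0,
            "meat_gd_full": 20.0, "meat_gd_partial": 70.0,
            "grains_legumes_full": 150.0, "grains_legumes_partial": 75.0,
            "dairy_full": 500.0, "dairy_partial": 700.0,
            "alcohol_full": 0.0, "alcohol_partial": 10.0,
            "smoking": {"never": 1.0, "former": 0.5, "current": 0.0},
        },
        "mds_alcohol_window": list(MDS_ALCOHOL_WINDOW),
        "version": "default-1",
    }


@dataclass
class CutpointConfig:
    """Threshold tables for WCRF/AICR and EHLI component scoring."""

    table: dict = field(default_factory=_default_cutpoints)

    def __post_init__(self) -> None:
        for index, comps in (("wcrf", ("bmi_full", "activity_full_min")),
                             ("ehli", ("bmi_full", "smoking"))):
            missing = [c for c in comps if c not in self.table.get(index, {})]
            if missing:
                raise ValueError(f"cut-point table for {index!r} missing {missing}")
        lo, hi = self.table["mds_alcohol_window"]
        if not lo < hi:
            raise ValueError("MDS alcohol window must be ordered")

    @classmethod
    def default(cls) -> "CutpointConfig":
        return cls()

    @classmethod
    def from_json(cls, path: str | Path) -> "CutpointConfig":
        return cls(table=json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.table, indent=2))

    @property
    def wcrf(self) -> dict:
        return self.table["wcrf"]

    @property
    def ehli(self) -> dict:
        return self.table["ehli"]

    @property
    def mds_alcohol_window(self) -> tuple[float, float]:
        lo, hi = self.table["mds_alcohol_window"]
        return float(lo), float(hi)


def _grade(value, full: bool, partial: bool):
    """1 / 0.5 / 0 grading with NaN propagation."""
    return np.where(pd.isna(value), np.nan, np.where(full, 1.0, np.where(partial, 0.5, 0.0)))


def _require_bmi(frame: pd.DataFrame) -> pd.Series:
    if "bmi" in frame:
        return frame["bmi"].astype(float)
    return frame["weight_kg"] / (frame["height_cm"] / 100.0) ** 2


def compute_mds(frame: pd.DataFrame,
                cutpoints: CutpointConfig | None = None) -> pd.DataFrame:
    """Mediterranean diet score against cohort-internal medians.

    Must be called on the analytic sample, because the component medians are
    computed within the sample being scored.  Returns component columns
    (``mds_<component>``), ``mds_total`` and per-component adherence flags.
    A zero-SFA record with positive MUFA gets an infinite ratio (scores 1
    whenever the cohort median is finite); this is logged.
    """
    cutpoints = cutpoints or CutpointConfig.default()
    out = pd.DataFrame(index=frame.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = frame["mufa"].astype(float) / frame["sfa"].astype(float)
    n_inf = int(np.isinf(ratio).sum())
    if n_inf:
        logger.warning("MUFA:SFA ratio infinite for %d record(s) (SFA = 0)", n_inf)

    values = {
        "fruit_nuts": frame["fruit_nuts"], "vegetables": frame["vegetables"],
        "cereals": frame["cereals"], "legumes": frame["legumes"],
        "fish_seafood": frame["fish_seafood"], "mufa_sfa_ratio": ratio,
        "dairy": frame["dairy"],
        "meat": frame["red_meat"].astype(float) + frame["processed_meat"].astype(float),
    }
    beneficial = {"fruit_nuts", "vegetables", "cereals", "legumes",
                  "fish_seafood", "mufa_sfa_ratio"}
    for comp, v in values.items():
        v = v.astype(float)
        med = v.median()
        if comp in beneficial:
            out[f"mds_{comp}"] = (v >= med).astype(float)
        else:
            out[f"mds_{comp}"] = (v < med).astype(float)

    lo, hi = cutpoints.mds_alcohol_window
    alc = frame["alcohol"].astype(float)
    out["mds_alcohol"] = ((alc >= lo) & (alc < hi)).astype(float)

    comp_cols = [f"mds_{c}" for c in MDS_COMPONENTS]
    out["mds_total"] = out[comp_cols].sum(axis=1)
    for c in MDS_COMPONENTS:
        out[f"mds_{c}_adherent"] = out[f"mds_{c}"] == 1.0
    return out


def compute_wcrf_modified(frame: pd.DataFrame,
                          cutpoints: CutpointConfig | None = None) -> pd.DataFrame:
    """Modified WCRF/AICR adherence score (six recommendations, 0–6).

    Requires BMI (or height/weight) and physical activity; records missing
    either are flagged unscoreable (``wcrf_scoreable = False``, NaN total)
    rather than dropped.
    """
    cp = (cutpoints or CutpointConfig.default()).wcrf
    out = pd.DataFrame(index=frame.index)
    bmi = _require_bmi(frame)
    pa = frame["physical_activity"].astype(float)

    out["wcrf_bmi"] = _grade(
        bmi,
        (bmi >= cp["bmi_full"][0]) & (bmi < cp["bmi_full"][1]),
        (bmi >= cp["bmi_partial"][0]) & (bmi < cp["bmi_partial"][1]))
    out["wcrf_physical_activity"] = _grade(
        pa, pa >= cp["activity_full_min"], pa >= cp["activity_partial_min"])

    # energy-dense food & sugary drinks: the riskier subcomponent governs
    dens = frame["energy_density"].astype(float)
    drinks = frame["sugary_drinks"].astype(float)
    dens_risk = np.where(dens < cp["energy_density_full"], 0,
                         np.where(dens < cp["energy_density_partial"], 1, 2))
    drink_risk = np.where(drinks <= cp["sugary_drinks_full"], 0,
                          np.where(drinks <= cp["sugary_drinks_partial"], 1, 2))
    risk = np.maximum(dens_risk, drink_risk)
    out["wcrf_energy_dense_food"] = _grade(dens + drinks, risk == 0, risk == 1)

    # plant foods: fruit+vegetables+legumes (g/d) and fibre (g/d)
    plants = (frame["fruit_nuts"].astype(float) + frame["vegetables"].astype(float)
              + frame["legumes"].astype(float))
    fiber = frame["fiber"].astype(float)
    plant_risk = np.where(plants >= cp["plant_gd_full"], 0,
                          np.where(plants >= cp["plant_gd_partial"], 1, 2))
    fiber_risk = np.where(fiber >= cp["fiber_full"], 0,
                          np.where(fiber >= cp["fiber_partial"], 1, 2))
    risk = np.maximum(plant_risk, fiber_risk)
    out["wcrf_plant_foods"] = _grade(plants + fiber, risk == 0, risk == 1)

    red_wk = frame["red_meat"].astype(float) * 7.0
    proc_wk = frame["processed_meat"].astype(float) * 7.0
    out["wcrf_red_processed_meat"] = _grade(
        red_wk + proc_wk,
        (red_wk < cp["red_meat_wk_max"]) & (proc_wk < cp["processed_wk_full"]),
        (red_wk < cp["red_meat_wk_max"]) & (proc_wk < cp["processed_wk_partial"]))

    alc = frame["alcohol"].astype(float)
    out["wcrf_alcohol"] = _grade(
        alc, alc <= cp["alcohol_full"], alc <= cp["alcohol_partial"])

    comp_cols = [f"wcrf_{c}" for c in WCRF_COMPONENTS]
    out["wcrf_scoreable"] = bmi.notna() & pa.notna()
    out["wcrf_total"] = out[comp_cols].sum(axis=1)
    out.loc[~out["wcrf_scoreable"], "wcrf_total"] = np.nan
    for c in WCRF_COMPONENTS:
        out[f"wcrf_{c}_adherent"] = out[f"wcrf_{c}"] == 1.0
    return out


def compute_ehli(frame: pd.DataFrame,
                 cutpoints: CutpointConfig | None = None) -> pd.DataFrame:
    """Extended Healthy Lifestyle Index (nine components, 0–9).

    Requires smoking status, BMI and physical activity; records missing any
    are flagged unscoreable with NaN total.
    """
    cp = (cutpoints or CutpointConfig.default()).ehli
    out = pd.DataFrame(index=frame.index)
    bmi = _require_bmi(frame)
    pa = frame["physical_activity"].astype(float)

    smoking_map = cp["smoking"]
    smoking = frame["smoking"].map(smoking_map)
    out["ehli_smoking"] = smoking.astype(float)

    alc = frame["alcohol"].astype(float)
    out["ehli_alcohol"] = _grade(alc, alc <= cp["alcohol_full"], alc <= cp["alcohol_partial"])
    out["ehli_physical_activity"] = _grade(
        pa, pa >= cp["activity_full_min"], pa >= cp["activity_partial_min"])
    out["ehli_bmi"] = _grade(
        bmi,
        (bmi >= cp["bmi_full"][0]) & (bmi < cp["bmi_full"][1]),
        (bmi >= cp["bmi_partial"][0]) & (bmi < cp["bmi_partial"][1]))

    fv = frame["fruit_nuts"].astype(float) + frame["vegetables"].astype(float)
    out["ehli_fruit_vegetables"] = _grade(
        fv, fv >= cp["fruit_veg_full"], fv >= cp["fruit_veg_partial"])

    drinks = frame["sugary_drinks"].astype(float)
    out["ehli_sugary_drinks"] = _grade(
        drinks, drinks <= cp["sugary_drinks_full"], drinks <= cp["sugary_drinks_partial"])

    meat = frame["red_meat"].astype(float) + frame["processed_meat"].astype(float)
    out["ehli_red_processed_meat"] = _grade(
        meat, meat <= cp["meat_gd_full"], meat <= cp["meat_gd_partial"])

    grains = frame["whole_grains"].astype(float) + frame["legumes"].astype(float)
    out["ehli_grains_legumes"] = _grade(
        grains, grains >= cp["grains_legumes_full"], grains >= cp["grains_legumes_partial"])

    dairy = frame["dairy"].astype(float)
    out["ehli_dairy"] = _grade(dairy, dairy <= cp["dairy_full"], dairy <= cp["dairy_partial"])

    comp_cols = [f"ehli_{c}" for c in EHLI_COMPONENTS]
    out["ehli_scoreable"] = bmi.notna() & pa.notna() & smoking.notna()
    out["ehli_total"] = out[comp_cols].sum(axis=1)
    out.loc[~out["ehli_scoreable"], "ehli_total"] = np.nan
    for c in EHLI_COMPONENTS:
        out[f"ehli_{c}_adherent"] = out[f"ehli_{c}"] == 1.0
    return out


def assign_tertiles(totals: pd.Series) -> pd.DataFrame:
    """Tertile labels {1, 2, 3} with boundary ties assigned to the lower tertile.

    Cuts at the empirical 1/3 and 2/3 quantiles (linear interpolation);
    tertile 3 flags "good" overall quality.  All-identical totals collapse to
    a single tertile with a warning.
    """
    totals = totals.astype(float)
    valid = totals.dropna()
    if len(valid) < 3:
        raise ValueError("need at least 3 scored records to form tertiles")
    q1, q2 = np.quantile(valid, [1.0 / 3.0, 2.0 / 3.0])
    if valid.nunique() == 1:
        warnings.warn("all index totals identical; a single tertile is assigned")
        tertile = pd.Series(1, index=totals.index, dtype="Int64")
        tertile[totals.isna()] = pd.NA
    else:
        tertile = pd.Series(3, index=totals.index, dtype="Int64")
        tertile[totals <= q2] = 2
        tertile[totals <= q1] = 1
        tertile[totals.isna()] = pd.NA
    return pd.DataFrame({
        "tertile": tertile,
        "good_quality": (tertile == 3).fillna(False).astype(bool),
    })
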
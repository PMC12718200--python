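"""Outcome derivation: anthropometry, glycemic measures, FACIT and HADS scoring.

Seventeen modelled outcomes are produced per participant: four glycemic
(HbA1c, fasting insulin, fasting glucose, HOMA-IR), four anthropometric
(BMI, waist, hip, waist-to-hip ratio), six quality-of-life domain/overall
scores (FACIT) and three anxiety/depression scores (HADS), plus HADS
severity categories.

FACIT: 43 items in five domains (7 physical, 7 social, 6 emotional,
7 functional, 16 condition-specific "additional concerns"), each 0–4 with
negatively worded items reverse-scored as ``4 - x``.  A domain score is
prorated to its full-item scale when more than half of its items were
answered; the overall score (maximum 172) is the sum of the domain scores
and is computed only when more than 80% of all items were answered.

HADS: two 7-item subscales (anxiety, depression), items 0–3, subscale range
0–21, with the same >50% / >80% proration rules, and severity categories
normal (0–7), mild (8–10), moderate (11–14), severe (15–21).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dietlife.simulate import (
    FACIT_DOMAINS,
    FACIT_ITEM_COLS,
    HADS_ANXIETY_ITEMS,
    HADS_DEPRESSION_ITEMS,
)

HOMA_IR_DENOMINATOR = 22.5

#: HADS severity bands; half-open on the left so fractional prorated scores
#: still partition [0, 21] without gaps or overlap.
HADS_CATEGORIES = [
    ("normal", 0.0, 7.0),
    ("mild", 7.0, 10.0),
    ("moderate", 10.0, 14.0),
    ("severe", 14.0, 21.0),
]

PRORATION_ITEM_FRACTION = 0.5   # subscale computable when answered fraction > this
OVERALL_ITEM_FRACTION = 0.8     # overall computable when answered fraction > this


def compute_homa_ir(glucose, insulin):
    """HOMA-IR = fasting glucose x fasting insulin / 22.5.

    Accepts scalars or aligned Series; a missing input yields a missing
    output (the record is retained), while a nonpositive recorded value is a
    data error and raises.
    """
    g = pd.Series(glucose, dtype=float) if not isinstance(glucose, pd.Series) else glucose.astype(float)
    i = pd.Series(insulin, dtype=float) if not isinstance(insulin, pd.Series) else insulin.astype(float)
    bad = (g.notna() & (g <= 0)) | (i.notna() & (i <= 0))
    if bad.any():
        raise ValueError(f"nonpositive glucose/insulin at records {list(g.index[bad])}")
    result = g * i / HOMA_IR_DENOMINATOR
    if np.isscalar(glucose) and np.isscalar(insulin):
        return float(result.iloc[0]) if result.notna().iloc[0] else np.nan
    return result


def derive_anthropometry(height_cm, weight_kg, waist_cm, hip_cm) -> pd.DataFrame:
    """BMI (kg/m^2) and waist-to-hip ratio from measured anthropometry."""
    h = pd.Series(height_cm, dtype=float) if not isinstance(height_cm, pd.Series) else height_cm.astype(float)
    w = pd.Series(weight_kg, dtype=float).reindex(h.index) if not isinstance(weight_kg, pd.Series) else weight_kg
    waist = pd.Series(waist_cm, dtype=float).reindex(h.index) if not isinstance(waist_cm, pd.Series) else waist_cm
    hip = pd.Series(hip_cm, dtype=float).reindex(h.index) if not isinstance(hip_cm, pd.Series) else hip_cm
    if ((h.notna()) & (h <= 0)).any() or ((hip.notna()) & (hip <= 0)).any():
        raise ValueError("height and hip circumference must be positive")
    return pd.DataFrame({
        "bmi": w.astype(float) / (h / 100.0) ** 2,
        "waist_hip_ratio": waist.astype(float) / hip.astype(float),
    })


@dataclass
class FacitKey:
    """Scoring key for the quality-of-life instrument.

    ``domains`` maps domain name -> item numbers (1-based); ``reversed_items``
    lists negatively worded items to be scored ``4 - x``.  The key is
    configuration because the reversed set depends on the instrument
    version; the default here is a synthetic stand-in key with the correct
    domain structure.
    """

    domains: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in FACIT_DOMAINS.items()})
    reversed_items: frozenset[int] = frozenset(
        list(range(1, 8)) + [15, 16, 17, 19, 20])

    def __post_init__(self) -> None:
        sizes = {d: len(v) for d, v in self.domains.items()}
        expected = {"physical": 7, "social": 7, "emotional": 6,
                    "functional": 7, "additional": 16}
        if sizes != expected:
            raise ValueError(f"domain sizes {sizes} != expected {expected}")
        all_items = sorted(i for v in self.domains.values() for i in v)
        if all_items != list(range(1, 44)):
            raise ValueError("domains must partition items 1..43")
        if not set(self.reversed_items) <= set(all_items):
            raise ValueError("reversed_items outside 1..43")

    @classmethod
    def from_json(cls, path: str | Path) -> "FacitKey":
        raw = json.loads(Path(path).read_text())
        return cls(domains=raw["domains"],
                   reversed_items=frozenset(raw["reversed_items"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "domains": self.domains,
            "reversed_items": sorted(self.reversed_items)}, indent=2))


def _prorated_sum(values: pd.DataFrame, n_items: int) -> pd.Series:
    """Sum prorated to the full item count when > 50% of items are answered."""
    answered = values.notna().sum(axis=1)
    total = values.sum(axis=1, min_count=1)
    score = total * (n_items / answered)
    score[answered <= PRORATION_ITEM_FRACTION * n_items] = np.nan
    return score


def score_facit(items: pd.DataFrame, key: FacitKey | None = None) -> pd.DataFrame:
    """Score the 43-item quality-of-life instrument.

    ``items`` holds columns ``facit_01`` .. ``facit_43`` with responses in
    {0..4} or missing.  Returns the five domain scores and the overall
    score (``facit_general``, range 0–172).
    """
    key = key or FacitKey()
    vals = items[FACIT_ITEM_COLS].astype(float)
    in_range = vals.isna() | ((vals >= 0) & (vals <= 4) & (vals == vals.round()))
    if not in_range.all().all():
        raise ValueError("FACIT responses must be integers in 0..4 or missing")

    scored = vals.copy()
    for item in key.reversed_items:
        col = f"facit_{item:02d}"
        scored[col] = 4.0 - scored[col]

    out = pd.DataFrame(index=items.index)
    for domain, numbers in key.domains.items():
        cols = [f"facit_{i:02d}" for i in numbers]
        out[f"facit_{domain}"] = _prorated_sum(scored[cols], len(cols))

    answered_all = vals.notna().sum(axis=1)
    domain_cols = [f"facit_{d}" for d in key.domains]
    general = out[domain_cols].sum(axis=1)
    computable = (answered_all > OVERALL_ITEM_FRACTION * 43) & out[domain_cols].notna().all(axis=1)
    out["facit_general"] = general.where(computable)
    return out


def _hads_category(score: pd.Series) -> pd.Series:
    cat = pd.Series(pd.NA, index=score.index, dtype=object)
    for label, lo, hi in HADS_CATEGORIES:
        band = (score > lo) & (score <= hi) if lo > 0 else (score >= 0) & (score <= hi)
        cat[band.fillna(False)] = label
    return cat


def score_hads(items: pd.DataFrame) -> pd.DataFrame:
    """Score the 14-item anxiety/depression instrument.

    Odd items form the anxiety subscale and even items the depression
    subscale, each 0–21 with >50% proration; the overall score (0–42)
    requires > 80% of all 14 items and both subscales.  Severity categories
    are assigned per subscale.
    """
    all_cols = HADS_ANXIETY_ITEMS + HADS_DEPRESSION_ITEMS
    vals = items[all_cols].astype(float)
    in_range = vals.isna() | ((vals >= 0) & (vals <= 3) & (vals == vals.round()))
    if not in_range.all().all():
        raise ValueError("HADS responses must be integers in 0..3 or missing")

    out = pd.DataFrame(index=items.index)
    out["hads_anxiety"] = _prorated_sum(vals[HADS_ANXIETY_ITEMS], 7)
    out["hads_depression"] = _prorated_sum(vals[HADS_DEPRESSION_ITEMS], 7)
    answered = vals.notna().sum(axis=1)
    overall = out["hads_anxiety"] + out["hads_depression"]
    out["hads_overall"] = overall.where(
        (answered > OVERALL_ITEM_FRACTION * 14)
        & out[["hads_anxiety", "hads_depression"]].notna().all(axis=1))
    out["hads_anxiety_category"] = _hads_category(out["hads_anxiety"])
    out["hads_depression_category"] = _hads_category(out["hads_depression"])
    return out


def score_outcomes(frame: pd.DataFrame, facit_key: FacitKey | None = None) -> pd.DataFrame:
    """Full outcome panel for a cohort frame with raw measures and item columns."""
    out = derive_anthropometry(
        frame["height_cm"], frame["weight_kg"], frame["waist_cm"], frame["hip_cm"])
    out["waist"] = frame["waist_cm"].astype(float)
    out["hip"] = frame["hip_cm"].astype(float)
    for col in ("hba1c", "fasting_glucose", "fasting_insulin"):
        out[col] = frame[col].astype(float)
    out["homa_ir"] = compute_homa_ir(out["fasting_glucose"], out["fasting_insulin"])
    out = pd.concat([out, score_facit(frame, facit_key), score_hads(frame)], axis=1)
    return out
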
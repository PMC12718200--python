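"""Energy-plausibility screening and the exclusion cascade.

Records are removed in a fixed order — implausible total energy intake,
missing baseline demographics, missing physical activity — yielding two
nested analytic samples: *diet-only* (energy and demographics criteria) and
*diet+lifestyle* (additionally requires recorded physical activity).  Each
excluded record carries exactly one primary reason, the first criterion it
fails in cascade order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

#: Fixed energy-plausibility window (kJ/d) used by the published analysis.
FIXED_ENERGY_BOUNDS_KJ: tuple[float, float] = (2568.0, 17031.0)

#: Thermochemical kilojoules per kilocalorie.
KJ_PER_KCAL: float = 4.184

#: Baseline covariates whose missingness triggers the demographic exclusion.
DEFAULT_DEMOGRAPHIC_FIELDS: tuple[str, ...] = (
    "age", "education", "marital_status", "smoking", "comorbidity_count",
)


def kj_to_kcal(kj: float) -> float:
    return kj / KJ_PER_KCAL


def compute_energy_bounds(frame: pd.DataFrame, mode: str = "fixed",
                          energy_col: str = "total_energy") -> tuple[float, float]:
    """Plausibility bounds for daily energy intake, in kJ/d.

    ``fixed`` returns the published operative window; ``data_driven``
    computes exp(mean(ln E) +/- 3 sd(ln E)) over the input records (sample
    SD, n-1).
    """
    if mode == "fixed":
        return FIXED_ENERGY_BOUNDS_KJ
    if mode != "data_driven":
        raise ValueError(f"unknown bounds mode {mode!r}")
    energy = frame[energy_col].astype(float)
    bad = frame.loc[energy.isna() | (energy <= 0), "id"] if "id" in frame else \
        frame.index[energy.isna() | (energy <= 0)]
    if len(bad):
        raise ValueError(f"nonpositive or missing energy for records: {list(bad)}")
    if len(energy) < 2:
        raise ValueError("need at least 2 records to compute data-driven bounds")
    log_e = np.log(energy)
    centre, spread = log_e.mean(), log_e.std(ddof=1)
    return float(np.exp(centre - 3.0 * spread)), float(np.exp(centre + 3.0 * spread))


@dataclass
class ExclusionReport:
    """Counts and per-record primary reasons from one cascade run."""

    n_ffq_complete: int
    n_excluded_energy: int
    n_excluded_demog: int
    n_excluded_pa: int
    n_diet_only: int
    n_diet_lifestyle: int
    reasons: dict[str, str] = field(default_factory=dict)  # id -> first failing criterion
    bounds_kj: tuple[float, float] = FIXED_ENERGY_BOUNDS_KJ

    def __post_init__(self) -> None:
        assert self.n_diet_only == (
            self.n_ffq_complete - self.n_excluded_energy - self.n_excluded_demog)
        assert self.n_diet_lifestyle == self.n_diet_only - self.n_excluded_pa

    def to_dict(self) -> dict:
        return asdict(self)


def apply_exclusion_cascade(
    frame: pd.DataFrame,
    bounds: tuple[float, float] | None = None,
    mode: str = "fixed",
    demographic_fields: Sequence[str] = DEFAULT_DEMOGRAPHIC_FIELDS,
) -> tuple[ExclusionReport, pd.DataFrame, pd.DataFrame]:
    """Apply the ordered exclusion cascade.

    Returns ``(report, diet_only, diet_lifestyle)``.  ``diet_only`` drops
    energy-implausible and demographics-missing records; ``diet_lifestyle``
    additionally drops records with unrecorded physical activity.  An empty
    analytic sample is a valid outcome, not an error.
    """
    if bounds is None:
        bounds = compute_energy_bounds(frame, mode=mode)
    lo, hi = bounds
    if not lo <= hi:
        raise ValueError(f"invalid bounds ({lo}, {hi})")

    energy = frame["total_energy"].astype(float)
    bad_energy = energy.isna() | (energy < lo) | (energy > hi)
    demog_missing = frame[list(demographic_fields)].isna().any(axis=1)
    pa_missing = frame["physical_activity"].isna()

    # first failing criterion in cascade order is the primary reason
    reason = pd.Series(pd.NA, index=frame.index, dtype=object)
    reason[pa_missing] = "physical_activity"
    reason[demog_missing] = "demographics"
    reason[bad_energy] = "energy"

    ids = frame["id"] if "id" in frame else frame.index.astype(str)
    reasons = {str(i): r for i, r in zip(ids, reason) if pd.notna(r)}

    diet_only = frame[~(bad_energy | demog_missing)].copy()
    diet_lifestyle = diet_only[diet_only["physical_activity"].notna()].copy()

    n_energy = int(bad_energy.sum())
    n_demog = int((demog_missing & ~bad_energy).sum())
    n_pa = int((pa_missing & ~bad_energy & ~demog_missing).sum())
    report = ExclusionReport(
        n_ffq_complete=len(frame),
        n_excluded_energy=n_energy,
        n_excluded_demog=n_demog,
        n_excluded_pa=n_pa,
        n_diet_only=len(diet_only),
        n_diet_lifestyle=len(diet_lifestyle),
        reasons=reasons,
        bounds_kj=(float(lo), float(hi)),
    )
    return report, diet_only, diet_lifestyle
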
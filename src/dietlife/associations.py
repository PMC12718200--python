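"""Covariate-adjusted association grid between lifestyle indices and outcomes.

Each model is an ordinary least-squares regression of one outcome on the
z-standardised index total plus a per-index covariate set, so coefficients
are per-SD effects.  Glycemic outcomes (HbA1c, fasting insulin, fasting
glucose, HOMA-IR) are modelled on the natural-log scale and estimates are
exponentiated back, giving multiplicative per-SD effects.  Each model uses
complete cases for its own variables.  Evidence is tiered against a
Bonferroni-adjusted threshold: the comparison family defaults to
3 indices x 17 outcomes = 51 even though the two BMI-outcome cells are
structurally skipped for the indices that already embed BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

#: The 17 modelled outcomes, in reporting order.
OUTCOMES: tuple[str, ...] = (
    "hba1c", "fasting_insulin", "fasting_glucose", "homa_ir",
    "bmi", "waist", "hip", "waist_hip_ratio",
    "facit_physical", "facit_social", "facit_emotional", "facit_functional",
    "facit_additional", "facit_general",
    "hads_anxiety", "hads_depression", "hads_overall",
)

#: Outcomes modelled on the natural-log scale with exponentiated estimates.
LOG_OUTCOMES: frozenset[str] = frozenset(
    {"hba1c", "fasting_insulin", "fasting_glucose", "homa_ir"})

#: Reference levels for indicator coding of categorical covariates.
REFERENCE_LEVELS: Mapping[str, str] = {
    "education": "high_school_or_less",
    "marital_status": "partner",
    "smoking": "never",
    "comorbidity_cat": "0",
}

#: Per-index adjustment sets.  BMI/activity/smoking are omitted where the
#: index already incorporates them; BMI is additionally dropped as a
#: covariate when BMI itself is the outcome.
COVARIATE_SETS: Mapping[str, tuple[str, ...]] = {
    "mds": ("age", "total_energy", "education", "marital_status", "smoking",
            "comorbidity_cat", "physical_activity", "bmi"),
    "wcrf": ("age", "total_energy", "education", "marital_status", "smoking",
             "comorbidity_cat"),
    "ehli": ("age", "total_energy", "education", "marital_status",
             "comorbidity_cat"),
}

#: (exposure, outcome) cells that are never fitted: BMI is part of the score.
STRUCTURAL_SKIPS: frozenset[tuple[str, str]] = frozenset(
    {("wcrf", "bmi"), ("ehli", "bmi")})

EXPOSURE_COLUMNS: Mapping[str, str] = {
    "mds": "mds_total", "wcrf": "wcrf_total", "ehli": "ehli_total"}


def standardize_exposure(values: pd.Series) -> pd.Series:
    """z-transform with the sample-SD (n-1) convention; errors on zero variance."""
    v = values.astype(float)
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot z-standardise a constant exposure")
    z = (v - v.mean()) / sd
    return z


@dataclass
class ModelResult:
    """One fitted exposure–outcome association on its reporting scale."""

    exposure: str
    outcome: str
    covariates: tuple[str, ...]
    estimate: float           # per-SD beta, or Exp(beta) for log outcomes
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    log_outcome: bool
    tier: str = "untier"      # strong | nominal | null, set by apply_bonferroni
    skipped: bool = False
    skip_reason: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = ";".join(self.covariates)
        return d


def _encode_design(data: pd.DataFrame, covariates: Sequence[str],
                   references: Mapping[str, str]) -> pd.DataFrame:
    """Numeric design columns with indicator coding for categoricals."""
    pieces = []
    for cov in covariates:
        col = data[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            ref = references.get(cov)
            dummies = pd.get_dummies(col, prefix=cov, dtype=float)
            ref_col = f"{cov}_{ref}"
            if ref is not None and ref_col in dummies:
                dummies = dummies.drop(columns=ref_col)
            pieces.append(dummies)
        else:
            pieces.append(col.astype(float).to_frame(cov))
    if not pieces:
        return pd.DataFrame(index=data.index)
    return pd.concat(pieces, axis=1)


def fit_association(data: pd.DataFrame, exposure_col: str, outcome: str,
                    covariates: Sequence[str] = (),
                    log_outcome: bool = False,
                    references: Mapping[str, str] = REFERENCE_LEVELS,
                    exposure_label: str | None = None) -> ModelResult:
    """OLS of one outcome on the z-standardised exposure plus covariates.

    Complete cases only; the z-transform is computed within the complete-case
    sample.  For ``log_outcome`` the response is ln(outcome) and the
    estimate/CI are exponentiated back; 95% CI from the t distribution with
    residual degrees of freedom.
    """
    cols = [exposure_col, outcome, *covariates]
    cc = data[cols].dropna()
    if len(cc) < len(covariates) + 3:
        raise ValueError(
            f"{exposure_col}->{outcome}: only {len(cc)} complete cases")
    y = cc[outcome].astype(float)
    if log_outcome:
        if (y <= 0).any():
            raise ValueError(
                f"{outcome}: nonpositive values cannot be log-transformed")
        y = np.log(y)
    z = standardize_exposure(cc[exposure_col])
    design = _encode_design(cc, covariates, references)
    X = pd.concat([z.rename("z_exposure"), design], axis=1)
    X = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); "
            f"check collinearity among {list(X.columns)}")
    fit = sm.OLS(y.to_numpy(), X).fit()
    beta = float(fit.params["z_exposure"])
    lo, hi = (float(v) for v in fit.conf_int(alpha=0.05).loc["z_exposure"])
    p = float(fit.pvalues["z_exposure"])
    if log_outcome:
        beta, lo, hi = np.exp(beta), np.exp(lo), np.exp(hi)
    return ModelResult(
        exposure=exposure_label or exposure_col, outcome=outcome,
        covariates=tuple(covariates), estimate=beta, ci_low=lo, ci_high=hi,
        p_value=p, n_used=len(cc), log_outcome=log_outcome)


def run_model_grid(diet_only: pd.DataFrame, diet_lifestyle: pd.DataFrame,
                   alpha: float = 0.05, family: int = 51,
                   subgroup: tuple[str, object] | None = None,
                   log_outcomes: frozenset[str] = LOG_OUTCOMES) -> pd.DataFrame:
    """Fit the full 3-exposure x 17-outcome grid.

    The MDS exposure is modelled on the diet-only analytic sample and
    WCRF/EHLI on the diet+lifestyle sample.  The two BMI-outcome cells for
    WCRF/EHLI are structurally skipped.  Failed cells are recorded and the
    grid continues.  Returns a tidy results table with Bonferroni evidence
    tiers over the given comparison ``family``.
    """
    samples = {"mds": diet_only, "wcrf": diet_lifestyle, "ehli": diet_lifestyle}
    results: list[ModelResult] = []
    for exposure in ("mds", "wcrf", "ehli"):
        data = samples[exposure]
        if subgroup is not None:
            var, level = subgroup
            data = data[data[var] == level]
        for outcome in OUTCOMES:
            if (exposure, outcome) in STRUCTURAL_SKIPS:
                results.append(ModelResult(
                    exposure=exposure, outcome=outcome, covariates=(),
                    estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p_value=np.nan, n_used=0, log_outcome=False,
                    skipped=True, skip_reason="BMI incorporated in the score"))
                continue
            covs = [c for c in COVARIATE_SETS[exposure] if c != outcome]
            try:
                res = fit_association(
                    data, EXPOSURE_COLUMNS[exposure], outcome, covs,
                    log_outcome=outcome in log_outcomes, exposure_label=exposure)
            except ValueError as err:
                res = ModelResult(
                    exposure=exposure, outcome=outcome, covariates=tuple(covs),
                    estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p_value=np.nan, n_used=0, log_outcome=outcome in log_outcomes,
                    skipped=True, skip_reason=f"fit failed: {err}")
            results.append(res)
    apply_bonferroni(results, n_comparisons=family, alpha=alpha)
    return pd.DataFrame([r.to_dict() for r in results])


def apply_bonferroni(results: Sequence[ModelResult], n_comparisons: int,
                     alpha: float = 0.05) -> float:
    """Assign evidence tiers in place; returns the adjusted threshold.

    strong: p < alpha/n_comparisons; nominal: threshold <= p < alpha;
    null otherwise.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    threshold = alpha / n_comparisons
    for res in results:
        if res.skipped or not np.isfinite(res.p_value):
            res.tier = "skipped"
        elif res.p_value < threshold:
            res.tier = "strong"
        elif res.p_value < alpha:
            res.tier = "nominal"
        else:
            res.tier = "null"
    return threshold


@dataclass
class TertileComparison:
    method: str
    statistic: float
    p_value: float
    shapiro_p: float | None = None
    warnings: list[str] = field(default_factory=list)


def compare_by_tertile(values: pd.Series, tertiles: pd.Series,
                       kind: str = "auto",
                       normality_alpha: float = 0.05) -> TertileComparison:
    """Compare one characteristic across tertile groups.

    Categorical characteristics use a chi-square test of homogeneity;
    continuous characteristics use one-way ANOVA when group-centred values
    pass a Shapiro–Wilk normality gate (configurable alpha), otherwise
    Kruskal–Wallis.  ``kind`` forces ``chi2``/``anova``/``kruskal``.
    """
    keep = values.notna() & tertiles.notna()
    v, t = values[keep], tertiles[keep]
    groups = [v[t == g] for g in sorted(t.unique())]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty tertile groups")
    is_categorical = v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype)
    if kind == "chi2" or (kind == "auto" and is_categorical):
        table = pd.crosstab(v, t)
        warn = []
        chi2, p, _, expected = stats.chi2_contingency(table)
        if (expected < 5).any():
            warn.append("expected cell count < 5")
        return TertileComparison("chi2", float(chi2), float(p), warnings=warn)
    centred = np.concatenate([g.astype(float) - g.astype(float).mean() for g in groups])
    shapiro_p = float(stats.shapiro(centred).pvalue) if 3 <= len(centred) <= 5000 else None
    if kind == "anova" or (kind == "auto" and shapiro_p is not None
                           and shapiro_p > normality_alpha):
        stat, p = stats.f_oneway(*[g.astype(float) for g in groups])
        return TertileComparison("anova", float(stat), float(p), shapiro_p)
    stat, p = stats.kruskal(*[g.astype(float) for g in groups])
    return TertileComparison("kruskal", float(stat), float(p), shapiro_p)
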
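"""Seeded synthetic cohorts emulating an obese baseline gynae-oncology trial sample.

The generator produces one row per participant with food-frequency-derived
intakes (g/d, kJ/d), physical activity (min/wk of moderate-or-vigorous
activity), objectively measured anthropometry, fasting glycemic measures,
item-level quality-of-life (43 items, 0–4) and anxiety/depression (14 items,
0–3) responses, and sociodemographic covariates.  Marginal distributions are
configurable per variable; the defaults emulate the published baseline
summaries of the cohort the pipeline targets (BMI ~ N(47.5, 9.3) truncated at
30, 66% aged >= 50, 78% physically inactive, ...).  Rank correlation among
intake variables is induced through a Gaussian copula.

Effects of a lifestyle index on an outcome can be planted on the modelling
scale (log scale for glycemic outcomes) so that downstream regression fits
can be validated against a known per-SD coefficient.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is invalid or infeasible."""


# --- column layout -----------------------------------------------------------

INTAKE_COLS = [
    "fruit_nuts", "vegetables", "legumes", "cereals", "whole_grains",
    "refined_grains", "fish_seafood", "dairy", "red_meat", "processed_meat",
    "sugary_drinks", "energy_density", "total_energy", "mufa", "sfa",
    "fiber", "alcohol",
]

FACIT_DOMAINS = {
    "physical": list(range(1, 8)),
    "social": list(range(8, 15)),
    "emotional": list(range(15, 21)),
    "functional": list(range(21, 28)),
    "additional": list(range(28, 44)),
}
FACIT_ITEM_COLS = [f"facit_{i:02d}" for i in range(1, 44)]
HADS_ITEM_COLS = [f"hads_{i:02d}" for i in range(1, 15)]
# odd items anxiety, even depression (conventional alternation)
HADS_ANXIETY_ITEMS = [f"hads_{i:02d}" for i in range(1, 15, 2)]
HADS_DEPRESSION_ITEMS = [f"hads_{i:02d}" for i in range(2, 15, 2)]

DEMOGRAPHIC_COLS = ["age", "education", "marital_status", "smoking", "comorbidity_count"]


@dataclass(frozen=True)
class MarginalSpec:
    """Distribution of one generated variable.

    Families:
      ``truncnorm``  params mean, sd, with optional ``lo``/``hi`` truncation
      ``lognormal``  params mu, sigma (of log); optional zero inflation via
                     ``p_zero`` (mass at exactly 0, e.g. non-drinkers)
      ``categorical`` params levels (list), probs (list)
      ``bernoulli_mix`` params p_upper and (mean, sd, lo, hi) for each of the
                     lower/upper truncated-normal branches — used for age,
                     where the published summary is P(age >= cut).
    """

    family: str
    params: Mapping[str, object]
    lo: float | None = None
    hi: float | None = None

    def validate(self, name: str) -> None:
        known = {"truncnorm", "lognormal", "categorical", "bernoulli_mix"}
        if self.family not in known:
            raise ConfigurationError(
                f"variable {name!r}: unknown distribution family {self.family!r}"
            )
        if self.lo is not None and self.hi is not None and self.lo >= self.hi:
            raise ConfigurationError(
                f"variable {name!r}: infeasible truncation [{self.lo}, {self.hi}]"
            )
        if self.family == "categorical":
            probs = np.asarray(self.params["probs"], dtype=float)
            if len(probs) != len(self.params["levels"]) or probs.min() < 0:
                raise ConfigurationError(f"variable {name!r}: invalid categorical probs")

    # inverse-CDF, so copula-correlated uniforms map straight through
    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "truncnorm":
            mean = float(self.params["mean"])
            sd = float(self.params["sd"])
            a = -np.inf if self.lo is None else (self.lo - mean) / sd
            b = np.inf if self.hi is None else (self.hi - mean) / sd
            return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
        if self.family == "lognormal":
            mu = float(self.params["mu"])
            sigma = float(self.params["sigma"])
            p_zero = float(self.params.get("p_zero", 0.0))
            x = np.zeros_like(u)
            pos = u >= p_zero
            if p_zero < 1.0:
                u_pos = (u[pos] - p_zero) / (1.0 - p_zero)
                u_pos = np.clip(u_pos, 1e-12, 1 - 1e-12)
                x[pos] = stats.lognorm.ppf(u_pos, s=sigma, scale=np.exp(mu))
            return x
        if self.family == "categorical":
            probs = np.asarray(self.params["probs"], dtype=float)
            probs = probs / probs.sum()
            edges = np.cumsum(probs)
            idx = np.searchsorted(edges, u, side="right").clip(0, len(probs) - 1)
            return np.asarray(self.params["levels"], dtype=object)[idx]
        if self.family == "bernoulli_mix":
            p_upper = float(self.params["p_upper"])
            lower = MarginalSpec("truncnorm", self.params["lower"],
                                 lo=self.params["lower"].get("lo"),
                                 hi=self.params["lower"].get("hi"))
            upper = MarginalSpec("truncnorm", self.params["upper"],
                                 lo=self.params["upper"].get("lo"),
                                 hi=self.params["upper"].get("hi"))
            in_upper = u >= (1.0 - p_upper)
            # re-uniformise within each branch
            u_low = np.clip(u / max(1.0 - p_upper, 1e-12), 1e-12, 1 - 1e-12)
            u_up = np.clip((u - (1.0 - p_upper)) / max(p_upper, 1e-12), 1e-12, 1 - 1e-12)
            return np.where(in_upper, upper.ppf(u_up), lower.ppf(u_low))
        raise ConfigurationError(f"unknown family {self.family!r}")


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort."""

    n_participants: int
    seed: int
    marginals: dict[str, MarginalSpec]
    intake_rank_corr: float = 0.2
    missingness: dict[str, float] = field(default_factory=dict)
    facit_domain_means: dict[str, float] = field(default_factory=dict)
    hads_domain_means: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        for name, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missingness[{name!r}] = {rate} outside [0, 1]")
        if not -0.99 < self.intake_rank_corr < 0.99:
            raise ConfigurationError("intake_rank_corr must lie in (-0.99, 0.99)")
        for name, spec in self.marginals.items():
            spec.validate(name)


def _lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given median and interquartile range."""
    sigma = float(np.arcsinh(iqr / (2.0 * median)) / stats.norm.ppf(0.75))
    return float(np.log(median)), sigma


def default_config(n_participants: int = 150, seed: int = 0) -> CohortConfig:
    """Default marginals emulating the target cohort's published baseline summaries.

    Anthropometry, glycemic medians/IQRs, age split, activity prevalence and
    the categorical frequencies mirror the printed baseline table of the
    trial population (obese women, BMI >= 30, two-thirds aged >= 50, 78%
    physically inactive).  Intake levels, for which no cohort summaries are
    printed, use realistic adult-female values documented in the methods
    note.  Total energy is lognormal(mu=8.797, sigma=0.315) so that the
    +/-3 SD log-energy plausibility rule lands on the kJ scale the exclusion
    cascade expects.
    """
    m: dict[str, MarginalSpec] = {}
    m["age"] = MarginalSpec("bernoulli_mix", {
        "p_upper": 0.66,
        "lower": {"mean": 43.0, "sd": 5.0, "lo": 25.0, "hi": 49.999},
        "upper": {"mean": 58.0, "sd": 6.0, "lo": 50.0, "hi": 80.0},
    })
    m["bmi"] = MarginalSpec("truncnorm", {"mean": 47.5, "sd": 9.3}, lo=30.0)
    m["height_cm"] = MarginalSpec("truncnorm", {"mean": 162.0, "sd": 7.0}, lo=140.0, hi=190.0)
    m["waist_cm"] = MarginalSpec("truncnorm", {"mean": 129.7, "sd": 17.0}, lo=80.0)
    m["hip_cm"] = MarginalSpec("truncnorm", {"mean": 144.9, "sd": 18.9}, lo=90.0)

    for name, med, iqr in [("hba1c", 5.8, 1.0), ("fasting_glucose", 5.9, 1.9),
                           ("fasting_insulin", 19.0, 20.0)]:
        mu, sigma = _lognormal_from_median_iqr(med, iqr)
        m[name] = MarginalSpec("lognormal", {"mu": mu, "sigma": sigma})

    # 78% report no moderate-or-vigorous activity; active minutes lognormal
    m["physical_activity"] = MarginalSpec(
        "lognormal", {"mu": np.log(120.0), "sigma": 0.8, "p_zero": 0.776})

    m["race"] = MarginalSpec("categorical", {
        "levels": ["white", "non_white"], "probs": [0.687, 0.313]})
    m["education"] = MarginalSpec("categorical", {
        "levels": ["high_school_or_less", "tafe_diploma_university"], "probs": [0.537, 0.463]})
    m["income"] = MarginalSpec("categorical", {
        "levels": ["low", "middle", "high"], "probs": [0.245, 0.398, 0.357]})
    m["marital_status"] = MarginalSpec("categorical", {
        "levels": ["partner", "no_partner"], "probs": [0.591, 0.409]})
    m["menopausal_status"] = MarginalSpec("categorical", {
        "levels": ["pre", "post"], "probs": [0.407, 0.593]})
    m["smoking"] = MarginalSpec("categorical", {
        "levels": ["never", "former", "current"], "probs": [0.547, 0.360, 0.093]})
    m["family_history"] = MarginalSpec("categorical", {
        "levels": ["no", "yes"], "probs": [0.246, 0.754]})
    m["diabetes"] = MarginalSpec("categorical", {
        "levels": ["no", "yes"], "probs": [0.693, 0.307]})
    m["comorbidity_count"] = MarginalSpec("categorical", {
        "levels": [0, 1, 2, 3], "probs": [0.347, 0.40, 0.18, 0.073]})

    intake_medians = {
        "fruit_nuts": 150.0, "vegetables": 200.0, "legumes": 20.0,
        "cereals": 150.0, "whole_grains": 60.0, "refined_grains": 120.0,
        "fish_seafood": 30.0, "dairy": 300.0, "red_meat": 70.0,
        "processed_meat": 30.0, "sugary_drinks": 100.0,
        "mufa": 30.0, "sfa": 32.0, "fiber": 22.0,
    }
    for name, med in intake_medians.items():
        m[name] = MarginalSpec("lognormal", {"mu": np.log(med), "sigma": 0.6})
    m["energy_density"] = MarginalSpec("truncnorm", {"mean": 1.6, "sd": 0.4}, lo=0.5, hi=3.5)
    m["total_energy"] = MarginalSpec("lognormal", {"mu": 8.797, "sigma": 0.315})
    m["alcohol"] = MarginalSpec("lognormal", {"mu": np.log(8.0), "sigma": 0.9, "p_zero": 0.45})

    return CohortConfig(
        n_participants=n_participants,
        seed=seed,
        marginals=m,
        intake_rank_corr=0.2,
        facit_domain_means={"physical": 2.96, "social": 3.00, "emotional": 2.80,
                            "functional": 2.33, "additional": 2.90},
        hads_domain_means={"anxiety": 1.83, "depression": 2.10},
    )


def _copula_uniforms(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """n x k uniforms with pairwise Gaussian-copula correlation rho."""
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    return stats.norm.cdf(z)


def _generate_items(rng: np.random.Generator, n: int, item_cols: Sequence[str],
                    domain_items: Mapping[str, Sequence[str]],
                    domain_means: Mapping[str, float], max_resp: int) -> pd.DataFrame:
    """Ordinal item responses from a per-domain latent severity.

    Each participant draws a latent level per domain around the planted
    domain mean; items discretise latent + item noise at equal-interval
    thresholds (a simple proportional-odds-style cut-point model), so the
    planted per-item domain means are controllable.
    """
    out = pd.DataFrame(index=range(n), columns=list(item_cols), dtype=float)
    for domain, cols in domain_items.items():
        mean = float(domain_means.get(domain, max_resp / 2.0))
        latent = rng.normal(mean, 0.5, size=n)
        for col in cols:
            resp = np.rint(latent + rng.normal(0.0, 0.7, size=n))
            out[col] = np.clip(resp, 0, max_resp)
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy per-participant DataFrame.

    Deterministic given ``config`` (including its seed).  Weight is derived
    from BMI and height so anthropometric invariants hold by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    df = pd.DataFrame({"id": [f"P{i + 1:04d}" for i in range(n)]})

    intake_names = [c for c in INTAKE_COLS if c in config.marginals]
    u_intake = _copula_uniforms(rng, n, len(intake_names), config.intake_rank_corr)
    for j, name in enumerate(intake_names):
        df[name] = config.marginals[name].ppf(u_intake[:, j])

    for name, spec in config.marginals.items():
        if name in intake_names:
            continue
        u = rng.uniform(1e-12, 1 - 1e-12, size=n)
        df[name] = spec.ppf(u)

    if "bmi" in df and "height_cm" in df:
        df["weight_kg"] = df["bmi"] * (df["height_cm"] / 100.0) ** 2

    facit = _generate_items(
        rng, n, FACIT_ITEM_COLS,
        {d: [f"facit_{i:02d}" for i in items] for d, items in FACIT_DOMAINS.items()},
        config.facit_domain_means, max_resp=4)
    hads = _generate_items(
        rng, n, HADS_ITEM_COLS,
        {"anxiety": HADS_ANXIETY_ITEMS, "depression": HADS_DEPRESSION_ITEMS},
        config.hads_domain_means, max_resp=3)
    df = pd.concat([df, facit, hads], axis=1)

    for name, rate in config.missingness.items():
        if name not in df.columns:
            raise ConfigurationError(f"missingness names unknown variable {name!r}")
        mask = rng.uniform(size=n) < rate
        df.loc[mask, name] = np.nan

    for col in ("age", "comorbidity_count"):
        if col in df:
            df[col] = pd.to_numeric(df[col])
    return df


@dataclass
class EffectSpec:
    """A planted exposure->outcome effect on the outcome's modelling scale.

    ``beta_per_sd`` is the change in the (possibly log) outcome per 1 SD of
    the exposure score; for glycemic outcomes pass the log-scale coefficient
    (e.g. ``log(0.92)`` for an 8% reduction per SD).
    """

    exposure: str                      # column holding the index total
    outcome: str                       # outcome column to overwrite
    beta_per_sd: float
    noise_sd: float = 0.0
    intercept: float | None = None     # default: keep the outcome's current mean
    covariate_effects: dict[str, float] = field(default_factory=dict)
    log_outcome: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def plant_effects(frame: pd.DataFrame, spec: EffectSpec, seed: int = 0) -> pd.DataFrame:
    """Overwrite ``spec.outcome`` as linear-in-z(exposure) + covariates + noise.

    Returns a copy.  With ``noise_sd = 0`` the matching regression recovers
    ``beta_per_sd`` exactly (to numerical tolerance).
    """
    if spec.outcome not in frame.columns:
        raise KeyError(
            f"unknown outcome {spec.outcome!r}; valid outcomes include "
            f"{sorted(c for c in frame.columns if not c.startswith(('facit_', 'hads_')))}")
    if spec.exposure not in frame.columns:
        raise KeyError(f"exposure column {spec.exposure!r} not found")
    out = frame.copy()
    x = out[spec.exposure].astype(float)
    z = (x - x.mean()) / x.std(ddof=1)
    if spec.intercept is None:
        y0 = out[spec.outcome].astype(float)
        base = float(np.log(y0).mean()) if spec.log_outcome else float(y0.mean())
    else:
        base = spec.intercept
    rng = np.random.default_rng(seed)
    eta = base + spec.beta_per_sd * z
    for cov, coef in spec.covariate_effects.items():
        eta = eta + coef * out[cov].astype(float)
    eta = eta + rng.normal(0.0, spec.noise_sd, size=len(out))
    out[spec.outcome] = np.exp(eta) if spec.log_outcome else eta
    return out


def make_exclusion_fixture(n_total: int, n_energy_implausible: int,
                           n_missing_demog: int, n_missing_pa: int,
                           seed: int = 0) -> pd.DataFrame:
    """Cohort with exactly the requested exclusion flags on disjoint records.

    Non-flagged records are guaranteed plausible: energy clipped inside the
    fixed kJ bounds, no missing demographics, physical activity recorded
    (zero minutes counts as recorded, not missing).
    """
    n_flagged = n_energy_implausible + n_missing_demog + n_missing_pa
    if n_flagged > n_total:
        raise ValueError(
            f"flag counts sum to {n_flagged} but cohort has only {n_total} records")
    cfg = default_config(n_participants=n_total, seed=seed)
    df = generate_cohort(cfg)
    # keep every unflagged record strictly inside the fixed plausibility window
    df["total_energy"] = df["total_energy"].clip(3000.0, 16000.0)

    order = np.random.default_rng(seed).permutation(n_total)
    lo_flags = order[:n_energy_implausible]
    demog_flags = order[n_energy_implausible:n_energy_implausible + n_missing_demog]
    pa_flags = order[n_energy_implausible + n_missing_demog:n_flagged]

    half = len(lo_flags) // 2
    df.loc[df.index[lo_flags[:half]], "total_energy"] = 1500.0     # < 2568 kJ
    df.loc[df.index[lo_flags[half:]], "total_energy"] = 20000.0    # > 17031 kJ
    df.loc[df.index[demog_flags], "education"] = np.nan
    df.loc[df.index[pa_flags], "physical_activity"] = np.nan
    return df


def cohort_digest(frame: pd.DataFrame) -> str:
    """SHA-256 of the CSV serialisation — used in determinism checks."""
    return hashlib.sha256(frame.to_csv(index=False).encode()).hexdigest()
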
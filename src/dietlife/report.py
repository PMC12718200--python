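"""End-to-end pipeline orchestration and descriptive reporting.

``run_pipeline`` chains simulate -> exclude -> score -> analyze -> agree
under one top-level seed, writes every intermediate table as CSV, and
records a manifest (config hash, seed, output digests) so a rerun with the
same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from dietlife._version import __version__ as _pkg_version
from dietlife.agreement import pairwise_agreement
from dietlife.associations import run_model_grid
from dietlife.indices import (
    CutpointConfig, EHLI_COMPONENTS, MDS_COMPONENTS, WCRF_COMPONENTS,
    assign_tertiles, compute_ehli, compute_mds, compute_wcrf_modified,
)
from dietlife.intake import apply_exclusion_cascade, compute_energy_bounds
from dietlife.outcomes import score_outcomes
from dietlife.simulate import make_exclusion_fixture


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    The default fixture reproduces the published participant flow: 157
    questionnaire completers with 6 energy-implausible, 1
    demographics-missing and 3 activity-missing records, yielding analytic
    samples of 150 (diet-only) and 147 (diet+lifestyle).
    """

    seed: int = 0
    n_total: int = 157
    n_energy_implausible: int = 6
    n_missing_demog: int = 1
    n_missing_pa: int = 3
    bounds_mode: str = "fixed"
    alpha: float = 0.05
    family: int = 51
    kappa_weights: str = "linear"
    outdir: str = "dietlife_run"

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    seed: int
    package_version: str
    bonferroni_threshold: float
    n_ffq_complete: int
    n_diet_only: int
    n_diet_lifestyle: int
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timestamp: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2))


def _fmt_pct(count: int, total: int) -> str:
    return f"{count} ({100.0 * count / total:.1f})"


def build_descriptive_table(cohort: pd.DataFrame, scores: pd.DataFrame,
                            outcomes: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics table: counts (%) for categoricals, mean (SD)
    or median (IQR) for continuous variables, component adherence and
    good-quality rows from tertile 3.

    Percentages use the non-missing denominator and are rounded to one
    decimal for display; full precision lives in the underlying CSVs.
    """
    rows: list[dict] = []
    n = len(cohort)

    def add(section: str, label: str, value: str, missing: int = 0) -> None:
        rows.append({"section": section, "characteristic": label,
                     "value": value, "n_missing": missing})

    age = cohort["age"].astype(float)
    add("demographics", "age >= 50 y", _fmt_pct(int((age >= 50).sum()), int(age.notna().sum())))
    for col in ("race", "education", "income", "marital_status",
                "menopausal_status", "smoking", "family_history", "diabetes"):
        if col not in cohort:
            continue
        present = cohort[col].dropna()
        miss = n - len(present)
        for level, count in present.value_counts().items():
            add("demographics", f"{col} = {level}", _fmt_pct(int(count), len(present)), miss)
    if "comorbidity_count" in cohort:
        cc = cohort["comorbidity_count"].dropna()
        add("demographics", "comorbidities 1+", _fmt_pct(int((cc >= 1).sum()), len(cc)))
    if "physical_activity" in cohort:
        pa = cohort["physical_activity"].dropna()
        add("demographics", "physically active", _fmt_pct(int((pa > 0).sum()), len(pa)),
            n - len(pa))

    for index, comps in (("mds", MDS_COMPONENTS), ("wcrf", WCRF_COMPONENTS),
                         ("ehli", EHLI_COMPONENTS)):
        for comp in comps:
            col = f"{index}_{comp}_adherent"
            if col in scores:
                flags = scores[col].dropna()
                add("adherence", f"{comp} ({index.upper()})",
                    _fmt_pct(int(flags.sum()), len(flags)))
        tcol = f"{index}_tertile"
        if tcol in scores:
            good = scores[tcol].dropna() == 3
            add("adherence", f"good quality ({index.upper()})",
                _fmt_pct(int(good.sum()), len(good)))

    for col, how in (("hba1c", "median"), ("fasting_insulin", "median"),
                     ("fasting_glucose", "median"), ("homa_ir", "median"),
                     ("bmi", "mean"), ("waist", "mean"), ("hip", "mean"),
                     ("waist_hip_ratio", "mean"),
                     ("facit_physical", "mean"), ("facit_social", "mean"),
                     ("facit_emotional", "mean"), ("facit_functional", "mean"),
                     ("facit_additional", "mean"), ("facit_general", "mean"),
                     ("hads_anxiety", "mean"), ("hads_depression", "mean"),
                     ("hads_overall", "mean")):
        if col not in outcomes:
            continue
        v = outcomes[col].dropna().astype(float)
        if len(v) == 0:
            add("outcomes", col, "— (all missing)", n)
        elif how == "mean":
            add("outcomes", f"{col}, mean (SD)", f"{v.mean():.1f} ({v.std(ddof=1):.1f})",
                n - len(v))
        else:
            iqr = float(v.quantile(0.75) - v.quantile(0.25))
            add("outcomes", f"{col}, median (IQR)", f"{v.median():.1f} ({iqr:.1f})",
                n - len(v))
    return pd.DataFrame(rows)


def _score_samples(diet_only: pd.DataFrame, diet_lifestyle: pd.DataFrame,
                   cutpoints: CutpointConfig | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score all three indices; MDS on the diet-only sample (cohort-internal
    medians), WCRF/EHLI on the diet+lifestyle sample."""
    cutpoints = cutpoints or CutpointConfig.default()
    mds = compute_mds(diet_only, cutpoints)
    mds = pd.concat([mds, assign_tertiles(mds["mds_total"]).rename(
        columns={"tertile": "mds_tertile", "good_quality": "mds_good"})], axis=1)
    diet_only_scored = pd.concat([diet_only, mds], axis=1)

    wcrf = compute_wcrf_modified(diet_lifestyle, cutpoints)
    ehli = compute_ehli(diet_lifestyle, cutpoints)
    wcrf = pd.concat([wcrf, assign_tertiles(wcrf["wcrf_total"]).rename(
        columns={"tertile": "wcrf_tertile", "good_quality": "wcrf_good"})], axis=1)
    ehli = pd.concat([ehli, assign_tertiles(ehli["ehli_total"]).rename(
        columns={"tertile": "ehli_tertile", "good_quality": "ehli_good"})], axis=1)
    diet_lifestyle_scored = pd.concat([diet_lifestyle, wcrf, ehli], axis=1)
    # MDS totals restricted to the diet+lifestyle subset, for agreement stats
    diet_lifestyle_scored = diet_lifestyle_scored.join(
        diet_only_scored[["mds_total", "mds_tertile"]])
    return diet_only_scored, diet_lifestyle_scored


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = make_exclusion_fixture(
        config.n_total, config.n_energy_implausible,
        config.n_missing_demog, config.n_missing_pa, seed=config.seed)
    bounds = compute_energy_bounds(cohort, mode=config.bounds_mode)
    report, diet_only, diet_lifestyle = apply_exclusion_cascade(cohort, bounds)

    diet_only_scored, diet_lifestyle_scored = _score_samples(diet_only, diet_lifestyle)
    panel_do = score_outcomes(diet_only_scored)
    panel_dl = score_outcomes(diet_lifestyle_scored)
    analytic_do = pd.concat([diet_only_scored, panel_do.drop(
        columns=[c for c in panel_do if c in diet_only_scored])], axis=1)
    analytic_dl = pd.concat([diet_lifestyle_scored, panel_dl.drop(
        columns=[c for c in panel_dl if c in diet_lifestyle_scored])], axis=1)
    analytic_do["comorbidity_cat"] = np.where(
        analytic_do["comorbidity_count"] >= 1, "1+", "0")
    analytic_dl["comorbidity_cat"] = np.where(
        analytic_dl["comorbidity_count"] >= 1, "1+", "0")

    models = run_model_grid(analytic_do, analytic_dl,
                            alpha=config.alpha, family=config.family)
    agreement = pairwise_agreement(
        analytic_dl[["mds_total", "wcrf_total", "ehli_total"]].rename(
            columns=lambda c: c.removesuffix("_total")),
        analytic_dl[["mds_tertile", "wcrf_tertile", "ehli_tertile"]].rename(
            columns=lambda c: c.removesuffix("_tertile")),
        weights=config.kappa_weights)
    table1 = build_descriptive_table(analytic_do, analytic_do, analytic_do)

    outputs = {
        "cohort.csv": cohort,
        "diet_only.csv": analytic_do,
        "diet_lifestyle.csv": analytic_dl,
        "models.csv": models,
        "agreement.csv": agreement,
        "table1.csv": table1,
        "exclusion_reasons.csv": pd.DataFrame(
            [{"id": k, "reason": v} for k, v in report.reasons.items()]),
    }
    digests: dict[str, str] = {}
    for name, frame in outputs.items():
        path = outdir / name
        frame.to_csv(path, index=False)
        digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (outdir / "exclusions.json").write_text(json.dumps(report.to_dict(), indent=2))
    digests["exclusions.json"] = hashlib.sha256(
        (outdir / "exclusions.json").read_bytes()).hexdigest()

    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=config.digest(),
        seed=config.seed,
        package_version=_pkg_version,
        bonferroni_threshold=config.alpha / config.family,
        n_ffq_complete=report.n_ffq_complete,
        n_diet_only=report.n_diet_only,
        n_diet_lifestyle=report.n_diet_lifestyle,
        outputs=digests,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(outdir / "manifest.json")
    return manifest
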
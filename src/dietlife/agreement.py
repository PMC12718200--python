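"""Pairwise agreement between lifestyle indices.

Continuous index totals are compared with Spearman rank correlation
(average ranks for ties, p from the t approximation); tertile
classifications are compared with weighted kappa (linear
Cicchetti–Allison disagreement weights by default, quadratic optional),
with an asymptotic p-value against kappa = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa


@dataclass
class AgreementResult:
    pair: tuple[str, str]
    spearman_rho: float
    spearman_p: float
    weighted_kappa: float
    kappa_p: float
    weight_scheme: str
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pair"] = "/".join(self.pair)
        return d


def spearman_between(scores_a: pd.Series, scores_b: pd.Series) -> tuple[float, float]:
    """Spearman rho and two-sided p for paired continuous scores."""
    keep = scores_a.notna() & scores_b.notna()
    a, b = scores_a[keep].astype(float), scores_b[keep].astype(float)
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")
    if a.nunique() == 1 or b.nunique() == 1:
        raise ValueError("Spearman correlation undefined for a constant score vector")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def weighted_kappa(tertiles_a: pd.Series, tertiles_b: pd.Series,
                   weights: str = "linear",
                   n_categories: int = 3) -> tuple[float, float]:
    """Weighted kappa between two ordinal classifications on the same scale.

    ``weights``: ``linear`` (|i-j|/(k-1), Cicchetti–Allison) or
    ``quadratic``.  p-value is two-sided from the large-sample null
    variance of kappa.
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError(f"unknown weight scheme {weights!r}")
    keep = pd.Series(tertiles_a).notna() & pd.Series(tertiles_b).notna()
    a = pd.Series(tertiles_a)[keep].astype(int)
    b = pd.Series(tertiles_b)[keep].astype(int)
    levels = list(range(1, n_categories + 1))
    if a.nunique() < 2 or b.nunique() < 2:
        raise ValueError("degenerate marginals: a rater used a single category")
    table = pd.crosstab(pd.Categorical(a, categories=levels),
                        pd.Categorical(b, categories=levels), dropna=False)
    res = cohens_kappa(table.to_numpy(), wt="linear" if weights == "linear" else "quadratic")
    return float(res.kappa), float(res.pvalue_two_sided)


def pairwise_agreement(totals: pd.DataFrame, tertiles: pd.DataFrame,
                       weights: str = "linear") -> pd.DataFrame:
    """All pairwise agreement statistics among the index columns.

    ``totals`` and ``tertiles`` carry one column per index (same names).
    Returns a tidy table with one row per unordered pair.
    """
    names = list(totals.columns)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            keep = totals[a].notna() & totals[b].notna()
            rho, rho_p = spearman_between(totals[a], totals[b])
            kap, kap_p = weighted_kappa(tertiles[a][keep], tertiles[b][keep],
                                        weights=weights)
            rows.append(AgreementResult(
                pair=(a, b), spearman_rho=rho, spearman_p=rho_p,
                weighted_kappa=kap, kappa_p=kap_p, weight_scheme=weights,
                n=int(keep.sum())).to_dict())
    return pd.DataFrame(rows)
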
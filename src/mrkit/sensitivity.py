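"""Diagnostics for MR analyses.

Heterogeneity among per-SNP causal estimates, leave-one-out stability,
single-SNP forest and funnel summaries, the Steiger directionality test
and the instrument-strength F statistic.  All outputs are plain pandas
tables; the optional plotting helpers in :mod:`mrkit.plots` render them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (MRResult, _dispatch, _ivw_parts, ivw, mr_egger,
                         wald_ratio, mr_all)
from .harmonise import SummarySet

__all__ = [
    "HeterogeneityResult", "SteigerResult", "heterogeneity", "leave_one_out",
    "single_snp_forest", "funnel_data", "steiger", "instrument_strength",
    "overlap_percentage",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q for the IVW fit or Q' for the Egger residuals."""

    method: str
    Q: float
    df: int
    pval: float


def heterogeneity(summary_set: SummarySet, method: str = "ivw",
                  scale: str = "ratio") -> HeterogeneityResult:
    """Heterogeneity of per-SNP causal estimates.

    For ``method="ivw"`` Q is computed on the ratio scale,
    Q = sum w_j (ratio_j - b_ivw)^2 with w_j = (beta_x_j/sigma_y_j)^2
    (df = L-1); ``scale="regression"`` gives the algebraically identical
    residual form sum sigma_y^-2 (beta_y - b*beta_x)^2.  For
    ``method="egger"`` Q' is the weighted residual sum of squares of the
    intercept model (df = L-2).  Large Q relative to its chi-square
    reference signals violations of the IV assumptions (e.g. horizontal
    pleiotropy).
    """
    if method == "ivw":
        bx, _, by, sy = summary_set.arrays()
        if len(bx) < 2:
            raise ValueError("IVW heterogeneity requires >= 2 kept SNPs")
        slope, _, q_reg = _ivw_parts(bx, by, sy)
        if scale == "ratio":
            w = (bx / sy) ** 2
            q = float(np.sum(w * (by / bx - slope) ** 2))
        elif scale == "regression":
            q = q_reg
        else:
            raise ValueError(f"unknown scale {scale!r}")
        df = len(bx) - 1
    elif method == "egger":
        res = mr_egger(summary_set)  # validates >= 3 SNPs
        q, df = res.info["Q"], res.info["Q_df"]
    else:
        raise ValueError(f"unknown heterogeneity method {method!r}")
    return HeterogeneityResult(method=method, Q=q, df=df,
                               pval=float(stats.chi2.sf(q, df)))


def leave_one_out(summary_set: SummarySet, method: str = "ivw",
                  seed: int = 0, n_boot: int = 1000) -> pd.DataFrame:
    """Re-estimate dropping one SNP at a time.

    Returns L+1 rows: one per excluded rsID plus an "All" row using every
    SNP, columns (snp, estimate, se, ci_low, ci_high, pval, nsnp).  A
    single SNP with a large pleiotropic effect shows up as the row whose
    exclusion shifts the estimate most.
    """
    kept = summary_set.kept()
    L = len(kept)
    if L < 3:
        raise ValueError("leave-one-out requires >= 3 kept SNPs")
    rows = []
    for i in range(L):
        sub = summary_set.subset(np.arange(L) != i)
        res = _dispatch(method, sub, seed, n_boot)
        rows.append({"snp": kept["SNP"].iloc[i], **_res_row(res)})
    rows.append({"snp": "All",
                 **_res_row(_dispatch(method, summary_set, seed, n_boot))})
    return pd.DataFrame(rows)


def _res_row(res: MRResult) -> dict:
    return {"estimate": res.estimate, "se": res.se, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "pval": res.pval, "nsnp": res.nsnp}


def single_snp_forest(summary_set: SummarySet,
                      methods: list[str] | None = None,
                      seed: int = 0, n_boot: int = 1000) -> pd.DataFrame:
    """Per-SNP Wald ratios plus combined rows for the requested methods."""
    kept = summary_set.kept()
    rows = []
    for _, r in kept.iterrows():
        res = wald_ratio(r)
        rows.append({"snp": r["SNP"], "method": "wald_ratio",
                     **_res_row(res)})
    combined, _ = mr_all(summary_set, methods, seed=seed, n_boot=n_boot)
    for res in combined:
        rows.append({"snp": "All", "method": res.method, **_res_row(res)})
    return pd.DataFrame(rows)


def funnel_data(summary_set: SummarySet) -> pd.DataFrame:
    """Per-SNP Wald estimate against its precision 1/se.

    Asymmetry of the funnel (estimate drifting with precision) suggests
    directional pleiotropy, exactly as in small-study-effect funnels in
    meta-analysis.
    """
    kept = summary_set.kept()
    rows = []
    for _, r in kept.iterrows():
        res = wald_ratio(r)
        rows.append({"snp": r["SNP"], "estimate": res.estimate,
                     "precision": 1.0 / res.se})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SteigerResult:
    """Directionality check: does the instrument explain more variance in
    the exposure than in the outcome?"""

    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    steiger_pval: float


def _r2_from_summary(beta, se, n):
    """Variance explained by one SNP from its Wald Z and sample size:
    r^2 = Z^2 / (Z^2 + n - 2) (continuous traits; approximate on the
    observed scale for binary traits with effective n)."""
    z2 = (beta / se) ** 2
    return z2 / (z2 + n - 2)


def steiger(summary_set: SummarySet) -> SteigerResult:
    """Aggregate Steiger directionality test over kept SNPs.

    Sums per-SNP variance explained on each side (instruments are
    independent after clumping), flags direction_correct when the
    exposure r2 strictly exceeds the outcome r2, and tests the difference
    by Fisher-transforming the two multiple correlations and comparing
    them as independent correlations (two-sample Z test).
    """
    kept = summary_set.kept()
    missing = kept.loc[kept["n_exp"].isna() | kept["n_out"].isna(), "SNP"]
    if len(missing):
        raise ValueError(
            f"Steiger test needs per-SNP sample sizes; missing for: "
            f"{missing.tolist()}")
    n_exp = float(kept["n_exp"].mean())
    n_out = float(kept["n_out"].mean())
    r2_exp = float(np.sum(_r2_from_summary(
        kept["beta_exp"].to_numpy(float), kept["se_exp"].to_numpy(float),
        kept["n_exp"].to_numpy(float))))
    r2_out = float(np.sum(_r2_from_summary(
        kept["beta_out"].to_numpy(float), kept["se_out"].to_numpy(float),
        kept["n_out"].to_numpy(float))))
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    z_exp = np.arctanh(math.sqrt(r2_exp))
    z_out = np.arctanh(math.sqrt(r2_out))
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_exp - z_out) / denom
    return SteigerResult(
        r2_exposure=r2_exp, r2_outcome=r2_out,
        direction_correct=bool(r2_exp > r2_out),
        steiger_pval=float(2 * stats.norm.sf(abs(z))))


def instrument_strength(r2_total: float, k: int, n: int) -> float:
    """Instrument-strength F statistic for a k-SNP score.

    F = [r2/k] / [(1-r2)/(n-k-1)], the ANOVA F for a joint regression of
    the exposure on k independent instruments explaining r2_total of its
    variance in n samples.  Values well above 10 indicate the analysis is
    unlikely to suffer weak-instrument bias.
    """
    if not 0.0 <= r2_total < 1.0:
        raise ValueError(f"r2_total must be in [0,1), got {r2_total}")
    if k < 1:
        raise ValueError("k must be a positive number of SNPs")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (got n={n}, k={k})")
    return (r2_total / k) / ((1.0 - r2_total) / (n - k - 1))


def overlap_percentage(n_shared: float, n_total: float) -> float:
    """Percentage of one study's participants shared with another.

    Sample overlap between the exposure and outcome GWAS biases 2SMR
    estimates toward the confounded observational association; this is
    the simple headcount ratio 100 * n_shared / n_total used to gauge it.
    """
    if n_total <= 0 or n_shared < 0 or n_shared > n_total:
        raise ValueError("need 0 <= n_shared <= n_total with n_total > 0")
    return 100.0 * n_shared / n_total
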
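"""Causal-effect estimators for harmonised summary sets.

Each SNP j contributes an exposure effect beta_x_j (se sigma_x_j) and an
outcome effect beta_y_j (se sigma_y_j) on a shared effect allele.  Under
the instrumental-variable assumptions the per-SNP ratio
beta_y_j / beta_x_j estimates the causal effect theta of the exposure on
the outcome.  The estimators differ in how they pool the ratios and in
which violations of the IV assumptions they tolerate:

wald_ratio
    Single-SNP ratio; se = sigma_y / |beta_x| (first order).
ivw
    Inverse-variance-weighted regression of beta_y on beta_x through the
    origin, weights 1/sigma_y^2.  Unbiased when pleiotropy is absent or
    balanced.  Fixed- and random-effects flavours share the same slope;
    the random model inflates the se by sqrt(Q/(L-1)) when the ratios are
    overdispersed.
maximum_likelihood
    Joint normal likelihood over the unknown true instrument effects and
    theta; accounts for measurement error in the SNP-exposure effects.
mr_egger
    Weighted regression *with* an intercept, which absorbs directional
    pleiotropy; unbiased under the InSIDE assumption (pleiotropic effects
    uncorrelated with instrument strength).
median_estimator
    Weighted median of the per-SNP ratios; consistent when at least half
    the weight comes from valid instruments.
mode_estimator
    Mode of a kernel-smoothed density of the ratios; consistent when the
    largest cluster of SNPs is valid (plurality validity).

All stochastic standard errors (median/mode bootstrap) take an explicit
seed and are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .harmonise import SummarySet

__all__ = [
    "MRResult", "wald_ratio", "ivw", "maximum_likelihood", "mr_egger",
    "median_estimator", "mode_estimator", "mr_all", "DEFAULT_METHODS",
]


@dataclass
class MRResult:
    """Uniform estimator output: method, estimate, se, CI, p-value, nSNP."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    model_flavour: str | None = None
    info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"method": self.method, "estimate": self.estimate, "se": self.se,
             "ci_low": self.ci_low, "ci_high": self.ci_high,
             "pval": self.pval, "nsnp": self.nsnp}
        if self.intercept is not None:
            d.update(intercept=self.intercept, intercept_se=self.intercept_se,
                     intercept_pval=self.intercept_pval)
        if self.model_flavour is not None:
            d["model_flavour"] = self.model_flavour
        return d


Z95 = stats.norm.ppf(0.975)


def _normal_result(method, estimate, se, nsnp, **kw) -> MRResult:
    z = estimate / se
    return MRResult(method=method, estimate=estimate, se=se,
                    ci_low=estimate - Z95 * se, ci_high=estimate + Z95 * se,
                    pval=float(2 * stats.norm.sf(abs(z))), nsnp=nsnp, **kw)


def _set_arrays(summary_set: SummarySet, minimum: int, method: str):
    bx, sx, by, sy = summary_set.arrays()
    if len(bx) < minimum:
        hint = ("; use wald_ratio for a single SNP"
                if minimum == 2 and len(bx) == 1 else "")
        raise ValueError(
            f"{method} requires at least {minimum} kept SNPs, "
            f"got {len(bx)}{hint}")
    return bx, sx, by, sy


def wald_ratio(row, second_order: bool = False) -> MRResult:
    """Single-instrument causal estimate beta_y/beta_x.

    ``row`` is one kept SummarySet row (anything with beta_exp/se_exp/
    beta_out/se_out attributes or keys).  First-order se is
    sigma_y/|beta_x|; ``second_order`` adds the delta-method term for
    uncertainty in beta_x.
    """
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    bx, sx = float(get("beta_exp")), float(get("se_exp"))
    by, sy = float(get("beta_out")), float(get("se_out"))
    if bx == 0:
        raise ZeroDivisionError("null instrument: beta_exp is 0")
    estimate = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    return _normal_result("wald_ratio", estimate, se, 1)


def _ivw_parts(bx, by, sy):
    w = sy**-2.0
    sw_bx2 = float(np.sum(w * bx * bx))
    slope = float(np.sum(w * bx * by)) / sw_bx2
    se_fixed = math.sqrt(1.0 / sw_bx2)
    q = float(np.sum(w * (by - slope * bx) ** 2))
    return slope, se_fixed, q


def ivw(summary_set: SummarySet, flavour: str = "auto") -> MRResult:
    """Inverse-variance-weighted estimate (regression through the origin).

    ``flavour``: "fixed", "random" (multiplicative overdispersion) or
    "auto" (default: random unless the ratios are underdispersed,
    Q/(L-1) < 1, in which case fixed).  Fixed and random share the same
    slope; only the se differs.
    """
    if flavour not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown IVW flavour {flavour!r}")
    bx, _, by, sy = _set_arrays(summary_set, 2, "ivw")
    L = len(bx)
    slope, se_fixed, q = _ivw_parts(bx, by, sy)
    disp = q / (L - 1)
    if flavour == "auto":
        flavour = "fixed" if disp < 1 else "random"
    se = se_fixed if flavour == "fixed" else se_fixed * max(1.0, math.sqrt(disp))
    method = "ivw_fe" if flavour == "fixed" else "ivw_re"
    return _normal_result(method, slope, se, L, model_flavour=flavour,
                          info={"Q": q, "Q_df": L - 1})


def _profile_neg2ll(theta, bx, sx, by, sy):
    # closed-form profile over the true instrument effects xi_j
    vx, vy = sx**2, sy**2
    xi = (bx / vx + theta * by / vy) / (1.0 / vx + theta**2 / vy)
    return float(np.sum((bx - xi) ** 2 / vx + (by - theta * xi) ** 2 / vy))


def maximum_likelihood(summary_set: SummarySet) -> MRResult:
    """Maximum-likelihood estimate of the causal effect.

    Models beta_x_j ~ N(xi_j, sigma_x_j^2) and
    beta_y_j ~ N(theta*xi_j, sigma_y_j^2) with independent errors and a
    linear exposure-outcome relationship; the nuisance xi_j are profiled
    out in closed form and theta maximised numerically.  The se comes
    from the curvature of the profile log-likelihood, which is robust to
    measurement error in the SNP-exposure effects (unlike IVW, which
    treats beta_x as fixed).
    """
    bx, sx, by, sy = _set_arrays(summary_set, 2, "maximum_likelihood")
    L = len(bx)
    start, _, _ = _ivw_parts(bx, by, sy)
    span = 10.0 * (abs(start) + 1.0)
    try:
        res = optimize.minimize_scalar(
            _profile_neg2ll, bracket=(start - 0.5, start + 0.5),
            args=(bx, sx, by, sy), method="brent", options={"xtol": 1e-10})
    except (RuntimeError, ValueError):
        res = optimize.minimize_scalar(
            _profile_neg2ll, bounds=(start - span, start + span),
            args=(bx, sx, by, sy), method="bounded",
            options={"xatol": 1e-10})
    if not res.success or not np.isfinite(res.x) or abs(res.x - start) > span:
        raise RuntimeError(
            f"likelihood maximisation failed: {getattr(res, 'message', res)}")
    theta = float(res.x)
    # observed information from the profile -2logL curvature
    h = 1e-4 * (abs(theta) + 1.0)
    f0 = _profile_neg2ll(theta, bx, sx, by, sy)
    fp = _profile_neg2ll(theta + h, bx, sx, by, sy)
    fm = _profile_neg2ll(theta - h, bx, sx, by, sy)
    d2 = (fp - 2 * f0 + fm) / h**2  # curvature of -2logL
    if d2 <= 0:
        raise RuntimeError("non-positive information at the optimum")
    se = math.sqrt(2.0 / d2)
    return _normal_result("max_lik", theta, se, L,
                          info={"converged": True, "n_iter": res.nit})


def _orient_positive(bx, by):
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def mr_egger(summary_set: SummarySet) -> MRResult:
    """Egger regression: weighted fit of beta_y on beta_x with intercept.

    SNPs are first oriented so every beta_x >= 0 (the intercept is only
    interpretable under a fixed exposure-increasing orientation).  The
    slope estimates the causal effect under InSIDE; the intercept
    estimates the average directional pleiotropic effect.  SEs carry a
    multiplicative overdispersion factor floored at 1; inference uses
    t(L-2).
    """
    import statsmodels.api as sm

    bx, _, by, sy = _set_arrays(summary_set, 3, "mr_egger")
    L = len(bx)
    bx, by = _orient_positive(bx, by)
    X = sm.add_constant(bx)
    w = sy**-2.0
    fit = sm.WLS(by, X, weights=w).fit()
    inter, slope = fit.params
    df = L - 2
    q_prime = float(fit.scale * df)  # weighted residual sum of squares
    # dispersion floored at 1: underdispersed fits keep the fixed weights
    sigma2 = max(1.0, fit.scale)
    cov_unit = np.linalg.inv(X.T @ (w[:, None] * X))
    inter_se, slope_se = np.sqrt(sigma2 * np.diag(cov_unit))

    def tpval(est, se):
        return float(2 * stats.t.sf(abs(est / se), df))

    tq = stats.t.ppf(0.975, df)
    return MRResult(
        method="mr_egger", estimate=float(slope), se=float(slope_se),
        ci_low=float(slope - tq * slope_se), ci_high=float(slope + tq * slope_se),
        pval=tpval(slope, slope_se), nsnp=L,
        intercept=float(inter), intercept_se=float(inter_se),
        intercept_pval=tpval(inter, inter_se),
        info={"Q": q_prime, "Q_df": df})


def _ratios(bx, by, sy, drop_null=True):
    ok = bx != 0
    return by[ok] / bx[ok], sy[ok] / np.abs(bx[ok]), ok


def weighted_quantile(values, weights, q=0.5) -> float:
    """Quantile of a weighted sample with linear interpolation.

    Cumulative weights are centred (cum - w/2, normalised); the quantile
    interpolates linearly between the bracketing order statistics.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if q <= cum[0]:
        return float(v[0])
    if q >= cum[-1]:
        return float(v[-1])
    return float(np.interp(q, cum, v))


def _median_point(bx, by, sy, weighting):
    ratios, _, ok = _ratios(bx, by, sy)
    if weighting == "simple":
        w = np.ones_like(ratios)
    else:
        w = sy[ok] ** -2.0  # inverse variance of the SNP-outcome association
    return weighted_quantile(ratios, w, 0.5)


def median_estimator(
    summary_set: SummarySet,
    weighting: str = "weighted",
    n_boot: int = 1000,
    seed: int | None = None,
) -> MRResult:
    """Median-based estimate; robust to up to 50% invalid weight.

    ``weighting``: "simple" (plain median of ratios) or "weighted"
    (weights 1/sigma_y^2).  The se is a seeded parametric bootstrap:
    beta_x_j and beta_y_j are resampled from normals with their reported
    SEs and the median recomputed.
    """
    if weighting not in ("simple", "weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if seed is None:
        raise ValueError("median_estimator requires an explicit seed")
    bx, sx, by, sy = _set_arrays(summary_set, 2, "median_estimator")
    if np.any(bx == 0):
        import warnings
        warnings.warn("excluding SNPs with beta_exp == 0", stacklevel=2)
    est = _median_point(bx, by, sy, weighting)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        boots[b] = _median_point(bxs, bys, sy, weighting)
    se = float(np.std(boots, ddof=1))
    method = f"{weighting}_median"
    res = _normal_result(method, est, max(se, 1e-300), int(np.sum(bx != 0)))
    res.info = {"n_boot": n_boot, "seed": seed}
    return res


def silverman_bandwidth(x, weights=None, factor: float = 1.0) -> float:
    """Modified Silverman rule: 0.9 * min(SD, MAD/0.6745) * L^(-1/5)."""
    x = np.asarray(x, float)
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    mad = float(np.median(np.abs(x - np.median(x)))) / 0.6745
    spread = min(s for s in (sd, mad) if s > 0) if max(sd, mad) > 0 else 0.0
    return factor * 0.9 * spread * len(x) ** (-1 / 5)


def _mode_point(bx, by, sy, weighting, bandwidth_factor, grid_size=512):
    ratios, ratio_se, _ = _ratios(bx, by, sy)
    if weighting == "simple":
        w = np.ones_like(ratios)
    else:
        w = ratio_se**-2.0
    w = w / w.sum()
    h = silverman_bandwidth(ratios, factor=bandwidth_factor)
    if h <= 0 or np.ptp(ratios) == 0:
        # degenerate: all ratios (effectively) identical
        return float(np.average(ratios, weights=w))
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimator(
    summary_set: SummarySet,
    weighting: str = "weighted",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MRResult:
    """Mode-based estimate: argmax of a kernel-smoothed ratio density.

    SNPs cluster by the causal effect they imply; the cluster carrying
    the largest (inverse-variance or equal) weight wins.  Bandwidth is
    ``bandwidth_factor`` x the modified Silverman rule on the ratio
    estimates; se via seeded parametric bootstrap of the argmax.
    """
    if weighting not in ("simple", "weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if seed is None:
        raise ValueError("mode_estimator requires an explicit seed")
    bx, sx, by, sy = _set_arrays(summary_set, 3, "mode_estimator")
    est = _mode_point(bx, by, sy, weighting, bandwidth_factor)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _mode_point(rng.normal(bx, sx), rng.normal(by, sy), sy,
                               weighting, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    method = f"{weighting}_mode"
    res = _normal_result(method, est, max(se, 1e-300), len(bx))
    res.info = {"n_boot": n_boot, "seed": seed,
                "bandwidth_factor": bandwidth_factor}
    return res


DEFAULT_METHODS = ["ivw", "max_lik", "mr_egger", "weighted_median",
                   "weighted_mode"]

_MIN_SNPS = {"wald_ratio": 1, "ivw": 2, "ivw_fe": 2, "ivw_re": 2,
             "max_lik": 2, "mr_egger": 3, "simple_median": 2,
             "weighted_median": 2, "simple_mode": 3, "weighted_mode": 3}


def _dispatch(name, summary_set, seed, n_boot):
    if name == "wald_ratio":
        return wald_ratio(summary_set.kept().iloc[0])
    if name == "ivw":
        return ivw(summary_set, "auto")
    if name == "ivw_fe":
        return ivw(summary_set, "fixed")
    if name == "ivw_re":
        return ivw(summary_set, "random")
    if name == "max_lik":
        return maximum_likelihood(summary_set)
    if name == "mr_egger":
        return mr_egger(summary_set)
    if name in ("simple_median", "weighted_median"):
        return median_estimator(summary_set, name.split("_")[0],
                                n_boot=n_boot, seed=seed)
    if name in ("simple_mode", "weighted_mode"):
        return mode_estimator(summary_set, name.split("_")[0],
                              n_boot=n_boot, seed=seed)
    raise KeyError(f"unknown method {name!r}")


def mr_all(
    summary_set: SummarySet,
    methods: list[str] | None = None,
    seed: int | None = 0,
    n_boot: int = 1000,
) -> tuple[list[MRResult], list[dict]]:
    """Run a battery of estimators on one summary set.

    Methods whose minimum-SNP precondition fails are skipped with a
    recorded reason rather than raising.  Returns (results, skipped);
    deterministic given ``seed``.
    """
    if methods is None:
        methods = list(DEFAULT_METHODS)
        if summary_set.n_kept == 1:
            methods = ["wald_ratio"] + methods
    unknown = [m for m in methods if m not in _MIN_SNPS]
    if unknown:
        raise KeyError(f"unknown method names: {unknown}")
    results, skipped = [], []
    for name in methods:
        need = _MIN_SNPS[name]
        if summary_set.n_kept < need:
            skipped.append({"method": name,
                            "reason": f"requires >= {need} SNPs, "
                                      f"have {summary_set.n_kept}"})
            continue
        results.append(_dispatch(name, summary_set, seed, n_boot))
    return results, skipped
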
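"""Synthetic two-sample MR summary data under controlled pleiotropy regimes.

The generator draws L independent instruments with true exposure effects
xi_j, then produces observed GWAS summary effects

    beta_x_j ~ N(xi_j,           sigma_x_j^2)
    beta_y_j ~ N(theta*xi_j + alpha_j, sigma_y_j^2)

where theta is the causal effect and alpha_j a per-SNP horizontal
pleiotropic effect.  Standard errors follow the standardised-trait GWAS
formula sigma^2 = 1 / (2*maf*(1-maf)*n), so sample size and allele
frequency control precision exactly as in real summary statistics.

Pleiotropy regimes (``pleiotropy_mode``):

none
    alpha_j = 0 — all instruments valid.
balanced
    alpha_j ~ N(0, sd) on the invalid fraction: heterogeneity without
    directional bias; IVW remains unbiased.
directional_inside
    alpha_j ~ N(mean, sd), independent of xi_j (InSIDE holds): IVW is
    biased by roughly mean/E[xi], Egger's intercept absorbs the mean and
    its slope stays unbiased.
correlated
    alpha_j loads linearly on xi_j (InSIDE violated): even Egger is
    biased; the median/mode families are the defensible estimators.
clustered
    alpha_j = (effect_c - theta) * xi_j within each cluster of
    ``cluster_spec``, so each invalid cluster implies a common spurious
    causal effect; the mode estimator should select the valid plurality.

Every draw is reproducible from ``seed``; the returned truth record
carries theta, xi, alpha and per-SNP validity flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .harmonise import COMPLEMENT, SUMMARY_COLUMNS, SummarySet, is_palindromic
from .ld_tools import LDMatrix, ProxyRecord
from .summary_data import GwasRecord, StudyMeta
from scipy import stats

__all__ = ["SimulationConfig", "simulate_summary_set", "simulate_record_pair",
           "se_standardised"]

PLEIOTROPY_MODES = ("none", "balanced", "directional_inside", "correlated",
                    "clustered")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic two-sample MR study.

    Defaults describe a well-powered consortium setting: 50 instruments
    for a standardised continuous exposure measured in 200k samples,
    outcome in 200k samples, common variants (MAF 0.05-0.5), true
    instrument effects |N(0, 0.05)| SD per allele.
    """

    theta: float = 0.5
    L: int = 50
    n_exp: int = 200_000
    n_out: int = 200_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_x_sd: float = 0.05
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 1.0
    cluster_spec: Sequence[tuple[float, float]] = field(default_factory=list)
    palindromic_fraction: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible simulation")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.n_exp < 4 or self.n_out < 4:
            raise ValueError("sample sizes n_exp/n_out must be >= 4")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, "
                             f"got {self.maf_range}")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of "
                             f"{PLEIOTROPY_MODES}, got {self.pleiotropy_mode!r}")
        for name in ("invalid_fraction", "palindromic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.pleiotropy_mode == "clustered":
            if not self.cluster_spec:
                raise ValueError("clustered mode requires cluster_spec")
            total = sum(f for f, _ in self.cluster_spec)
            if total > 1.0 + 1e-12:
                raise ValueError("cluster fractions must sum to <= 1")


def se_standardised(maf, n):
    """Analytic SE of a per-allele effect on a standardised trait:
    1 / sqrt(2*maf*(1-maf)*n)."""
    maf = np.asarray(maf, float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * np.asarray(n, float))


def _draw_alpha(cfg: SimulationConfig, xi, rng):
    L = len(xi)
    alpha = np.zeros(L)
    if cfg.pleiotropy_mode == "none":
        return alpha, np.ones(L, bool)
    if cfg.pleiotropy_mode == "clustered":
        valid = np.ones(L, bool)
        start = 0
        order = rng.permutation(L)
        for frac, effect in cfg.cluster_spec:
            size = int(round(frac * L))
            idx = order[start:start + size]
            alpha[idx] = (effect - cfg.theta) * xi[idx]
            valid[idx] = False
            start += size
        return alpha, valid
    n_invalid = int(round(cfg.invalid_fraction * L))
    invalid = np.zeros(L, bool)
    invalid[rng.permutation(L)[:n_invalid]] = True
    if cfg.pleiotropy_mode == "balanced":
        alpha[invalid] = rng.normal(0.0, cfg.pleiotropy_sd, invalid.sum())
    elif cfg.pleiotropy_mode == "directional_inside":
        alpha[invalid] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd,
                                    invalid.sum())
    elif cfg.pleiotropy_mode == "correlated":
        # InSIDE violation: alpha loads on instrument strength
        load = cfg.pleiotropy_mean / max(float(np.mean(np.abs(xi))), 1e-12)
        alpha[invalid] = (load * xi[invalid]
                          + rng.normal(0.0, cfg.pleiotropy_sd, invalid.sum()))
    return alpha, ~invalid


def _core_draw(cfg: SimulationConfig, rng):
    maf = rng.uniform(*cfg.maf_range, cfg.L)
    xi = np.abs(rng.normal(0.0, cfg.beta_x_sd, cfg.L))
    sx = se_standardised(maf, cfg.n_exp)
    sy = se_standardised(maf, cfg.n_out)
    alpha, valid = _draw_alpha(cfg, xi, rng)
    bx = rng.normal(xi, sx)
    by = rng.normal(cfg.theta * xi + alpha, sy)
    return maf, xi, alpha, valid, bx, sx, by, sy


def _pvals(beta, se):
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def simulate_summary_set(cfg: SimulationConfig,
                         noise_free: bool = False,
                         noise_free_exposure: bool = False,
                         ) -> tuple[SummarySet, dict]:
    """Generate a harmonisation-ready SummarySet plus its ground truth.

    ``noise_free`` replaces the observed effects with their means
    (beta_x = xi, beta_y = theta*xi + alpha) while keeping the analytic
    SEs — the zero-measurement-error limit in which every valid ratio
    equals theta exactly.  ``noise_free_exposure`` removes sampling error
    from the exposure side only (beta_x = xi, beta_y noisy): the regime
    the IVW and Egger regression models assume, in which the SNP-exposure
    effects act as fixed regressors.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    maf, xi, alpha, valid, bx, sx, by, sy = _core_draw(cfg, rng)
    if noise_free or noise_free_exposure:
        bx = xi.copy()
    if noise_free:
        by = cfg.theta * xi + alpha
    snps = [f"rs{i + 1}" for i in range(cfg.L)]
    table = pd.DataFrame({
        "SNP": snps, "effect_allele": "A", "other_allele": "G",
        "beta_exp": bx, "se_exp": sx, "eaf_exp": maf,
        "pval_exp": _pvals(bx, sx), "n_exp": cfg.n_exp,
        "beta_out": by, "se_out": sy, "eaf_out": maf,
        "pval_out": _pvals(by, sy), "n_out": cfg.n_out,
        "palindromic": False, "ambiguous": False,
        "keep": True, "exclusion_reason": "",
    })[SUMMARY_COLUMNS]
    truth = {"theta": cfg.theta, "xi": xi, "alpha": alpha, "valid": valid,
             "maf": maf, "config": asdict(cfg)}
    meta_x = StudyMeta(trait="simulated exposure", units="SD", n=cfg.n_exp,
                       id="sim-exposure")
    meta_y = StudyMeta(trait="simulated outcome", units="SD", n=cfg.n_out,
                       id="sim-outcome")
    return SummarySet(table, action=1, exposure_meta=meta_x,
                      outcome_meta=meta_y), truth


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMES = [("A", "T"), ("G", "C")]


def simulate_record_pair(
    cfg: SimulationConfig,
    scramble: bool = True,
    drop_from_outcome: int = 0,
    noise_free: bool = False,
) -> tuple[list[GwasRecord], list[GwasRecord], LDMatrix, list[ProxyRecord]]:
    """Un-harmonised exposure/outcome record files for end-to-end runs.

    Outcome records have deliberately scrambled allele orientations
    (random effect/other swaps and strand complements on non-palindromic
    SNPs) that harmonisation must undo.  A fraction
    ``cfg.palindromic_fraction`` of SNPs gets A/T or G/C alleles.  Each
    instrument comes with one satellite SNP in strong LD (r2=0.95) and a
    weaker p-value, so clumping has real work to do, and the LD matrix is
    block-diagonal over those pairs.  ``drop_from_outcome`` removes the
    last k instruments from the outcome records; a consistent r2=1 proxy
    table allows the pipeline to recover them.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    maf, xi, alpha, valid, bx, sx, by, sy = _core_draw(cfg, rng)
    if noise_free:
        bx = xi.copy()
        by = cfg.theta * xi + alpha
    L = cfg.L
    snps = [f"rs{i + 1}" for i in range(L)]

    n_pal = int(round(cfg.palindromic_fraction * L))
    pal_idx = set(rng.permutation(L)[:n_pal].tolist())
    pairs = []
    for i in range(L):
        if i in pal_idx:
            pairs.append(_PALINDROMES[int(rng.integers(2))])
        else:
            pairs.append(_ALLELE_PAIRS[int(rng.integers(4))])

    px = _pvals(bx, sx)
    py = _pvals(by, sy)
    exposure, outcome = [], []
    proxies: list[ProxyRecord] = []
    sat_records = []
    positions, ld_snps = [], []
    r2 = np.zeros((2 * L, 2 * L))
    for i, snp in enumerate(snps):
        ea, oa = pairs[i]
        exposure.append(GwasRecord(snp, ea, oa, float(maf[i]), float(bx[i]),
                                   float(sx[i]), float(px[i]), cfg.n_exp))
        # outcome orientation scrambling (undone by harmonisation)
        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(by[i]), float(maf[i])
        if scramble:
            if rng.random() < 0.5:  # swap effect/other alleles
                o_ea, o_oa = o_oa, o_ea
                o_beta, o_eaf = -o_beta, 1.0 - o_eaf
            if i not in pal_idx and rng.random() < 0.5:  # strand complement
                o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        outcome.append(GwasRecord(snp, o_ea, o_oa, o_eaf, o_beta,
                                  float(sy[i]), float(py[i]), cfg.n_out))

        # satellite SNP in strong LD: same signal, inflated se, so the
        # index SNP always carries the smaller p within its block
        sat = f"{snp}_b"
        sat_bx = float(bx[i])
        sat_px = float(_pvals(np.array([sat_bx]), np.array([sx[i] * 1.2]))[0])
        sat_records.append(GwasRecord(sat, ea, oa, float(maf[i]), sat_bx,
                                      float(sx[i] * 1.2), sat_px, cfg.n_exp))
        base = 1_000_000 * (i + 1)
        ld_snps.extend([snp, sat])
        positions.extend([base, base + 5_000])
        j = 2 * i
        r2[j, j] = r2[j + 1, j + 1] = 1.0
        r2[j, j + 1] = r2[j + 1, j] = 0.95

        # perfect-LD proxy available in the outcome for every instrument
        proxy_id = f"{snp}_p"
        proxies.append(ProxyRecord(target=snp, proxy=proxy_id, r2=1.0,
                                   phase={ea: ea, oa: oa},
                                   distance_bp=2_000))
        outcome.append(GwasRecord(proxy_id, ea, oa, float(maf[i]),
                                  float(by[i]), float(sy[i]), float(py[i]),
                                  cfg.n_out))

    exposure = exposure + sat_records
    ld = LDMatrix(ld_snps, np.array(positions), r2)

    if drop_from_outcome:
        dropped = set(snps[-drop_from_outcome:])
        outcome = [r for r in outcome if r.snp not in dropped]

    return exposure, outcome, ld, proxies
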
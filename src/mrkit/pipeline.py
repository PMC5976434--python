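"""End-to-end 2SMR orchestration.

``run_mr_pipeline`` chains the whole workflow — read and QC both summary
files, select genome-wide-significant independent instruments, extract
outcome effects (falling back to LD proxies for missing SNPs), harmonise,
estimate with the full method battery and run every diagnostic — and
writes a reproducible report bundle: tab-delimited result tables plus a
JSON manifest of all inputs, parameters and seeds.  Re-running a manifest
reproduces the tables byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .estimators import DEFAULT_METHODS, mr_all
from .harmonise import SummarySet, count_exclusions, harmonise
from .ld_tools import LDMatrix, ProxyRecord, apply_proxy, clump, find_proxy
from .sensitivity import (funnel_data, heterogeneity, leave_one_out,
                          single_snp_forest, steiger)
from .summary_data import GwasRecord, qc_records, read_summary_file

__all__ = ["RunConfig", "select_instruments", "run_mr_pipeline",
           "bonferroni_threshold", "fdr_threshold_mask"]

log = logging.getLogger("mrkit.pipeline")

#: Conventional genome-wide significance threshold for instrument discovery.
GWAS_P_THRESHOLD = 5e-8


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    exposure_path: str
    outcome_path: str
    output_dir: str
    ld_matrix_path: str | None = None
    ld_sidecar_path: str | None = None
    proxy_path: str | None = None
    exposure_columns: dict | None = None
    outcome_columns: dict | None = None
    action: int = 2
    p_threshold: float = GWAS_P_THRESHOLD
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    methods: list[str] = field(default_factory=lambda: list(DEFAULT_METHODS))
    n_boot: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0,1]")
        if self.action not in (1, 2, 3):
            raise ValueError("action must be 1, 2 or 3")
        for p in (self.exposure_path, self.outcome_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def select_instruments(
    records: Sequence[GwasRecord],
    p_threshold: float = GWAS_P_THRESHOLD,
    ld: LDMatrix | None = None,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000,
) -> list[GwasRecord]:
    """Filter to p < threshold, then clump to independent index SNPs."""
    hits = [r for r in records if r.pval < p_threshold]
    if not hits:
        raise ValueError(
            f"no instruments: no SNP passes p < {p_threshold:g}")
    if ld is None:
        return hits
    retained = set(clump(hits, ld, clump_r2, clump_kb))
    out = [r for r in hits if r.snp in retained]
    log.info("selected %d instruments (%d significant before clumping)",
             len(out), len(hits))
    return out


def _extract_outcome(instruments, outcome_records, proxies):
    """Outcome records for each instrument, proxy-substituted when absent."""
    by_snp = {r.snp: r for r in outcome_records}
    available = set(by_snp)
    out, proxy_log = [], []
    for rec in instruments:
        if rec.snp in by_snp:
            out.append(by_snp[rec.snp])
            continue
        hit = find_proxy(rec.snp, available, proxies or [])
        if hit is None:
            proxy_log.append({"target": rec.snp, "proxy": "", "r2": ""})
            continue
        out.append(apply_proxy(by_snp[hit.proxy], hit))
        proxy_log.append({"target": rec.snp, "proxy": hit.proxy,
                          "r2": hit.r2})
    return out, proxy_log


def run_mr_pipeline(config: RunConfig) -> dict:
    """Execute the full 2SMR chain and write the report bundle.

    Writes to ``config.output_dir``: summary_set.tsv, mr_results.tsv,
    heterogeneity.tsv, egger_intercept.tsv, leave_one_out.tsv,
    single_snp.tsv, funnel.tsv, steiger.tsv, exclusions.tsv and
    manifest.json.  Returns the artifacts in memory keyed by the same
    names (minus extension).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        stage("read exposure")
        exp_raw, exp_rej = read_summary_file(config.exposure_path,
                                             config.exposure_columns)
        exp_clean, exp_qc = qc_records(exp_raw)
        stage("read outcome")
        out_raw, out_rej = read_summary_file(config.outcome_path,
                                             config.outcome_columns)
        out_clean, out_qc = qc_records(out_raw)
    except Exception as exc:
        raise RuntimeError(f"[input] {exc}") from exc

    ld = None
    if config.ld_matrix_path:
        ld = LDMatrix.from_square_file(config.ld_matrix_path,
                                       config.ld_sidecar_path)
    proxies: list[ProxyRecord] = []
    if config.proxy_path:
        from .ld_tools import read_proxy_table
        proxies = read_proxy_table(config.proxy_path)

    try:
        stage("select instruments")
        instruments = select_instruments(exp_clean, config.p_threshold, ld,
                                         config.clump_r2, config.clump_kb)
        stage("extract outcome effects")
        outcome_rows, proxy_log = _extract_outcome(instruments, out_clean,
                                                   proxies)
        stage("harmonise")
        summary_set = harmonise(instruments, outcome_rows, config.action)
    except Exception as exc:
        raise RuntimeError(f"[harmonise] {exc}") from exc

    stage("estimate")
    results, skipped = mr_all(summary_set, config.methods,
                              seed=config.seed, n_boot=config.n_boot)
    mr_table = pd.DataFrame([r.to_dict() for r in results])

    het_rows = []
    for method, minimum in (("ivw", 2), ("egger", 3)):
        if summary_set.n_kept >= minimum:
            h = heterogeneity(summary_set, method)
            het_rows.append({"method": method, "Q": h.Q, "df": h.df,
                             "pval": h.pval})
    het_table = pd.DataFrame(het_rows)

    egger = next((r for r in results if r.method == "mr_egger"), None)
    egger_table = pd.DataFrame(
        [] if egger is None else
        [{"intercept": egger.intercept, "se": egger.intercept_se,
          "pval": egger.intercept_pval}])

    loo = (leave_one_out(summary_set, "ivw", seed=config.seed,
                         n_boot=config.n_boot)
           if summary_set.n_kept >= 3 else pd.DataFrame())
    forest = single_snp_forest(summary_set, config.methods,
                               seed=config.seed, n_boot=config.n_boot)
    funnel = funnel_data(summary_set)

    kept = summary_set.kept()
    if summary_set.n_kept and kept["n_exp"].notna().all() \
            and kept["n_out"].notna().all():
        s = steiger(summary_set)
        steiger_table = pd.DataFrame([{
            "r2_exposure": s.r2_exposure, "r2_outcome": s.r2_outcome,
            "direction_correct": s.direction_correct,
            "steiger_pval": s.steiger_pval}])
    else:
        steiger_table = pd.DataFrame()

    excl = count_exclusions(summary_set)
    excl_rows = [{"reason": k, "count": v} for k, v in sorted(excl.items())]
    excl_rows += [{"reason": f"qc ({r})", "count": c}
                  for r, c in sorted(exp_qc.counts.items())]
    excl_rows += [{"reason": f"read rejection", "count": len(exp_rej) + len(out_rej)}] \
        if (exp_rej or out_rej) else []
    excl_table = pd.DataFrame(excl_rows, columns=["reason", "count"])

    artifacts = {
        "summary_set": summary_set.table,
        "mr_results": mr_table,
        "heterogeneity": het_table,
        "egger_intercept": egger_table,
        "leave_one_out": loo,
        "single_snp": forest,
        "funnel": funnel,
        "steiger": steiger_table,
        "exclusions": excl_table,
    }
    for name, df in artifacts.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.17g")

    manifest = {
        "mrkit_version": __version__,
        "config": asdict(config),
        "skipped_methods": skipped,
        "proxy_substitutions": proxy_log,
        "n_instruments": len(instruments),
        "n_kept": summary_set.n_kept,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    artifacts["manifest"] = manifest
    return artifacts


def run_from_manifest(manifest_path: str | Path) -> dict:
    """Replay a run from its manifest; outputs are byte-identical."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = RunConfig(**manifest["config"])
    return run_mr_pipeline(cfg)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise p-value threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return alpha / n_tests


def fdr_threshold_mask(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg discovery mask for a PheWAS-style scan."""
    from statsmodels.stats.multitest import multipletests
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject
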
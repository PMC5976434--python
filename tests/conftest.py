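import numpy as np
import pandas as pd
import pytest

from mrkit import GwasRecord, SimulationConfig, simulate_summary_set


@pytest.fixture
def toy_records():
    """Three clean biallelic records."""
    return [
        GwasRecord("rs1", "A", "G", 0.30, 0.12, 0.02, 2e-9, 50_000),
        GwasRecord("rs2", "C", "T", 0.45, -0.08, 0.015, 1e-7, 50_000),
        GwasRecord("rs3", "G", "A", 0.10, 0.20, 0.03, 3e-11, 50_000),
    ]


@pytest.fixture
def sim_set():
    """A 30-SNP simulated summary set with no pleiotropy, seeded."""
    cfg = SimulationConfig(theta=0.5, L=30, seed=11)
    sset, truth = simulate_summary_set(cfg)
    return sset, truth


def make_set(bx, by, sy, sx=None, snps=None):
    """Hand-built SummarySet from effect arrays (sx defaults tiny)."""
    from mrkit.harmonise import SUMMARY_COLUMNS, SummarySet

    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, float)
    L = len(bx)
    table = pd.DataFrame({
        "SNP": snps or [f"rs{i+1}" for i in range(L)],
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": bx, "se_exp": sx, "eaf_exp": 0.3,
        "pval_exp": 1e-9, "n_exp": 100_000,
        "beta_out": by, "se_out": sy, "eaf_out": 0.3,
        "pval_out": 0.01, "n_out": 100_000,
        "palindromic": False, "ambiguous": False,
        "keep": True, "exclusion_reason": "",
    })[SUMMARY_COLUMNS]
    return SummarySet(table, action=1)
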
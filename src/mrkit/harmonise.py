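"""Aligning exposure and outcome SNP effects onto a shared effect allele.

Two GWAS rarely report a SNP with the same effect allele, and may report
it on opposite reference strands.  Harmonisation brings the SNP-outcome
effect onto the exposure study's effect allele so that the ratio
beta_out / beta_exp is meaningful.  Four scenarios arise:

1. Alleles already aligned — copy through.
2. Swapped effect/other alleles (G/T vs T/G) — flip the sign of the
   outcome effect and replace its eaf by 1 - eaf.
3. Strand difference (G/T vs C/A) — complement the outcome alleles
   (A<->T, C<->G), then apply rule 1 or 2.
4. Palindromic SNPs (A/T or G/C) — the letters alone cannot distinguish
   a strand flip from an allele swap.  Behaviour is controlled by
   ``action``: 1 assumes both studies report the forward strand; 2 infers
   orientation from the effect-allele frequencies (dropping SNPs whose
   frequency is too close to 0.5 to call); 3 drops all palindromic SNPs.

Anything else (A/G vs A/C) is an incompatible-allele error and the SNP is
excluded with a recorded reason.  The outcome side is always the one
modified; the exposure effects pass through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .summary_data import GwasRecord, StudyMeta

__all__ = ["SummarySet", "harmonise", "count_exclusions",
           "COMPLEMENT", "is_palindromic"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default half-width of the frequency band around 0.5 inside which a
#: palindromic SNP's orientation is considered unresolvable from EAF.
DEFAULT_EAF_BAND = 0.08

SUMMARY_COLUMNS = [
    "SNP", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "eaf_exp", "pval_exp", "n_exp",
    "beta_out", "se_out", "eaf_out", "pval_out", "n_out",
    "palindromic", "ambiguous", "keep", "exclusion_reason",
]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and G/C SNPs, whose alleles read the same on both strands."""
    return {a1, a2} in ({"A", "T"}, {"G", "C"})


@dataclass
class SummarySet:
    """Harmonised per-SNP exposure and outcome effects on a shared allele.

    ``table`` has one row per shared SNP with columns ``SUMMARY_COLUMNS``.
    Rows with ``keep == False`` carry an ``exclusion_reason`` and are
    ignored by every estimator.
    """

    table: pd.DataFrame
    action: int = 2
    exposure_meta: StudyMeta = field(default_factory=StudyMeta)
    outcome_meta: StudyMeta = field(default_factory=StudyMeta)

    def kept(self) -> pd.DataFrame:
        return self.table[self.table["keep"]].reset_index(drop=True)

    @property
    def n_kept(self) -> int:
        return int(self.table["keep"].sum())

    def __len__(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) over kept rows."""
        k = self.kept()
        return (k["beta_exp"].to_numpy(float), k["se_exp"].to_numpy(float),
                k["beta_out"].to_numpy(float), k["se_out"].to_numpy(float))

    def subset(self, mask) -> "SummarySet":
        """New SummarySet restricted to kept rows selected by boolean mask."""
        k = self.kept()
        return SummarySet(k[np.asarray(mask, bool)].reset_index(drop=True),
                          self.action, self.exposure_meta, self.outcome_meta)

    def to_file(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_file(cls, path: str | Path, action: int = 2) -> "SummarySet":
        df = pd.read_csv(path, sep="\t")
        df["keep"] = df["keep"].astype(bool)
        df["palindromic"] = df["palindromic"].astype(bool)
        df["ambiguous"] = df["ambiguous"].astype(bool)
        df["exclusion_reason"] = df["exclusion_reason"].fillna("")
        return cls(df, action=action)


def _exclude(row: dict, reason: str) -> dict:
    row["keep"] = False
    row["exclusion_reason"] = reason
    return row


def _harmonise_one(exp: GwasRecord, out: GwasRecord, action: int,
                   band: float) -> dict:
    ea_e, oa_e = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele

    row = {
        "SNP": exp.snp, "effect_allele": ea_e, "other_allele": oa_e,
        "beta_exp": exp.beta, "se_exp": exp.se, "eaf_exp": exp.eaf,
        "pval_exp": exp.pval, "n_exp": exp.n,
        "beta_out": out.beta, "se_out": out.se, "eaf_out": out.eaf,
        "pval_out": out.pval, "n_out": out.n,
        "palindromic": False, "ambiguous": False,
        "keep": True, "exclusion_reason": "",
    }

    if oa_e is None or oa_o is None:
        return _exclude(row, "missing other allele")

    def flip_outcome():
        row["beta_out"] = -row["beta_out"]
        if row["eaf_out"] is not None:
            row["eaf_out"] = 1.0 - row["eaf_out"]

    if is_palindromic(ea_e, oa_e):
        row["palindromic"] = True
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return _exclude(row, "incompatible alleles")
        if action == 3:
            return _exclude(row, "palindromic")
        # align by letters first (complementing is a no-op on the letter pair)
        if ea_o != ea_e:
            flip_outcome()
        if action == 1:
            return row
        # action 2: use allele frequencies to detect opposite reference strands
        eaf_e, eaf_o = row["eaf_exp"], row["eaf_out"]
        if eaf_e is None or eaf_o is None:
            row["ambiguous"] = True
            return _exclude(row, "palindromic, EAF missing")
        if abs(eaf_e - 0.5) < band or abs(eaf_o - 0.5) < band:
            row["ambiguous"] = True
            return _exclude(row, "palindromic, EAF ambiguous")
        if (eaf_e - 0.5) * (eaf_o - 0.5) < 0:
            # minor allele in one study, major in the other: strands differ
            flip_outcome()
        return row

    if (ea_o, oa_o) == (ea_e, oa_e):
        return row
    if (ea_o, oa_o) == (oa_e, ea_e):
        flip_outcome()
        return row
    ea_c, oa_c = COMPLEMENT.get(ea_o), COMPLEMENT.get(oa_o)
    if (ea_c, oa_c) == (ea_e, oa_e):
        return row
    if (ea_c, oa_c) == (oa_e, ea_e):
        flip_outcome()
        return row
    return _exclude(row, "incompatible alleles")


def harmonise(
    exposure: Iterable[GwasRecord],
    outcome: Iterable[GwasRecord],
    action: int = 2,
    eaf_ambiguity_band: float = DEFAULT_EAF_BAND,
    exposure_meta: StudyMeta | None = None,
    outcome_meta: StudyMeta | None = None,
) -> SummarySet:
    """Build a harmonised SummarySet from QC-clean exposure and outcome records.

    ``action`` selects the palindromic-SNP policy: 1 = assume forward
    strand in both studies; 2 = infer strand from effect-allele frequency
    (default); 3 = drop palindromic SNPs.  SNPs are matched on rsID;
    exposure input order is preserved.
    """
    if action not in (1, 2, 3):
        raise ValueError(f"action must be 1, 2 or 3, got {action}")
    out_by_snp: Mapping[str, GwasRecord] = {r.snp: r for r in outcome}
    rows = [_harmonise_one(e, out_by_snp[e.snp], action, eaf_ambiguity_band)
            for e in exposure if e.snp in out_by_snp]
    if not rows:
        warnings.warn("no SNPs shared between exposure and outcome",
                      stacklevel=2)
        table = pd.DataFrame(columns=SUMMARY_COLUMNS)
    else:
        table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return SummarySet(table, action=action,
                      exposure_meta=exposure_meta or StudyMeta(),
                      outcome_meta=outcome_meta or StudyMeta())


def count_exclusions(summary_set: SummarySet) -> dict[str, int]:
    """Exclusion-reason -> count over keep=False rows; values sum to the
    total number excluded."""
    excl = summary_set.table[~summary_set.table["keep"]]
    return excl["exclusion_reason"].value_counts().to_dict()
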
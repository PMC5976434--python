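"""Reading, standardising and quality-controlling GWAS summary statistics.

GWAS summary files arrive in wildly heterogeneous shapes.  Everything in
this package runs on a uniform 8-column record model: rsID, effect allele,
other allele, effect-allele frequency, beta, standard error, p-value and
sample size.  This module converts arbitrary delimited files into that
model (deriving missing standard errors from confidence intervals or
p-values, converting odds ratios to log odds ratios) and applies the
quality-control rules that every downstream step assumes:

* biallelic SNPs only, single-base A/C/G/T alleles;
* one record per rsID (duplicates resolved to the smallest p-value);
* se > 0, eaf in [0, 1], p in (0, 1], n > 0 where present.

Rejected rows are reported, never silently dropped.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GwasRecord",
    "StudyMeta",
    "or_to_logor",
    "se_from_ci",
    "se_from_beta_p",
    "read_summary_file",
    "write_summary_file",
    "qc_records",
]

VALID_ALLELES = frozenset("ACGT")

#: Smallest positive double; p-values of exactly 0 in input are coerced
#: to this value (common in truncated GWAS exports).
TINY_PVAL = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with one trait — the atom of all I/O.

    ``beta`` is the effect per copy of ``effect_allele``, in trait units
    for continuous traits or log odds for binary traits.
    """

    snp: str
    effect_allele: str
    other_allele: str | None
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if clean)."""
        problems = []
        if not self.snp:
            problems.append("missing snp id")
        if self.effect_allele not in VALID_ALLELES:
            problems.append("non-SNP variant" if len(self.effect_allele or "") > 1
                            else "invalid effect allele")
        if self.other_allele is not None and self.other_allele not in VALID_ALLELES:
            problems.append("non-SNP variant" if len(self.other_allele) > 1
                            else "invalid other allele")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append("eaf outside [0,1]")
        if not math.isfinite(self.beta):
            problems.append("beta not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            problems.append("se not > 0")
        if not (math.isfinite(self.pval) and 0.0 < self.pval <= 1.0):
            problems.append("pval outside (0,1]")
        if self.n is not None and self.n <= 0:
            problems.append("n not > 0")
        return problems


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata attached to a set of summary records."""

    trait: str = ""
    units: str = ""
    n: int | None = None
    ncase: int | None = None
    ncontrol: int | None = None
    trait_sd: float | None = None
    population: str = ""
    sex: str = "both"
    id: str = ""

    def __post_init__(self) -> None:
        if (self.ncase is not None and self.ncontrol is not None
                and self.n is not None and self.ncase + self.ncontrol > self.n):
            raise ValueError("ncase + ncontrol exceeds total sample size n")


def or_to_logor(odds_ratio: float) -> float:
    """Natural log of an odds ratio; raises on non-positive input."""
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return math.log(odds_ratio)


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal confidence interval.

    se = (upper - lower) / (2 * z), with z the (1+level)/2 normal quantile
    (1.959964 for 95% coverage).
    """
    if not 0 < level < 1:
        raise ValueError(f"coverage level must be in (0,1), got {level}")
    if upper <= lower:
        raise ValueError(f"upper bound {upper} must exceed lower bound {lower}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (upper - lower) / (2.0 * z)


def se_from_beta_p(beta: float, pval: float) -> float:
    """Standard error recovered from an effect estimate and its p-value.

    Inverts the two-sided Wald test: se = |beta| / |Phi^-1(p/2)|.
    """
    if beta == 0:
        raise ValueError("cannot recover se when beta is exactly 0")
    if not 0 < pval < 1:
        raise ValueError(
            f"p-value must be strictly inside (0,1) to invert, got {pval}")
    z = abs(stats.norm.ppf(pval / 2.0))
    return abs(beta) / z


_KNOWN_ROLES = {
    "snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n",
    "odds_ratio", "ci_lower", "ci_upper",
}
_MANDATORY = {"snp", "effect_allele", "beta"}


def _coerce_row(row: Mapping[str, object], roles: Mapping[str, str],
                ci_level: float) -> GwasRecord:
    """Build one GwasRecord from a raw row; raises ValueError on bad cells."""

    def get(role):
        col = roles.get(role)
        if col is None:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    snp = str(get("snp") or "").strip()

    def fnum(role):
        v = get(role)
        if v is None:
            return None
        return float(v)  # raises ValueError on junk like "NA "

    beta = fnum("beta")
    if beta is None:
        oratio = fnum("odds_ratio")
        if oratio is None:
            raise ValueError("missing beta")
        beta = or_to_logor(oratio)

    pval = fnum("pval")
    if pval == 0.0:
        pval = TINY_PVAL

    se = fnum("se")
    if se is None:
        lo, hi = fnum("ci_lower"), fnum("ci_upper")
        if lo is not None and hi is not None:
            se = se_from_ci(lo, hi, ci_level)
        elif pval is not None and beta != 0:
            se = se_from_beta_p(beta, pval)
        else:
            raise ValueError("missing se and no ci/pval to derive it from")

    if pval is None:
        # two-sided Wald p from beta and se
        pval = float(2.0 * stats.norm.sf(abs(beta) / se))

    nval = fnum("n")
    ea = str(get("effect_allele") or "").strip().upper()
    oa_raw = get("other_allele")
    oa = str(oa_raw).strip().upper() if oa_raw is not None else None
    eaf = fnum("eaf")
    return GwasRecord(
        snp=snp, effect_allele=ea, other_allele=oa or None, eaf=eaf,
        beta=beta, se=se, pval=pval,
        n=int(round(nval)) if nval is not None else None,
    )


def read_summary_file(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    ci_level: float = 0.95,
    default_n: int | None = None,
) -> tuple[list[GwasRecord], list[dict]]:
    """Read a delimited GWAS summary file into GwasRecords.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file (optionally gzipped), header row
        required.
    column_map
        Mapping of role -> column name.  Roles: snp, effect_allele,
        other_allele, eaf, beta, se, pval, n, plus the derivation roles
        odds_ratio (used when beta is absent), ci_lower/ci_upper (se from a
        confidence interval).  When omitted, columns are matched to roles by
        name.  snp, effect_allele and beta (or odds_ratio) are mandatory.
    default_n
        Optional study-level sample size used to fill records whose per-SNP
        n is missing.

    Returns
    -------
    (records, rejections)
        Rejections are dicts with the 0-based data row index, the raw row
        and the reason; rows are never silently dropped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                         dtype=str, keep_default_na=True)
    except OSError as exc:  # pragma: no cover - passthrough
        raise IOError(f"cannot read summary file {path}: {exc}") from exc

    if column_map is None:
        # match columns to roles by (case-insensitive) name
        column_map = {c.lower(): c for c in df.columns
                      if c.lower() in _KNOWN_ROLES}
    roles = {role: col for role, col in column_map.items()}
    unknown = set(roles) - _KNOWN_ROLES
    if unknown:
        raise KeyError(f"unknown column roles: {sorted(unknown)}")
    missing_cols = [c for c in roles.values() if c not in df.columns]
    if missing_cols:
        raise KeyError(f"columns not found in {path.name}: {missing_cols}")
    have = set(roles)
    if "odds_ratio" in have:
        have.add("beta")
    lacking = _MANDATORY - have
    if lacking:
        raise KeyError(f"column_map must assign roles {sorted(lacking)}")

    records: list[GwasRecord] = []
    rejections: list[dict] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            rec = _coerce_row(row, roles, ci_level)
        except (ValueError, KeyError) as exc:
            rejections.append({"row": i, "reason": str(exc), "data": row})
            continue
        if rec.n is None and default_n is not None:
            rec = replace(rec, n=default_n)
        records.append(rec)
    return records, rejections


UNIFORM_COLUMNS = ["SNP", "effect_allele", "other_allele", "eaf",
                   "beta", "se", "pval", "n"]


def records_to_frame(records: Iterable[GwasRecord]) -> pd.DataFrame:
    """Uniform 8-column DataFrame view of a record list."""
    rows = [(r.snp, r.effect_allele, r.other_allele, r.eaf, r.beta, r.se,
             r.pval, r.n) for r in records]
    return pd.DataFrame(rows, columns=UNIFORM_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[GwasRecord]:
    out = []
    for row in df.itertuples(index=False):
        oa = getattr(row, "other_allele", None)
        if isinstance(oa, float) and math.isnan(oa):
            oa = None
        eaf = getattr(row, "eaf", None)
        if eaf is not None and isinstance(eaf, float) and math.isnan(eaf):
            eaf = None
        n = getattr(row, "n", None)
        if n is not None and (isinstance(n, float) and math.isnan(n)):
            n = None
        out.append(GwasRecord(
            snp=str(row.SNP), effect_allele=str(row.effect_allele),
            other_allele=None if oa is None else str(oa),
            eaf=None if eaf is None else float(eaf),
            beta=float(row.beta), se=float(row.se), pval=float(row.pval),
            n=None if n is None else int(n)))
    return out


def write_summary_file(records: Iterable[GwasRecord], path: str | Path) -> None:
    """Write records in the uniform tab-delimited 8-column format."""
    df = records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class QCReport:
    """Counts of rejected records grouped by reason."""

    counts: Counter = field(default_factory=Counter)
    rejected: list[tuple[GwasRecord, str]] = field(default_factory=list)

    def add(self, record: GwasRecord, reason: str) -> None:
        self.counts[reason] += 1
        self.rejected.append((record, reason))

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def qc_records(records: Iterable[GwasRecord]) -> tuple[list[GwasRecord], QCReport]:
    """Apply the standard quality-control rules to a record list.

    Removes records violating the type invariants (bad alleles, se <= 0,
    out-of-range eaf or p, missing rsID) and resolves duplicate rsIDs by
    keeping the record with the smallest p-value (ties: first occurrence).
    p-values of exactly 0 are coerced to the smallest positive double.
    Returns the clean list (input order preserved) and a rejection report.
    Idempotent: a clean list passes through unchanged.
    """
    report = QCReport()
    valid: list[GwasRecord] = []
    for rec in records:
        if rec.pval == 0.0:
            rec = replace(rec, pval=TINY_PVAL)
        problems = rec.validate()
        if problems:
            report.add(rec, problems[0])
            continue
        valid.append(rec)

    # duplicate resolution: smallest p wins, first occurrence breaks ties
    best: dict[str, int] = {}
    for idx, rec in enumerate(valid):
        cur = best.get(rec.snp)
        if cur is None or rec.pval < valid[cur].pval:
            if cur is not None:
                report.add(valid[cur], "duplicate")
            best[rec.snp] = idx
        else:
            report.add(rec, "duplicate")
    keep_idx = sorted(best.values())
    return [valid[i] for i in keep_idx], report
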
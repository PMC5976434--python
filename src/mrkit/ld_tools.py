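"""Instrument independence (LD clumping) and proxy-SNP substitution.

MR assumes each instrument is an independent natural experiment, so
correlated SNPs must be pruned to one index SNP per LD region before
estimation.  ``clump`` implements the standard greedy procedure: take the
smallest-p unclaimed SNP as index, discard every unclaimed SNP within the
window whose squared correlation with it exceeds the threshold, repeat.

When an instrument is absent from the outcome study, a correlated
surrogate ("proxy") can stand in for it, provided the proxy's effect is
re-expressed on the allele in phase with the target's effect allele.
``find_proxy`` and ``apply_proxy`` implement that lookup and phase-aware
relabelling.  LD matrices and proxy tables are user-supplied files (or
simulator output); no reference genotype panel ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .summary_data import GwasRecord

__all__ = ["LDMatrix", "ProxyRecord", "clump", "find_proxy", "apply_proxy"]

#: Minimum squared correlation for a proxy to be usable at all.
MIN_PROXY_R2 = 0.6


@dataclass
class LDMatrix:
    """Pairwise squared correlations with base-pair positions.

    ``r2`` is symmetric with unit diagonal, indexed by ``snps`` order;
    ``positions`` are 1-based base pairs on a single chromosome (clumping
    windows are measured index-SNP to candidate).
    """

    snps: list[str]
    positions: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snps)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 shape {self.r2.shape} does not match "
                             f"{k} SNPs")
        if self.positions.shape != (k,):
            raise ValueError("positions length does not match SNP list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0,1]")
        self._index = {s: i for i, s in enumerate(self.snps)}

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def loc(self, snp: str) -> int:
        return self._index[snp]

    @classmethod
    def from_square_file(cls, matrix_path: str | Path,
                         sidecar_path: str | Path) -> "LDMatrix":
        """Whitespace-delimited square matrix + two-column sidecar (snp, pos)."""
        r2 = np.loadtxt(matrix_path)
        side = pd.read_csv(sidecar_path, sep=r"\s+", header=None,
                           names=["snp", "pos"])
        return cls(side["snp"].astype(str).tolist(),
                   side["pos"].to_numpy(np.int64), np.atleast_2d(r2))

    @classmethod
    def from_triplets(cls, df: pd.DataFrame,
                      positions: Mapping[str, int]) -> "LDMatrix":
        """Long format (snpA, snpB, r2); missing pairs default to r2=0."""
        snps = sorted(positions)
        idx = {s: i for i, s in enumerate(snps)}
        r2 = np.eye(len(snps))
        for a, b, v in df[["snpA", "snpB", "r2"]].itertuples(index=False):
            i, j = idx[str(a)], idx[str(b)]
            r2[i, j] = r2[j, i] = float(v)
        return cls(snps, np.array([positions[s] for s in snps]), r2)


def clump(
    records: Sequence[GwasRecord],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    strict: bool = True,
) -> list[str]:
    """Greedy p-value clumping; returns retained rsIDs sorted by p ascending.

    Repeatedly takes the smallest-p unclaimed SNP as index (p ties broken
    by rsID) and removes unclaimed SNPs within ``window_kb`` of it with
    r2 > ``r2_threshold``.  With ``strict`` (default), a record absent
    from ``ld`` raises KeyError; otherwise such records pass through
    untouched.
    """
    missing = [r.snp for r in records if r.snp not in ld]
    if missing and strict:
        raise KeyError(f"SNPs missing from LD matrix: {missing}")
    passthrough = list(dict.fromkeys(missing))

    pool = sorted((r for r in records if r.snp in ld),
                  key=lambda r: (r.pval, r.snp))
    window_bp = window_kb * 1000.0
    claimed: set[str] = set()
    retained: list[str] = []
    for rec in pool:
        if rec.snp in claimed:
            continue
        retained.append(rec.snp)
        claimed.add(rec.snp)
        i = ld.loc(rec.snp)
        pos_i = ld.positions[i]
        for other in pool:
            if other.snp in claimed:
                continue
            j = ld.loc(other.snp)
            if (abs(ld.positions[j] - pos_i) <= window_bp
                    and ld.r2[i, j] > r2_threshold):
                claimed.add(other.snp)
    return retained + passthrough


@dataclass(frozen=True)
class ProxyRecord:
    """An LD surrogate for a target SNP, with allele phase.

    ``phase`` maps each target allele to the proxy allele carried on the
    same haplotype; the proxy allele in phase with the target's effect
    allele is the surrogate effect allele.
    """

    target: str
    proxy: str
    r2: float
    phase: Mapping[str, str]
    distance_bp: int = 0

    def __post_init__(self) -> None:
        if not MIN_PROXY_R2 <= self.r2 <= 1.0:
            raise ValueError(
                f"proxy r2 must be in [{MIN_PROXY_R2}, 1], got {self.r2}")
        if len(self.phase) != 2 or len(set(self.phase.values())) != 2:
            raise ValueError("phase must be a bijection on two alleles")


def read_proxy_table(path: str | Path) -> list[ProxyRecord]:
    """Tab-delimited proxy table: target, proxy, r2, distance_bp,
    target_A1, target_A2, proxy_A1_inphase, proxy_A2_inphase."""
    df = pd.read_csv(path, sep="\t")
    return [
        ProxyRecord(
            target=str(r.target), proxy=str(r.proxy), r2=float(r.r2),
            phase={str(r.target_A1): str(r.proxy_A1_inphase),
                   str(r.target_A2): str(r.proxy_A2_inphase)},
            distance_bp=int(r.distance_bp))
        for r in df.itertuples(index=False)
    ]


def find_proxy(
    target: str,
    outcome_snps: set[str] | frozenset[str],
    proxies: Iterable[ProxyRecord],
    min_r2: float = MIN_PROXY_R2,
) -> ProxyRecord | None:
    """Best available proxy for ``target`` among SNPs present in the outcome.

    Returns None when the target itself is present (no proxy needed) or
    no proxy reaches ``min_r2``.  Eligible proxies are ranked by r2
    descending, then distance ascending, then rsID.
    """
    if target in outcome_snps:
        return None
    candidates = [p for p in proxies
                  if p.target == target and p.proxy in outcome_snps
                  and p.r2 >= min_r2]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (-p.r2, p.distance_bp, p.proxy))


def apply_proxy(set_row: GwasRecord, proxy: ProxyRecord) -> GwasRecord:
    """Re-key an outcome record observed at the proxy SNP to the target.

    The phase map (first entry: target effect allele -> in-phase proxy
    allele) determines which target allele the record's effect allele
    tags.  The returned record carries the target rsID and the target's
    own alleles, oriented onto the target's effect allele: when the
    record's effect allele is in phase with the target's *other* allele
    the effect sign flips and the eaf is complemented.
    """
    if set_row.snp != proxy.proxy:
        raise ValueError(
            f"record is for {set_row.snp}, proxy table row is for {proxy.proxy}")
    inverse = {v: k for k, v in proxy.phase.items()}
    target_ea, target_oa = list(proxy.phase.keys())
    try:
        mapped_ea = inverse[set_row.effect_allele]
    except KeyError as exc:
        raise ValueError(
            f"proxy effect allele {set_row.effect_allele} absent from phase "
            f"map {dict(proxy.phase)}") from exc
    if mapped_ea == target_ea:
        return replace(set_row, snp=proxy.target,
                       effect_allele=target_ea, other_allele=target_oa)
    return replace(set_row, snp=proxy.target,
                   effect_allele=target_ea, other_allele=target_oa,
                   beta=-set_row.beta,
                   eaf=None if set_row.eaf is None else 1.0 - set_row.eaf)
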
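"""Pairwise linkage disequilibrium (r² and D') between variant sites.

Individuals in a haplotype result are effectively phased — after the
default removal of heterozygotes every accession is homozygous at every
site — so each individual contributes a single gamete.  Per site, alleles
are collapsed to biallelic major-vs-rest; for a site pair with major-allele
frequencies pA, pB and joint major-major frequency pAB:

    D   = pAB − pA·pB
    r²  = D² / (pA(1−pA) pB(1−pB))
    D'  = |D| / Dmax,   Dmax = min(pA(1−pB), (1−pA)pB)        if D > 0
                        Dmax = min(pA·pB, (1−pA)(1−pB))        if D < 0

Monomorphic sites (after pairwise-complete filtering) yield NaN entries.
Individuals with residual heterozygous or missing calls at either site of a
pair are dropped pairwise, not listwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HapResult, is_hetero, is_missing


@dataclass
class LDMatrix:
    """Symmetric r²/D' matrices with post-transform site labels."""

    labels: list[str]
    r2: pd.DataFrame
    dprime: pd.DataFrame

    def matrix(self, measure: str) -> pd.DataFrame:
        if measure == "r2":
            return self.r2
        if measure == "dprime":
            return self.dprime
        raise ValueError(f"unknown LD measure {measure!r}")

    def to_tsv(self, path, measure: str = "r2") -> None:
        self.matrix(measure).to_csv(path, sep="\t", float_format="%.6g")


def ld_pair(pA: float, pB: float, pAB: float) -> tuple[float, float, float]:
    """(D, r², D') from the major-allele marginals and joint frequency."""
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom == 0:
        return D, float("nan"), float("nan")
    r2 = D * D / denom
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return D, r2, 0.0
    return D, r2, abs(D) / dmax


def compute_ld(h: HapResult) -> LDMatrix:
    """Pairwise r² and D' over all site pairs of a haplotype result."""
    if h.n_sites < 2:
        raise ValueError("need at least two sites for LD")
    if h.n_ind < 2:
        raise ValueError("need at least two individuals for LD")
    labels = [f"{s.chrom}:{s.pos}" for s in h.sites]
    n_sites = h.n_sites
    # columns of usable (non-missing, homozygous) calls per site
    cols: list[list[str | None]] = []
    for j in range(n_sites):
        col = []
        for vec in h.genotypes:
            c = vec[j]
            col.append(None if is_missing(c) or is_hetero(c) else c)
        cols.append(col)
    majors = []
    for col in cols:
        called = [c for c in col if c is not None]
        if not called:
            majors.append(None)
            continue
        counts: dict[str, int] = {}
        for c in called:
            counts[c] = counts.get(c, 0) + 1
        majors.append(min(counts, key=lambda a: (-counts[a], a)))

    r2 = np.full((n_sites, n_sites), np.nan)
    dp = np.full((n_sites, n_sites), np.nan)
    np.fill_diagonal(r2, 1.0)
    np.fill_diagonal(dp, 1.0)
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            if majors[i] is None or majors[j] is None:
                continue
            pairs = [(a, b) for a, b in zip(cols[i], cols[j])
                     if a is not None and b is not None]
            n = len(pairs)
            if n == 0:
                continue
            pA = sum(a == majors[i] for a, _ in pairs) / n
            pB = sum(b == majors[j] for _, b in pairs) / n
            pAB = sum(a == majors[i] and b == majors[j] for a, b in pairs) / n
            _, r2[i, j], dp[i, j] = ld_pair(pA, pB, pAB)
            r2[j, i], dp[j, i] = r2[i, j], dp[i, j]
    return LDMatrix(labels=labels,
                    r2=pd.DataFrame(r2, index=labels, columns=labels),
                    dprime=pd.DataFrame(dp, index=labels, columns=labels))


__all__ = ["LDMatrix", "ld_pair", "compute_ld"]
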
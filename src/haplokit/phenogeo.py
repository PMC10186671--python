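"""Haplotype–phenotype comparison and geographic distribution summaries.

Phenotype comparison follows the conservative defaults of candidate-gene
haplotype studies: per haplotype group, trait values outside
``[Q1 − k·IQR, Q3 + k·IQR]`` (k = 3, quartiles by linear interpolation,
bounds inclusive) are removed first; groups that then hold fewer than
``min_members`` (default 5) individuals are excluded; every remaining pair
of haplotypes is compared with a two-sided two-sample test (Welch t by
default, Wilcoxon rank-sum optional) and annotated with significance stars
(* p<0.05, ** p<0.01, *** p<0.001).  Raw p-values are reported, with a
Benjamini–Hochberg-adjusted column alongside for transparency.

The geographic summary counts, per (longitude, latitude) location, the
accessions carrying each of the top-N most frequent haplotypes (N
defaulting to 4 — more tends to make the pies unreadable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model import AccessionTable, HapResult


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def remove_outliers(values, k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Split *values* into (kept, removed) by the k×IQR rule.

    Quartiles use linear interpolation between order statistics; the bounds
    ``Q1 − k·IQR`` and ``Q3 + k·IQR`` are inclusive, so an IQR of zero
    keeps all values equal to the quartiles.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no numeric values to screen for outliers")
    q1, q3 = np.percentile(arr, [25, 75])
    lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
    mask = (arr >= lo) & (arr <= hi)
    return arr[mask], arr[~mask]


@dataclass
class PhenoComparison:
    """Pairwise haplotype-vs-phenotype test results for one trait."""

    trait: str
    groups: dict[str, np.ndarray]          # haplotype -> retained values
    pairs: pd.DataFrame                    # hapA, hapB, statistic, p, p_bh, stars
    removed: dict[str, np.ndarray] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)  # groups under min_members

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        col = "p_bh" if adjusted else "p"
        return self.pairs[self.pairs[col] < alpha]


def compare_pheno(h: HapResult, acc: AccessionTable, trait: str,
                  min_members: int = 5, k: float = 3.0,
                  test: str = "t") -> PhenoComparison:
    """Compare a numeric trait between every pair of haplotypes.

    Outliers are removed per group before the group-size rule is applied
    (membership is counted after removal).  Fewer than two eligible groups
    yields an empty comparison set rather than an error.
    """
    if trait not in acc.table.columns:
        raise KeyError(f"trait {trait!r} not in accession table")
    if test not in ("t", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    values = pd.to_numeric(acc.table[trait], errors="coerce")

    kept: dict[str, np.ndarray] = {}
    removed: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, members in h.members().items():
        vals = values.reindex(members).dropna().to_numpy()
        if vals.size == 0:
            excluded.append(name)
            continue
        inlier, outlier = remove_outliers(vals, k=k)
        if outlier.size:
            removed[name] = outlier
        if inlier.size >= min_members:
            kept[name] = inlier
        else:
            excluded.append(name)

    rows = []
    for a, b in combinations(sorted(kept), 2):
        if test == "t":
            res = stats.ttest_ind(kept[a], kept[b], equal_var=False)
        else:
            res = stats.mannwhitneyu(kept[a], kept[b], alternative="two-sided")
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    pairs = pd.DataFrame(rows, columns=["hapA", "hapB", "statistic", "p"])
    if len(pairs):
        from statsmodels.stats.multitest import multipletests

        pairs["p_bh"] = multipletests(pairs["p"], method="fdr_bh")[1]
    else:
        pairs["p_bh"] = pd.Series(dtype=float)
    pairs["stars"] = pairs["p"].map(significance_stars)
    return PhenoComparison(trait=trait, groups=kept, pairs=pairs,
                           removed=removed, excluded=excluded)


@dataclass
class GeoDistribution:
    """Per-location accession counts for the top-N haplotypes."""

    hap_names: list[str]                           # the top-N, by frequency
    locations: pd.DataFrame                        # lon, lat, <hap cols>, total
    skipped: list[str] = field(default_factory=list)  # accessions w/o coords

    @property
    def n_locations(self) -> int:
        return len(self.locations)


def geo_distribution(h: HapResult, acc: AccessionTable, top_n: int = 4,
                     round_digits: int | None = None) -> GeoDistribution:
    """Summarize where the major haplotypes occur.

    Accessions of the ``top_n`` most frequent haplotypes are grouped by
    their (longitude, latitude), optionally rounded to ``round_digits``
    decimal degrees to bin nearby collection points; accessions lacking
    coordinates are logged and skipped.
    """
    lon_col, lat_col = acc.coordinate_columns()
    if lon_col is None or lat_col is None:
        raise ValueError("accession table has no longitude/latitude columns")
    members = h.members()
    top = sorted(members, key=lambda n: (-len(members[n]), n))[:top_n]

    counts: dict[tuple[float, float], dict[str, int]] = {}
    skipped: list[str] = []
    for name in top:
        for a in members[name]:
            if a not in acc.table.index:
                skipped.append(a)
                continue
            lon = pd.to_numeric(pd.Series([acc.table.at[a, lon_col]]),
                                errors="coerce").iloc[0]
            lat = pd.to_numeric(pd.Series([acc.table.at[a, lat_col]]),
                                errors="coerce").iloc[0]
            if pd.isna(lon) or pd.isna(lat):
                skipped.append(a)
                continue
            if round_digits is not None:
                lon, lat = round(float(lon), round_digits), round(float(lat), round_digits)
            key = (float(lon), float(lat))
            counts.setdefault(key, {})[name] = counts.get(key, {}).get(name, 0) + 1

    rows = []
    for (lon, lat), d in sorted(counts.items()):
        row = {"lon": lon, "lat": lat}
        row.update({n: d.get(n, 0) for n in top})
        row["total"] = sum(d.values())
        rows.append(row)
    if not rows:
        raise ValueError("no accession of the selected haplotypes has coordinates")
    return GeoDistribution(hap_names=top,
                           locations=pd.DataFrame(rows), skipped=skipped)


__all__ = ["remove_outliers", "compare_pheno", "geo_distribution",
           "PhenoComparison", "GeoDistribution", "significance_stars"]
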
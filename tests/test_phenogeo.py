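"""Outlier rule, pairwise phenotype tests and geographic summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haplokit import (
    AccessionTable, HapResult, VariantSite, compare_pheno, geo_distribution,
    remove_outliers,
)
from haplokit.phenogeo import significance_stars


def hap_with_groups(sizes: dict[str, int]) -> HapResult:
    """HapResult with the requested group sizes; accession IDs are
    '<hap>_<k>'."""
    sites = [VariantSite("c", 10, "A", "G"), VariantSite("c", 20, "C", "T")]
    vec_pool = [("A", "C"), ("G", "C"), ("A", "T"), ("G", "T")]
    names, genos, accs = [], [], []
    for i, (name, size) in enumerate(sizes.items()):
        for k in range(size):
            names.append(name)
            genos.append(vec_pool[i % len(vec_pool)])
            accs.append(f"{name}_{k}")
    return HapResult(sites, names, genos, accs)


def acc_table(values: dict[str, float], extra_cols=None) -> AccessionTable:
    df = pd.DataFrame({"Trait": pd.Series(values)})
    if extra_cols:
        for c, v in extra_cols.items():
            df[c] = pd.Series(v)
    df.index.name = "ID"
    return AccessionTable(df)


class TestRemoveOutliers:
    def test_constant_vector_keeps_everything(self):
        kept, removed = remove_outliers([5.0] * 8)
        assert len(kept) == 8 and len(removed) == 0

    def test_huge_k_keeps_everything(self):
        kept, removed = remove_outliers([1, 2, 3, 4, 1000], k=1e9)
        assert len(removed) == 0

    def test_matches_direct_bound_computation(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            vals = rng.normal(size=rng.integers(4, 60)) * 10
            # sprinkle gross outliers
            vals[: rng.integers(0, 3)] += 1e4
            kept, removed = remove_outliers(vals, k=3)
            q1, q3 = np.percentile(vals, [25, 75])
            lo, hi = q1 - 3 * (q3 - q1), q3 + 3 * (q3 - q1)
            expect_removed = sorted(v for v in vals if v < lo or v > hi)
            assert sorted(removed) == pytest.approx(expect_removed)
            assert len(kept) + len(removed) == len(vals)

    def test_known_case(self):
        vals = [1, 2, 3, 4, 1000]
        kept, removed = remove_outliers(vals, k=3)
        assert list(removed) == [1000] and sorted(kept) == [1, 2, 3, 4]

    def test_idempotent_at_default_k(self):
        # with the default 3xIQR bounds a second pass removes nothing on
        # random (contaminated) Gaussian samples
        rng = np.random.default_rng(77)
        for _ in range(100):
            vals = rng.normal(size=rng.integers(5, 80))
            kept1, _ = remove_outliers(vals, k=3)
            kept2, removed2 = remove_outliers(kept1, k=3)
            assert removed2.size == 0
            assert np.array_equal(np.sort(kept1), np.sort(kept2))

    def test_empty_error(self):
        with pytest.raises(ValueError):
            remove_outliers([])


class TestComparePheno:
    def test_separated_groups_highly_significant(self):
        h = hap_with_groups({"H001": 10, "H002": 10})
        vals = {f"H001_{k}": 1.0 + k for k in range(10)}
        vals.update({f"H002_{k}": 101.0 + k for k in range(10)})
        for test in ("t", "wilcoxon"):
            pc = compare_pheno(h, acc_table(vals), "Trait", test=test)
            assert len(pc.pairs) == 1
            assert pc.pairs.iloc[0]["p"] < 0.001
            assert pc.pairs.iloc[0]["stars"] == "***"

    def test_small_group_excluded(self):
        h = hap_with_groups({"H001": 10, "H002": 10, "H003": 4})
        rng = np.random.default_rng(0)
        vals = {a: float(v) for a, v in
                zip(h.accessions, rng.normal(size=len(h.accessions)))}
        pc = compare_pheno(h, acc_table(vals), "Trait", min_members=5)
        assert "H003" in pc.excluded
        assert set(pc.pairs["hapA"]) | set(pc.pairs["hapB"]) == {"H001", "H002"}

    def test_min_members_counted_after_outlier_removal(self):
        h = hap_with_groups({"H001": 5, "H002": 10})
        vals = {f"H001_{k}": float(k) for k in range(4)}
        vals["H001_4"] = 1e6  # outlier drops H001 to 4 members
        vals.update({f"H002_{k}": float(k) for k in range(10)})
        pc = compare_pheno(h, acc_table(vals), "Trait", min_members=5)
        assert "H001" in pc.excluded and len(pc.pairs) == 0

    def test_null_rejection_rate_close_to_alpha(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 100
        h = hap_with_groups({"H001": 30, "H002": 30})
        for _ in range(n_rep):
            vals = {a: float(v) for a, v in
                    zip(h.accessions, rng.normal(size=60))}
            pc = compare_pheno(h, acc_table(vals), "Trait")
            if pc.pairs.iloc[0]["p"] < 0.05:
                rejections += 1
        assert rejections <= 10  # >=90% of null replicates carry no star

    def test_bh_column_present_and_monotone(self):
        h = hap_with_groups({"H001": 8, "H002": 8, "H003": 8})
        rng = np.random.default_rng(3)
        vals = {a: float(v) + (10.0 if a.startswith("H003") else 0.0)
                for a, v in zip(h.accessions, rng.normal(size=24))}
        pc = compare_pheno(h, acc_table(vals), "Trait")
        assert (pc.pairs["p_bh"] >= pc.pairs["p"] - 1e-15).all()

    def test_missing_trait_errors(self):
        h = hap_with_groups({"H001": 5, "H002": 5})
        with pytest.raises(KeyError):
            compare_pheno(h, acc_table({a: 1.0 for a in h.accessions}), "nope")


class TestStars:
    @pytest.mark.parametrize("p,expect", [
        (0.2, ""), (0.04, "*"), (0.009, "**"), (0.0009, "***")])
    def test_mapping(self, p, expect):
        assert significance_stars(p) == expect


class TestGeoDistribution:
    def test_shared_location_totals(self, table1_accessions):
        # three of the example accessions share lon 121 / lat 14.6
        h = hap_with_groups({"H001": 3, "H002": 3})
        h.accessions[:] = [f"C00{i}" for i in range(1, 7)]
        gd = geo_distribution(h, table1_accessions, top_n=4)
        row = gd.locations.set_index(["lon", "lat"]).loc[(121.0, 14.6)]
        assert row["total"] == 3

    def test_top_n_one_keeps_only_modal_hap(self, table1_accessions):
        h = hap_with_groups({"H001": 4, "H002": 2})
        h.accessions[:] = [f"C00{i}" for i in range(1, 7)]
        gd = geo_distribution(h, table1_accessions, top_n=1)
        assert gd.hap_names == ["H001"]
        assert (gd.locations["H001"] == gd.locations["total"]).all()

    def test_counts_conserve_accessions(self, table1_accessions):
        h = hap_with_groups({"H001": 2, "H002": 2, "H003": 2})
        h.accessions[:] = [f"C00{i}" for i in range(1, 7)]
        gd = geo_distribution(h, table1_accessions, top_n=2)
        in_top = sum(len(m) for n, m in h.members().items()
                     if n in gd.hap_names)
        assert gd.locations["total"].sum() == in_top - len(gd.skipped)
        hap_cols = gd.locations[gd.hap_names].sum(axis=1)
        assert (hap_cols == gd.locations["total"]).all()

    def test_missing_coordinates_logged(self):
        h = hap_with_groups({"H001": 2})
        df = pd.DataFrame({"Longitude": [10.0, np.nan],
                           "Latitude": [20.0, np.nan]},
                          index=["H001_0", "H001_1"])
        gd = geo_distribution(h, AccessionTable(df), top_n=1)
        assert gd.skipped == ["H001_1"]
        assert gd.locations["total"].sum() == 1

    def test_no_coordinates_errors(self):
        h = hap_with_groups({"H001": 2})
        df = pd.DataFrame({"x": [1.0, 2.0]}, index=["H001_0", "H001_1"])
        with pytest.raises(ValueError, match="longitude/latitude"):
            geo_distribution(h, AccessionTable(df))
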
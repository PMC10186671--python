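"""Haplotype grouping/naming rules and the ATG-as-zero coordinate
transform."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from haplokit import (
    Annotation, AtgAnchor, Feature, VariantSet, VariantSite,
    call_haplotypes, find_atg, invert_atg_zero, set_atg_zero,
    summarize_haplotypes,
)
from haplokit.haplotype import hap_name


def random_variantset(rng: random.Random, n_acc: int, n_sites: int,
                      het_missing: bool = False) -> VariantSet:
    sites = [VariantSite("chrX", 10 * (j + 1), "A", "G")
             for j in range(n_sites)]
    pool = ["A", "G"] + (["A/G", "."] if het_missing else [])
    calls = [[rng.choice(pool) for _ in range(n_sites)] for _ in range(n_acc)]
    names = [f"acc{i}" for i in range(n_acc)]
    return VariantSet(sites, names, calls)


def brute_force_partition(vs: VariantSet) -> list[set[str]]:
    """O(n²) all-pairs equality partition (independent of the grouping
    code path)."""
    accs = vs.accessions
    groups: list[set[str]] = []
    for a in accs:
        va = vs.calls_for(a)
        for g in groups:
            if vs.calls_for(next(iter(g))) == va:
                g.add(a)
                break
        else:
            groups.append({a})
    return groups


class TestCallHaplotypes:
    def test_naming_by_descending_size(self, tiny_vs):
        h = call_haplotypes(tiny_vs)
        members = h.members()
        assert members["H001"] == ["s1", "s2"]
        assert set(members) == {"H001", "H002", "H003"}

    def test_na_and_hetero_removal(self, tiny_vs):
        h = call_haplotypes(tiny_vs, na_drop=True, hetero_remove=True)
        assert "s5" not in h.accessions and "s6" not in h.accessions

    def test_flags_false_keep_everyone(self, tiny_vs):
        h = call_haplotypes(tiny_vs, na_drop=False, hetero_remove=False)
        assert h.n_ind == tiny_vs.n_accessions
        assert "A/G" in {g for vec in h.genotypes for g in vec}

    def test_grouping_matches_bruteforce_on_random_fixtures(self):
        rng = random.Random(123)
        for _ in range(30):
            vs = random_variantset(rng, rng.randint(2, 30), rng.randint(1, 6))
            h = call_haplotypes(vs, na_drop=False, hetero_remove=False)
            got = sorted(sorted(m) for m in h.members().values())
            want = sorted(sorted(g) for g in brute_force_partition(vs))
            assert got == want

    def test_partition_property(self, tiny_hap):
        # every accession in exactly one haplotype; vectors pairwise distinct
        assert len(tiny_hap.accessions) == len(set(tiny_hap.accessions))
        vecs = {n: v for n, v in zip(tiny_hap.hap_names, tiny_hap.genotypes)}
        assert len(set(vecs.values())) == len(vecs)

    def test_naming_stable_under_accession_permutation(self):
        rng = random.Random(7)
        vs = random_variantset(rng, 20, 4)
        h1 = call_haplotypes(vs, na_drop=False, hetero_remove=False)
        order = list(range(20))
        rng.shuffle(order)
        vs2 = VariantSet(vs.sites, [vs.accessions[i] for i in order],
                         [list(vs.calls_for(vs.accessions[i])) for i in order])
        h2 = call_haplotypes(vs2, na_drop=False, hetero_remove=False)
        # up to frequency ties: the vector -> size mapping must agree
        size1 = {v: h1.hap_names.count(n)
                 for n, v in zip(h1.hap_names, h1.genotypes)}
        size2 = {v: h2.hap_names.count(n)
                 for n, v in zip(h2.hap_names, h2.genotypes)}
        assert size1 == size2

    def test_all_filtered_is_error(self):
        vs = VariantSet([VariantSite("c", 1, "A", "G")], ["x"], [["."]])
        with pytest.raises(ValueError, match="survive"):
            call_haplotypes(vs, na_drop=True)

    def test_name_width_grows(self):
        assert hap_name(1, 999) == "H001"
        assert hap_name(1000, 1000) == "H1000"


class TestSummarize:
    def test_freqs_sorted_and_conserved(self, tiny_hap, tiny_summary):
        assert tiny_summary.freqs == sorted(tiny_summary.freqs, reverse=True)
        assert tiny_summary.n_ind == tiny_hap.n_ind
        assert tiny_summary.freqs[0] == 2

    def test_singleton(self):
        vs = VariantSet([VariantSite("c", 1, "A", "G")], ["x"], [["A"]])
        hs = summarize_haplotypes(call_haplotypes(vs))
        assert hs.hap_names == ["H001"] and hs.freqs == [1]


class TestAtg:
    @pytest.fixture
    def plus_ann(self):
        return Annotation([
            Feature("chr7", 1000, 1200, "+", "g1", "CDS", "g1.1"),
            Feature("chr7", 1400, 1600, "+", "g1", "CDS", "g1.1"),
        ])

    @pytest.fixture
    def minus_ann(self):
        return Annotation([
            Feature("chr7", 1000, 1100, "-", "g2", "CDS", "g2.1"),
            Feature("chr7", 1300, 1500, "-", "g2", "CDS", "g2.1"),
        ])

    def test_plus_anchor_is_smallest_cds_start(self, plus_ann):
        assert find_atg(plus_ann, "g1.1") == AtgAnchor("chr7", 1000, "+")

    def test_minus_anchor_is_largest_cds_end(self, minus_ann):
        assert find_atg(minus_ann, "g2.1") == AtgAnchor("chr7", 1500, "-")

    def test_mixed_strand_error(self):
        ann = Annotation([Feature("c", 1, 5, "+", "g", "CDS", "g.1"),
                          Feature("c", 9, 12, "-", "g", "CDS", "g.1")])
        with pytest.raises(ValueError, match="mixed"):
            find_atg(ann, "g.1")

    def test_absent_id_and_no_cds(self, plus_ann):
        with pytest.raises(ValueError, match="no features"):
            find_atg(plus_ann, "nope")
        ann = Annotation([Feature("c", 1, 5, "+", "g", "exon", "g.1")])
        with pytest.raises(ValueError, match="no CDS"):
            find_atg(ann, "g.1")


class TestSetAtgZero:
    def test_plus_strand_arithmetic(self, tiny_hap):
        out = set_atg_zero(tiny_hap, AtgAnchor("chr7", 1000, "+"))
        # original positions 100, 250, 400
        assert [s.pos for s in out.sites] == [-900, -750, -600]

    def test_minus_strand_reverses_and_stays_ascending(self, tiny_hap):
        out = set_atg_zero(tiny_hap, AtgAnchor("chr7", 2000, "-"))
        assert [s.pos for s in out.sites] == [1600, 1750, 1900]
        # genotype vectors reversed to track the site order
        assert out.genotypes[0] == tiny_hap.genotypes[0][::-1]

    def test_alleles_unchanged(self, tiny_hap):
        out = set_atg_zero(tiny_hap, AtgAnchor("chr7", 2000, "-"))
        assert {s.ref for s in out.sites} == {s.ref for s in tiny_hap.sites}

    @pytest.mark.parametrize("strand,pos", [("+", 1000), ("-", 2000)])
    def test_invertible(self, tiny_hap, tiny_summary, strand, pos):
        anchor = AtgAnchor("chr7", pos, strand)
        for obj in (tiny_hap, tiny_summary):
            assert invert_atg_zero(set_atg_zero(obj, anchor), anchor) == obj

    def test_annotation_transform_invertible(self, tiny_hap):
        ann = Annotation([Feature("chr7", 1000, 1200, "-", "g", "CDS", "g.1")])
        anchor = AtgAnchor("chr7", 1500, "-")
        out = set_atg_zero(ann, anchor)
        assert (out.features[0].start, out.features[0].end) == (300, 500)
        assert invert_atg_zero(out, anchor) == ann


@given(st.integers(-5000, 5000), st.sampled_from(["+", "-"]))
@settings(max_examples=50, deadline=None)
def test_atg_transform_roundtrip_property(anchor_pos, strand):
    sites = [VariantSite("chr7", p, "A", "G") for p in (100, 250, 400)]
    vs = VariantSet(sites, ["a"], [["A", "G", "A"]])
    h = call_haplotypes(vs, na_drop=False, hetero_remove=False)
    anchor = AtgAnchor("chr7", anchor_pos, strand)
    assert invert_atg_zero(set_atg_zero(h, anchor), anchor) == h
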
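import pytest

from haplokit import (
    AccessionTable, HapResult, VariantSet, VariantSite,
    call_haplotypes, generate_dataset, summarize_haplotypes,
)

import pandas as pd


@pytest.fixture
def tiny_sites():
    return [
        VariantSite("chr7", 100, "A", "G"),
        VariantSite("chr7", 250, "C", "T"),
        VariantSite("chr7", 400, "T", "A,DEL", info="indel"),
    ]


@pytest.fixture
def tiny_vs(tiny_sites):
    """Six accessions over three sites: 3 clean haplotypes, one het, one
    missing carrier."""
    calls = [
        ["A", "C", "T"],       # s1 -> hap X
        ["A", "C", "T"],       # s2 -> hap X
        ["G", "T", "T"],       # s3 -> hap Y
        ["G", "T", "DEL"],     # s4 -> hap Z
        ["A/G", "C", "T"],     # s5 heterozygous at site 1
        ["A", ".", "T"],       # s6 missing at site 2
    ]
    return VariantSet(tiny_sites, [f"s{i}" for i in range(1, 7)], calls)


@pytest.fixture
def tiny_hap(tiny_vs) -> HapResult:
    return call_haplotypes(tiny_vs, na_drop=True, hetero_remove=True)


@pytest.fixture
def tiny_summary(tiny_hap):
    return summarize_haplotypes(tiny_hap)


@pytest.fixture
def table1_accessions() -> AccessionTable:
    """The six-accession example metadata table (groups, coordinates,
    two grain traits)."""
    df = pd.DataFrame(
        {
            "Subpopulation": ["Indica", "Intermediate", "Japonica",
                              "Japonica", "Japonica", "Indica"],
            "Longitude": [121, 121, 51.3, 116.28, 121, 116.28],
            "Latitude": [14.6, 14.6, 35.45, 39.54, 14.6, 39.54],
            "GrainLength": [8.50, 10.20, 8.75, 7.83, 10.47, 8.10],
            "GrainWidth": [2.90, 2.63, 3.32, 3.22, 3.00, 2.47],
        },
        index=pd.Index([f"C00{i}" for i in range(1, 7)], name="ID"),
    )
    return AccessionTable(df)


@pytest.fixture
def sim_dataset(tmp_path):
    return generate_dataset(tmp_path / "sim", n_accessions=60, n_sites=6,
                            n_haplotypes=4, hetero_rate=0.03,
                            missing_rate=0.03, effect_size=1.5, seed=11)


@pytest.fixture
def clean_dataset(tmp_path):
    """Noise-free dataset: haplotype calling must recover the truth."""
    return generate_dataset(tmp_path / "clean", n_accessions=50, n_sites=6,
                            n_haplotypes=4, hetero_rate=0.0,
                            missing_rate=0.0, effect_size=2.0, seed=7)
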
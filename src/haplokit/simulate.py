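"""Self-contained synthetic candidate-gene datasets with known truth.

The generator plants ``n_haplotypes`` distinct allele vectors over
``n_sites`` biallelic SNP sites inside a small gene model, assigns each of
``n_accessions`` accessions to a haplotype multinomially (with mildly
skewed frequencies, as real germplasm panels show), then corrupts calls
into heterozygotes / no-calls at the requested rates.  A numeric trait is
drawn per accession as ``effect_size × haplotype_index + N(0, 1)``, so
``effect_size = 0`` gives an exact null for calibration studies and larger
values give a planted superior haplotype.  Coordinates scatter accessions
over a handful of fixed collection sites.  Everything is reproducible from
the seed, and the returned truth record stores the intended partition.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import write_vcf
from .model import MISSING, VariantSet, VariantSite, hetero_call

_BASES = ("A", "C", "G", "T")

#: A handful of plausible collection sites (lon, lat) for the geo summary.
_SITES_GEO = [
    (121.0, 14.6), (116.28, 39.54), (51.3, 35.45), (78.0, 20.0), (104.0, 1.3),
]


@dataclass
class Truth:
    """Ground truth of a simulated dataset."""

    hap_vectors: list[list[str]]           # planted allele vector per haplotype
    assignment: dict[str, int]             # accession -> haplotype index
    frequencies: list[int]                 # realized accessions per haplotype
    effect_size: float
    clean_accessions: list[str] = field(default_factory=list)  # no injected noise

    def partition(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for acc, h in self.assignment.items():
            out.setdefault(h, []).append(acc)
        return out


@dataclass
class SyntheticDataset:
    vcf: Path
    gff: Path
    accession_table: Path
    truth: Truth
    variants: VariantSet


def generate_dataset(out_dir: str | Path, n_accessions: int = 100,
                     n_sites: int = 8, n_haplotypes: int = 5,
                     hetero_rate: float = 0.02, missing_rate: float = 0.02,
                     effect_size: float = 1.0,
                     groups: Sequence[str] = ("Indica", "Japonica", "Intermediate"),
                     seed: int = 0, chrom: str = "chr7",
                     gene_start: int = 1000) -> SyntheticDataset:
    """Write a VCF + GFF3 + accession table trio with known haplotype truth.

    Raises if ``n_haplotypes`` exceeds the number of distinct binary
    vectors over ``n_sites`` or if a rate falls outside [0, 1].
    """
    if n_haplotypes > 2 ** n_sites:
        raise ValueError(f"cannot plant {n_haplotypes} distinct haplotypes "
                         f"over {n_sites} biallelic sites")
    for name, r in (("hetero_rate", hetero_rate), ("missing_rate", missing_rate)):
        if not 0 <= r <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- sites: biallelic SNPs spread over a ~2 kb gene body -------------
    positions = np.sort(rng.choice(np.arange(gene_start, gene_start + 2000),
                                   size=n_sites, replace=False))
    sites = []
    for pos in positions:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        sites.append(VariantSite(chrom=chrom, pos=int(pos), ref=str(ref),
                                 alt=str(alt), info="."))

    # --- planted haplotype vectors (distinct binary patterns) ------------
    patterns: set[tuple[int, ...]] = set()
    patterns.add(tuple([0] * n_sites))  # reference haplotype first
    while len(patterns) < n_haplotypes:
        patterns.add(tuple(rng.integers(0, 2, size=n_sites)))
    pattern_list = sorted(patterns)
    rng.shuffle(pattern_list)
    hap_vectors = [[s.alt if p else s.ref for s, p in zip(sites, pat)]
                   for pat in pattern_list]

    # --- multinomial assignment with skewed frequencies ------------------
    raw = 1.0 / (1.0 + np.arange(n_haplotypes))
    probs = raw / raw.sum()
    hap_idx = rng.choice(n_haplotypes, size=n_accessions, p=probs)
    accessions = [f"ACC{i + 1:04d}" for i in range(n_accessions)]

    # --- genotype matrix with injected noise ------------------------------
    calls: list[list[str]] = []
    clean: list[str] = []
    for i, acc in enumerate(accessions):
        vec = list(hap_vectors[hap_idx[i]])
        noisy = False
        for j, s in enumerate(sites):
            u = rng.random()
            if u < missing_rate:
                vec[j] = MISSING
                noisy = True
            elif u < missing_rate + hetero_rate:
                vec[j] = hetero_call(s.ref, s.alt)
                noisy = True
        if not noisy:
            clean.append(acc)
        calls.append(vec)
    vs = VariantSet(sites, accessions, calls)
    vcf_path = write_vcf(vs, out_dir / "variants.vcf")

    # --- annotation: gene / mRNA / two exons+CDS on the + strand ----------
    gff_path = out_dir / "annotation.gff3"
    gene_end = gene_start + 2100
    mid = gene_start + 900
    g = "GENE0001"
    t = f"{g}.1"
    rows = [
        (chrom, "sim", "gene", gene_start, gene_end, ".", "+", ".", f"ID={g};Name={g}"),
        (chrom, "sim", "mRNA", gene_start, gene_end, ".", "+", ".", f"ID={t};Parent={g}"),
        (chrom, "sim", "exon", gene_start, mid, ".", "+", ".", f"ID={t}.e1;Parent={t}"),
        (chrom, "sim", "CDS", gene_start, mid, ".", "+", "0", f"ID={t}.c1;Parent={t}"),
        (chrom, "sim", "exon", mid + 200, gene_end, ".", "+", ".", f"ID={t}.e2;Parent={t}"),
        (chrom, "sim", "CDS", mid + 200, gene_end, ".", "+", "0", f"ID={t}.c2;Parent={t}"),
    ]
    gff_path.write_text("##gff-version 3\n" + "\n".join(
        "\t".join(str(x) for x in r) for r in rows) + "\n")

    # --- accession table: group, coordinates, one trait -------------------
    geo_idx = rng.integers(0, len(_SITES_GEO), size=n_accessions)
    group_idx = rng.integers(0, len(groups), size=n_accessions)
    trait = effect_size * hap_idx + rng.standard_normal(n_accessions)
    table_path = out_dir / "accessions.tsv"
    header = "ID\tSubpopulation\tLongitude\tLatitude\tTrait"
    lines = [header]
    for i, acc in enumerate(accessions):
        lon, lat = _SITES_GEO[geo_idx[i]]
        lines.append(f"{acc}\t{groups[group_idx[i]]}\t{lon}\t{lat}\t{trait[i]:.4f}")
    table_path.write_text("\n".join(lines) + "\n")

    truth = Truth(hap_vectors=hap_vectors,
                  assignment={a: int(h) for a, h in zip(accessions, hap_idx)},
                  frequencies=np.bincount(hap_idx, minlength=n_haplotypes).tolist(),
                  effect_size=effect_size, clean_accessions=clean)
    (out_dir / "truth.json").write_text(json.dumps(asdict(truth), indent=1))
    return SyntheticDataset(vcf=vcf_path, gff=gff_path,
                            accession_table=table_path, truth=truth, variants=vs)


__all__ = ["generate_dataset", "SyntheticDataset", "Truth"]
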
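"""Core data model for candidate-gene haplotype analysis.

The central objects mirror the tabular structures a haplotype study
manipulates: an ordered set of variant sites with a per-accession genotype
matrix (:class:`VariantSet`), genomic feature annotation
(:class:`Annotation`), per-accession metadata (:class:`AccessionTable`), and
the per-individual / per-haplotype result tables (:class:`HapResult`,
:class:`HapSummary`).

Genotype call encoding
----------------------
Each cell of the genotype matrix is a plain string:

* a homozygous call is the allele string itself (``"A"``, ``"ATG"``,
  ``"DEL"`` for a deletion allele);
* a heterozygous call joins the two distinct alleles with ``"/"``
  (``"A/G"``, alleles sorted for canonicity);
* a missing call is ``"."``.

``is_hetero`` / ``is_missing`` are the only places that knowledge lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

#: Genotype-call token for a missing (no-call) genotype.
MISSING = "."

#: Separator joining the two alleles of a heterozygous call.
HET_SEP = "/"

#: Allele string denoting a deletion; treated as an ordinary allele for
#: haplotype grouping.
DEL = "DEL"


def is_missing(call: str) -> bool:
    """True for a no-call genotype token."""
    return call == MISSING or call == ""


def is_hetero(call: str) -> bool:
    """True for a heterozygous genotype token (two alleles joined by '/')."""
    return HET_SEP in call and not is_missing(call)


def hetero_call(a: str, b: str) -> str:
    """Canonical heterozygous token for alleles *a* and *b* (sorted)."""
    return HET_SEP.join(sorted((a, b)))


@dataclass(frozen=True)
class VariantSite:
    """One variant site: chromosome, 1-based position, ref/alt alleles.

    ``pos`` may become negative after re-anchoring coordinates on the start
    codon.  ``alt`` holds comma-separated alternate alleles for
    multi-allelic sites.  ``info`` is free-text annotation carried along
    unchanged.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    info: str = "."

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"ref and alt must be non-empty at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def alts(self) -> tuple[str, ...]:
        return tuple(self.alt.split(","))

    @property
    def alleles(self) -> tuple[str, ...]:
        """Reference allele followed by every alternate allele."""
        return (self.ref,) + self.alts

    @property
    def allele_str(self) -> str:
        """'ref/alt' rendering used in the ALLELE header row."""
        return f"{self.ref}{HET_SEP}{self.alt}"

    @classmethod
    def from_allele_str(cls, chrom: str, pos: int, allele: str, info: str = ".") -> "VariantSite":
        ref, _, alt = allele.partition(HET_SEP)
        if not alt:
            raise ValueError(f"malformed ALLELE field {allele!r} (expected 'ref/alt')")
        return cls(chrom=chrom, pos=pos, ref=ref, alt=alt, info=info)


class VariantSet:
    """Ordered variant sites plus a per-accession genotype matrix.

    The genotype matrix is a pandas DataFrame with one row per accession and
    one (string) column per site, ordered like ``sites``.
    """

    def __init__(self, sites: Sequence[VariantSite], accessions: Sequence[str],
                 genotypes: Sequence[Sequence[str]]):
        self.sites = list(sites)
        self.accessions = list(accessions)
        mat = pd.DataFrame(
            list(genotypes), index=pd.Index(self.accessions, name="accession"),
            columns=range(len(self.sites)), dtype=object,
        ) if self.accessions else pd.DataFrame(
            columns=range(len(self.sites)), dtype=object)
        if mat.shape != (len(self.accessions), len(self.sites)):
            raise ValueError(
                f"genotype matrix shape {mat.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.sites)} sites")
        self.genotypes = mat
        self._check_order()

    def _check_order(self) -> None:
        by_chrom: dict[str, int] = {}
        for s in self.sites:
            prev = by_chrom.get(s.chrom)
            if prev is not None and s.pos <= prev:
                raise ValueError(
                    f"sites not strictly increasing on {s.chrom}: {prev} then {s.pos}")
            by_chrom[s.chrom] = s.pos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def calls_for(self, accession: str) -> tuple[str, ...]:
        return tuple(self.genotypes.loc[accession])

    def subset_sites(self, keep: Iterable[int]) -> "VariantSet":
        """New VariantSet restricted to the site indices *keep* (order kept)."""
        idx = list(keep)
        sites = [self.sites[i] for i in idx]
        geno = self.genotypes[idx].to_numpy().tolist() if self.accessions else []
        return VariantSet(sites, self.accessions, geno)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantSet):
            return NotImplemented
        return (self.sites == other.sites and self.accessions == other.accessions
                and self.genotypes.to_numpy().tolist() == other.genotypes.to_numpy().tolist())

    def __repr__(self) -> str:
        return f"VariantSet({self.n_accessions} accessions x {self.n_sites} sites)"


@dataclass(frozen=True)
class Feature:
    """One annotated genomic feature (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    type: str
    transcript: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class Annotation:
    """A list of genomic features parsed from GFF3 or BED."""

    features: list[Feature] = field(default_factory=list)

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    def for_id(self, gene_or_transcript: str) -> list[Feature]:
        """Features whose name or transcript id matches."""
        return [f for f in self.features
                if gene_or_transcript in (f.name, f.transcript)]

    def __len__(self) -> int:
        return len(self.features)


class AccessionTable:
    """Accession metadata: group labels, coordinates, phenotype columns.

    Wraps a DataFrame indexed by unique accession ID.  Numeric columns are
    phenotypes or coordinates; non-numeric columns are group labels.
    Longitude/latitude columns (matched case-insensitively by name) are
    validated against [-180, 180] / [-90, 90].
    """

    LON_NAMES = ("longitude", "lon", "long")
    LAT_NAMES = ("latitude", "lat")

    def __init__(self, table: pd.DataFrame):
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate accession IDs: {dups}")
        self.table = table
        lon, lat = self.coordinate_columns()
        if lon is not None:
            vals = pd.to_numeric(table[lon], errors="coerce").dropna()
            if ((vals < -180) | (vals > 180)).any():
                raise ValueError("longitude outside [-180, 180]")
        if lat is not None:
            vals = pd.to_numeric(table[lat], errors="coerce").dropna()
            if ((vals < -90) | (vals > 90)).any():
                raise ValueError("latitude outside [-90, 90]")

    def coordinate_columns(self) -> tuple[str | None, str | None]:
        lon = lat = None
        for c in self.table.columns:
            lc = str(c).strip().lower()
            if lc in self.LON_NAMES and lon is None:
                lon = c
            elif lc in self.LAT_NAMES and lat is None:
                lat = c
        return lon, lat

    def group_columns(self) -> list[str]:
        """Non-numeric columns, i.e. candidate group/category labels."""
        return [c for c in self.table.columns
                if not pd.api.types.is_numeric_dtype(self.table[c])]

    @property
    def accessions(self) -> list[str]:
        return [str(i) for i in self.table.index]

    def __len__(self) -> int:
        return len(self.table)


def _check_hap_parts(sites: Sequence[VariantSite],
                     genotypes: Sequence[Sequence[str]]) -> None:
    for vec in genotypes:
        if len(vec) != len(sites):
            raise ValueError(
                f"genotype vector length {len(vec)} != {len(sites)} sites")


@dataclass
class HapResult:
    """Per-individual haplotype table.

    One row per surviving individual: its haplotype name, full genotype
    vector and accession ID.  All rows sharing a haplotype name carry
    identical genotype vectors.
    """

    sites: list[VariantSite]
    hap_names: list[str]
    genotypes: list[tuple[str, ...]]
    accessions: list[str]

    def __post_init__(self) -> None:
        n = len(self.hap_names)
        if not (len(self.genotypes) == len(self.accessions) == n):
            raise ValueError("hap_names, genotypes and accessions must align")
        self.genotypes = [tuple(g) for g in self.genotypes]
        _check_hap_parts(self.sites, self.genotypes)
        seen: dict[str, tuple[str, ...]] = {}
        for name, vec in zip(self.hap_names, self.genotypes):
            if seen.setdefault(name, vec) != vec:
                raise ValueError(f"haplotype {name} has inconsistent genotype vectors")

    @property
    def n_hap(self) -> int:
        return len(set(self.hap_names))

    @property
    def n_ind(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def hap_of(self) -> dict[str, str]:
        """Mapping accession -> haplotype name."""
        return dict(zip(self.accessions, self.hap_names))

    def members(self) -> dict[str, list[str]]:
        """Mapping haplotype name -> accession list (row order)."""
        out: dict[str, list[str]] = {}
        for name, acc in zip(self.hap_names, self.accessions):
            out.setdefault(name, []).append(acc)
        return out


@dataclass
class HapSummary:
    """Per-haplotype summary table.

    One row per haplotype, ordered by descending frequency; carries the
    member-accession list and a frequency column (the feature that
    distinguishes it from :class:`HapResult`).
    """

    sites: list[VariantSite]
    hap_names: list[str]
    genotypes: list[tuple[str, ...]]
    accession_lists: list[list[str]]
    freqs: list[int]

    def __post_init__(self) -> None:
        n = len(self.hap_names)
        if not (len(self.genotypes) == len(self.accession_lists) == len(self.freqs) == n):
            raise ValueError("summary columns must align")
        self.genotypes = [tuple(g) for g in self.genotypes]
        _check_hap_parts(self.sites, self.genotypes)
        for accs, f in zip(self.accession_lists, self.freqs):
            if len(accs) != f:
                raise ValueError("frequency does not match accession list length")
        if any(self.freqs[i] < self.freqs[i + 1] for i in range(n - 1)):
            raise ValueError("haplotypes must be sorted by descending frequency")

    @property
    def n_hap(self) -> int:
        return len(self.hap_names)

    @property
    def n_ind(self) -> int:
        return sum(self.freqs)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class AtgAnchor:
    """Position of the first base of a gene's start codon, with strand."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


__all__ = [
    "MISSING", "HET_SEP", "DEL", "is_missing", "is_hetero", "hetero_call",
    "VariantSite", "VariantSet", "Feature", "Annotation", "AccessionTable",
    "HapResult", "HapSummary", "AtgAnchor",
]
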
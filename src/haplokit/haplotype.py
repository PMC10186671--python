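"""Haplotype identification and start-codon-anchored coordinates.

A haplotype here is the exact genotype vector shared by a group of
accessions across the sites of a candidate-gene region.  Identification is
two steps: resolve each accession's genotype vector (optionally discarding
accessions with missing or heterozygous calls — heterozygous effects are
usually unclear and imputation is deliberately out of scope), then group
identical vectors and assign names H001, H002, ... in descending order of
group size.

Because chromosome-based coordinates are awkward for gene-level work, the
module also re-anchors positions so the first base of the start codon (ATG)
sits at zero, strand-aware, for haplotype tables and annotations alike.
"""

from __future__ import annotations

from dataclasses import replace

from .model import (
    Annotation, AtgAnchor, Feature, HapResult, HapSummary, VariantSet,
    is_hetero, is_missing,
)


def hap_name(rank: int, total: int) -> str:
    """H-prefixed, zero-padded name; width 3 grows automatically past 999."""
    width = max(3, len(str(total)))
    return f"H{rank:0{width}d}"


def call_haplotypes(vs: VariantSet, na_drop: bool = True,
                    hetero_remove: bool = True) -> HapResult:
    """Group accessions by exact genotype-vector equality into haplotypes.

    With ``hetero_remove`` every accession carrying at least one
    heterozygous call is removed; with ``na_drop`` every accession with a
    missing call is removed.  With both flags off, residual HETERO/MISSING
    tokens are retained verbatim in the vectors (they then participate in
    equality like any other string).  Groups are sorted by descending size,
    ties broken by first-seen accession order, and named H001, H002, ...
    """
    if vs.n_sites == 0:
        raise ValueError("variant set has no sites")
    rows = []
    for acc in vs.accessions:
        vec = vs.calls_for(acc)
        if hetero_remove and any(is_hetero(c) for c in vec):
            continue
        if na_drop and any(is_missing(c) for c in vec):
            continue
        rows.append((acc, vec))
    if not rows:
        raise ValueError("no accessions survive the missing/heterozygote filters")

    groups: dict[tuple[str, ...], list[str]] = {}
    first_seen: dict[tuple[str, ...], int] = {}
    for i, (acc, vec) in enumerate(rows):
        groups.setdefault(vec, []).append(acc)
        first_seen.setdefault(vec, i)
    ordered = sorted(groups, key=lambda v: (-len(groups[v]), first_seen[v]))
    name_of = {vec: hap_name(r + 1, len(ordered)) for r, vec in enumerate(ordered)}

    hap_names, genotypes, accessions = [], [], []
    for vec in ordered:
        for acc in groups[vec]:
            hap_names.append(name_of[vec])
            genotypes.append(vec)
            accessions.append(acc)
    return HapResult(sites=list(vs.sites), hap_names=hap_names,
                     genotypes=genotypes, accessions=accessions)


def summarize_haplotypes(h: HapResult) -> HapSummary:
    """Collapse a per-individual table to one row per haplotype.

    Rows are ordered by descending frequency; frequencies sum to the
    individual count of the source.
    """
    members = h.members()
    vec_of = {name: vec for name, vec in zip(h.hap_names, h.genotypes)}
    order = sorted(members, key=lambda n: (-len(members[n]), n))
    return HapSummary(
        sites=list(h.sites),
        hap_names=order,
        genotypes=[vec_of[n] for n in order],
        accession_lists=[list(members[n]) for n in order],
        freqs=[len(members[n]) for n in order],
    )


def find_atg(ann: Annotation, gene_or_transcript: str) -> AtgAnchor:
    """Locate the start codon of a gene/transcript from its CDS features.

    On the + strand the anchor is the smallest CDS start; on the − strand
    the largest CDS end.  Mixed-strand CDS features are an error.
    """
    cds = [f for f in ann.for_id(gene_or_transcript) if f.type.upper() == "CDS"]
    if not cds:
        if not ann.for_id(gene_or_transcript):
            raise ValueError(f"no features found for {gene_or_transcript!r}")
        raise ValueError(f"no CDS features for {gene_or_transcript!r}")
    strands = {f.strand for f in cds}
    if len(strands) > 1:
        raise ValueError(f"mixed strands among CDS of {gene_or_transcript!r}")
    strand = strands.pop()
    if strand == "+":
        pos = min(f.start for f in cds)
    else:
        pos = max(f.end for f in cds)
    return AtgAnchor(chrom=cds[0].chrom, pos=pos, strand=strand)


def set_atg_zero(obj: HapResult | HapSummary | Annotation,
                 anchor: AtgAnchor) -> HapResult | HapSummary | Annotation:
    """Re-express coordinates relative to the start codon (ATG = 0).

    On the + strand ``new_pos = pos - anchor.pos``; on the − strand
    ``new_pos = anchor.pos - pos`` and site order is reversed so positions
    stay ascending.  Allele strings are never reverse-complemented — only
    coordinates change, keeping genotypes comparable with the source
    variants.  Applying the transform twice with the same anchor (strand
    kept, position 0 for the second call on +) inverts it; use
    :func:`invert_atg_zero` for the exact inverse.
    """
    if isinstance(obj, Annotation):
        feats = []
        for f in obj.features:
            if anchor.strand == "+":
                s, e = f.start - anchor.pos, f.end - anchor.pos
            else:
                s, e = anchor.pos - f.end, anchor.pos - f.start
            feats.append(replace(f, start=s, end=e))
        return Annotation(feats)

    def new_pos(p: int) -> int:
        return p - anchor.pos if anchor.strand == "+" else anchor.pos - p

    sites = [replace(s, pos=new_pos(s.pos)) for s in obj.sites]
    order = list(range(len(sites)))
    if anchor.strand == "-":
        order.reverse()
        sites.reverse()
    if isinstance(obj, HapSummary):
        return HapSummary(
            sites=sites,
            hap_names=list(obj.hap_names),
            genotypes=[tuple(vec[i] for i in order) for vec in obj.genotypes],
            accession_lists=[list(a) for a in obj.accession_lists],
            freqs=list(obj.freqs),
        )
    return HapResult(
        sites=sites,
        hap_names=list(obj.hap_names),
        genotypes=[tuple(vec[i] for i in order) for vec in obj.genotypes],
        accessions=list(obj.accessions),
    )


def invert_atg_zero(obj, anchor: AtgAnchor):
    """Exact inverse of :func:`set_atg_zero` for the same anchor."""
    inverse = AtgAnchor(chrom=anchor.chrom, pos=0, strand=anchor.strand)
    back = set_atg_zero(obj, inverse)
    if isinstance(back, Annotation):
        feats = [replace(f, start=f.start + anchor.pos, end=f.end + anchor.pos)
                 for f in back.features]
        return Annotation(feats)
    sites = [replace(s, pos=s.pos + anchor.pos) for s in back.sites]
    back.sites = sites
    return back


__all__ = ["call_haplotypes", "summarize_haplotypes", "find_atg",
           "set_atg_zero", "invert_atg_zero", "hap_name"]
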
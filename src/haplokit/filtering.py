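"""Target-region variant extraction and rare-haplotype removal.

Three in-memory extraction modes: by position (chromosome + inclusive
boundaries), by annotated feature type, or both (intersection).  A
multi-base variant is considered inside a region or feature iff its POS
(left anchor) is inside.  :func:`stream_filter` applies the position mode
record-at-a-time to arbitrarily large VCF or PLINK files without loading
them, so peak memory stays independent of input size.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Sequence

from .model import Annotation, HapResult, HapSummary, VariantSet


def filter_variants(vs: VariantSet, mode: str = "position", *,
                    chrom: str | None = None, start: int | None = None,
                    end: int | None = None, ann: Annotation | None = None,
                    feature_type: str | None = None) -> VariantSet:
    """Keep variant sites inside a genomic window and/or a feature type.

    ``mode='position'`` keeps sites with ``start <= pos <= end`` on
    ``chrom``; ``mode='type'`` keeps sites whose POS falls inside any
    feature of ``feature_type``; ``mode='both'`` intersects the two.
    Site order is preserved.
    """
    if mode not in ("position", "type", "both"):
        raise ValueError(f"unknown filter mode {mode!r}")
    want_pos = mode in ("position", "both")
    want_type = mode in ("type", "both")
    if want_pos:
        if chrom is None or start is None or end is None:
            raise ValueError("position mode requires chrom, start and end")
        if start > end:
            raise ValueError(f"start {start} > end {end}")
    if want_type:
        if ann is None or feature_type is None:
            raise ValueError("type mode requires annotation and feature_type")
        feats = ann.of_type(feature_type)

    keep = []
    for i, s in enumerate(vs.sites):
        if want_pos and not (s.chrom == chrom and start <= s.pos <= end):
            continue
        if want_type and not any(
                f.chrom == s.chrom and f.start <= s.pos <= f.end for f in feats):
            continue
        keep.append(i)
    return vs.subset_sites(keep)


def stream_filter(in_path: str | Path, out_path: str | Path, format: str, *,
                  chrom: str, start: int, end: int,
                  map_in: str | Path | None = None,
                  map_out: str | Path | None = None) -> Path:
    """Single-pass region extraction for large files.

    For ``vcf`` the full header is copied and only in-region data records
    are written.  For ``plink`` the ``.map`` sites are filtered and every
    ``.ped`` record is rewritten with only the corresponding allele pairs
    (``map_in``/``map_out`` default to the in/out paths with a ``.map``
    suffix).  Output content matches :func:`filter_variants` applied to the
    fully loaded file.
    """
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    in_path, out_path = Path(in_path), Path(out_path)
    if format == "vcf":
        return _stream_vcf(in_path, out_path, chrom, start, end)
    if format == "plink":
        map_in = Path(map_in) if map_in else in_path.with_suffix(".map")
        map_out = Path(map_out) if map_out else out_path.with_suffix(".map")
        return _stream_plink(in_path, map_in, out_path, map_out, chrom, start, end)
    raise ValueError(f"unknown streaming format {format!r}")


def _open_text(path: Path):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path, "rt")


def _stream_vcf(in_path: Path, out_path: Path, chrom: str, start: int, end: int) -> Path:
    with _open_text(in_path) as src, open(out_path, "wt") as dst:
        for ln, line in enumerate(src, start=1):
            if line.startswith("#"):
                dst.write(line)
                continue
            fields = line.split("\t", 2)
            if len(fields) < 3:
                raise ValueError(f"malformed VCF record at line {ln}")
            try:
                pos = int(fields[1])
            except ValueError:
                raise ValueError(f"malformed VCF record at line {ln}: "
                                 f"non-integer POS {fields[1]!r}") from None
            if fields[0] == chrom and start <= pos <= end:
                dst.write(line)
    return out_path


def _stream_plink(ped_in: Path, map_in: Path, ped_out: Path, map_out: Path,
                  chrom: str, start: int, end: int) -> Path:
    keep: list[int] = []
    with _open_text(map_in) as src, open(map_out, "wt") as dst:
        j = 0
        for ln, line in enumerate(src, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed .map record at line {ln}")
            if parts[0] == chrom and start <= int(parts[3]) <= end:
                keep.append(j)
                dst.write(line)
            j += 1
    n_sites = j
    with _open_text(ped_in) as src, open(ped_out, "wt") as dst:
        for ln, line in enumerate(src, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_sites:
                raise ValueError(f"malformed .ped record at line {ln}: "
                                 f"{len(parts)} fields for {n_sites} map sites")
            out = parts[:6]
            for k in keep:
                out += parts[6 + 2 * k:8 + 2 * k]
            dst.write(" ".join(out) + "\n")
    return ped_out


def filter_hap(h: HapResult | HapSummary, min_members: int = 1,
               keep: Sequence[str] | None = None) -> HapResult | HapSummary:
    """Drop rare haplotypes (fewer than *min_members* individuals).

    When *keep* is given, exactly those haplotype names are retained
    regardless of size.  Retained haplotypes keep their original names, so
    identities stay stable across filtering.  Summary counts are
    recomputed.
    """
    if keep is None and min_members < 1:
        raise ValueError("min_members must be >= 1")
    if isinstance(h, HapSummary):
        sel = [i for i, (name, f) in enumerate(zip(h.hap_names, h.freqs))
               if (name in keep if keep is not None else f >= min_members)]
        if not sel:
            raise ValueError("filter removed every haplotype")
        return HapSummary(
            sites=list(h.sites),
            hap_names=[h.hap_names[i] for i in sel],
            genotypes=[h.genotypes[i] for i in sel],
            accession_lists=[list(h.accession_lists[i]) for i in sel],
            freqs=[h.freqs[i] for i in sel],
        )
    sizes: dict[str, int] = {}
    for name in h.hap_names:
        sizes[name] = sizes.get(name, 0) + 1
    wanted = (set(keep) if keep is not None
              else {n for n, c in sizes.items() if c >= min_members})
    sel = [i for i, name in enumerate(h.hap_names) if name in wanted]
    if not sel:
        raise ValueError("filter removed every haplotype")
    return HapResult(
        sites=list(h.sites),
        hap_names=[h.hap_names[i] for i in sel],
        genotypes=[h.genotypes[i] for i in sel],
        accessions=[h.accessions[i] for i in sel],
    )


__all__ = ["filter_variants", "stream_filter", "filter_hap"]
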
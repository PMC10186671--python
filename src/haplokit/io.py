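"""Readers and writers for every supported interchange format.

Variant inputs: VCF 4.x (optionally gzipped, via pysam), PLINK .ped/.map,
HapMap tab text, pre-aligned FASTA and a plain genotype table.  Annotation:
GFF3 (via gffutils) or the custom BED4/BED6 dialect whose fourth column
holds "name type" separated by a space.  Accession metadata: any delimited
table with the accession ID in the first column.

The haplotype-result serialization round-trips :class:`~haplokit.model.HapResult`
and :class:`~haplokit.model.HapSummary` through a tab-delimited layout:
summary counts as ``#``-prefixed comment lines, then four fixed header rows
labelled CHROM / POS / INFO / ALLELE, then one row per individual (result)
or per haplotype (summary, with member list and frequency columns).
"""

from __future__ import annotations

import gzip
import tempfile
from collections import Counter
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import (
    DEL, MISSING, AccessionTable, Annotation, Feature, HapResult, HapSummary,
    VariantSet, VariantSite, hetero_call, is_hetero, is_missing,
)

HAP_HEADER_LABELS = ("CHROM", "POS", "INFO", "ALLELE")

#: HapMap meta columns preceding the genotype columns.
HAPMAP_META_COLS = (
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def read_variants(path: str | Path, format: str, **options) -> VariantSet:
    """Read variants plus genotype calls into a :class:`VariantSet`.

    Parameters
    ----------
    path
        Input file.  For ``plink`` give the ``.ped`` path (the ``.map`` is
        found next to it) or pass ``map_path=...``.
    format
        One of ``vcf``, ``plink``, ``hapmap``, ``table``, ``fasta``.
    options
        Format-specific: ``map_path`` (plink), ``sep`` (table),
        ``chrom``/``offset`` (fasta coordinate mapping).

    Genotype coding: homozygous calls become the allele string, mixed
    alleles become a canonical ``a/b`` heterozygous token, and no-calls
    become ``"."``.
    """
    readers = {
        "vcf": _read_vcf,
        "plink": _read_plink,
        "hapmap": _read_hapmap,
        "table": _read_table,
        "fasta": _read_fasta,
    }
    if format not in readers:
        raise ValueError(f"unknown variant format {format!r} "
                         f"(expected one of {sorted(readers)})")
    return readers[format](Path(path), **options)


def _detect_sep(path: Path) -> str:
    """Pick the delimiter of a text table from its header line."""
    first = next(iter(_text_lines(path)), "")
    counts = {sep: first.count(sep) for sep in ("\t", ",", ";", "|")}
    best = max(counts, key=counts.get)
    return best if counts[best] else r"\s+"


def _read_vcf(path: Path) -> VariantSet:
    import pysam

    if str(path).endswith(".gz"):
        # htslib only seeks in BGZF; transparently re-inflate plain gzip
        try:
            with pysam.VariantFile(str(path)):
                pass
        except (NotImplementedError, OSError, ValueError):
            with gzip.open(path, "rt") as src, tempfile.NamedTemporaryFile(
                    "wt", suffix=".vcf", delete=False) as dst:
                dst.write(src.read())
                path = Path(dst.name)

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        sites: list[VariantSite] = []
        rows: list[list[str]] = [[] for _ in samples]
        for rec in vf:
            alts = rec.alts or ()
            if not alts:
                continue  # monomorphic record: no alternate allele
            alleles = (rec.ref,) + tuple(alts)
            info = rec.id if rec.id and rec.id != "." else "."
            sites.append(VariantSite(chrom=rec.chrom, pos=rec.pos,
                                     ref=rec.ref, alt=",".join(alts), info=info))
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                rows[i].append(_code_gt(gt, alleles))
    return VariantSet(sites, samples, rows)


def _code_gt(gt, alleles: tuple[str, ...]) -> str:
    """Map a pysam GT tuple to the call encoding (total on any input)."""
    if gt is None:
        return MISSING
    idx = [g for g in gt if g is not None]
    if not idx:
        return MISSING
    if any(g < 0 or g >= len(alleles) for g in idx):
        raise ValueError(f"GT allele index out of range: {gt}")
    called = {alleles[g] for g in idx}
    if len(called) == 1:
        return called.pop()
    return hetero_call(*sorted(called)[:2])


def _major_allele(tokens: list[str]) -> str:
    """Most frequent allele among homozygous and het-component calls."""
    counts: Counter[str] = Counter()
    for t in tokens:
        if is_missing(t):
            continue
        counts.update(t.split("/"))
    if not counts:
        raise ValueError("site has no called alleles")
    # deterministic: highest count, then allele-string sort
    return min(counts, key=lambda a: (-counts[a], a))


def _sites_from_calls(chrom_pos: list[tuple[str, int]],
                      calls: list[list[str]]) -> list[VariantSite]:
    """Derive ref (major allele) / alt for formats lacking the designation."""
    sites = []
    for j, (chrom, pos) in enumerate(chrom_pos):
        col = [row[j] for row in calls]
        alleles = set()
        for t in col:
            if not is_missing(t):
                alleles.update(t.split("/"))
        ref = _major_allele(col)
        alts = sorted(alleles - {ref})
        if not alts:
            raise ValueError(f"monomorphic site at {chrom}:{pos}")
        sites.append(VariantSite(chrom=chrom, pos=pos, ref=ref, alt=",".join(alts)))
    return sites


def _read_plink(path: Path, map_path: str | Path | None = None) -> VariantSet:
    ped = path
    mp = Path(map_path) if map_path else ped.with_suffix(".map")
    map_rows = []
    for line in _text_lines(mp):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"malformed .map line: {line!r}")
        map_rows.append((parts[0], int(parts[3])))
    n_sites = len(map_rows)
    accessions: list[str] = []
    calls: list[list[str]] = []
    for line in _text_lines(ped):
        parts = line.split()
        if len(parts) != 6 + 2 * n_sites:
            raise ValueError(
                f".ped record has {len(parts)} fields, expected {6 + 2 * n_sites} "
                f"for {n_sites} map sites")
        accessions.append(parts[1])
        row = []
        for j in range(n_sites):
            a, b = parts[6 + 2 * j], parts[7 + 2 * j]
            if a in ("0", "-9") or b in ("0", "-9"):
                row.append(MISSING)
            elif a == b:
                row.append(a)
            else:
                row.append(hetero_call(a, b))
        calls.append(row)
    sites = _sites_from_calls(map_rows, calls)
    return VariantSet(sites, accessions, calls)


def _read_hapmap(path: Path) -> VariantSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < len(HAPMAP_META_COLS) + 1:
        raise ValueError("HapMap file needs 11 meta columns plus genotypes")
    accessions = list(df.columns[len(HAPMAP_META_COLS):])
    sites: list[VariantSite] = []
    calls: list[list[str]] = [[] for _ in accessions]
    for _, row in df.iterrows():
        ref, _, alt = str(row.iloc[1]).partition("/")
        if not alt:
            raise ValueError(f"malformed alleles field {row.iloc[1]!r}")
        sites.append(VariantSite(chrom=str(row.iloc[2]), pos=int(row.iloc[3]),
                                 ref=ref, alt=alt, info=str(row.iloc[0])))
        for i, acc in enumerate(accessions):
            calls[i].append(_code_hapmap_cell(str(row[acc]), ref))
    return VariantSet(sites, accessions, calls)


def _code_hapmap_cell(cell: str, ref: str) -> str:
    cell = cell.strip()
    if cell in ("NN", "N", "", "nan", "--", MISSING):
        return MISSING
    if "/" in cell:  # already 'a/b' style (indel-friendly)
        a, _, b = cell.partition("/")
        return a if a == b else hetero_call(a, b)
    if len(cell) == 2 and len(ref) == 1:  # classic two-letter diploid code
        a, b = cell[0], cell[1]
        return a if a == b else hetero_call(a, b)
    return cell  # single allele string (haploid / multi-base)


def _read_table(path: Path, sep: str | None = None) -> VariantSet:
    """Plain genotype table: CHROM, POS, REF, ALT, INFO then one column per
    accession; cells hold an allele string, ``DEL``, ``N``/empty for missing
    or ``a/b`` for heterozygotes."""
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                     keep_default_na=False)
    required = ["CHROM", "POS", "REF", "ALT", "INFO"]
    if list(df.columns[:5]) != required:
        raise ValueError(f"genotype table must start with columns {required}, "
                         f"got {list(df.columns[:5])}")
    accessions = list(df.columns[5:])
    sites = [VariantSite(chrom=r.CHROM, pos=int(r.POS), ref=r.REF, alt=r.ALT,
                         info=r.INFO or ".")
             for r in df.itertuples()]
    calls: list[list[str]] = []
    for acc in accessions:
        col = []
        for cell in df[acc]:
            cell = cell.strip()
            if cell in ("", "N", "NA", MISSING):
                col.append(MISSING)
            elif "/" in cell:
                a, _, b = cell.partition("/")
                col.append(a if a == b else hetero_call(a, b))
            else:
                col.append(cell)
        calls.append(col)
    vs = VariantSet(sites, accessions, calls)
    _validate_table_calls(vs)
    return vs


def _validate_table_calls(vs: VariantSet) -> None:
    for j, site in enumerate(vs.sites):
        valid = set(site.alleles) | {DEL}
        for acc in vs.accessions:
            call = vs.genotypes.at[acc, j]
            if is_missing(call):
                continue
            for a in call.split("/"):
                if a not in valid:
                    raise ValueError(
                        f"genotype {call!r} of {acc} at {site.chrom}:{site.pos} "
                        f"is not among alleles {sorted(valid)}")


def _read_fasta(path: Path, chrom: str = "aln", offset: int = 0) -> VariantSet:
    """Derive variant sites from a pre-aligned FASTA.

    Positions are 1-based alignment-column indices plus *offset*.  Runs of
    consecutive columns with an identical gap pattern collapse into a single
    site; a sequence whose run is entirely gaps carries the ``DEL`` allele.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError("empty FASTA")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"FASTA sequences are not aligned (lengths {sorted(lengths)})")
    n = lengths.pop()
    seqs = [str(r.seq).upper() for r in records]
    names = [r.id for r in records]

    sites: list[VariantSite] = []
    calls: list[list[str]] = [[] for _ in names]
    j = 0
    while j < n:
        col = [s[j] for s in seqs]
        if "-" in col:
            # extend the run while the gap pattern is unchanged
            pattern = tuple(c == "-" for c in col)
            k = j + 1
            while k < n and "-" in [s[k] for s in seqs] and \
                    tuple(s[k] == "-" for s in seqs) == pattern:
                k += 1
            run_alleles = []
            for s in seqs:
                seg = s[j:k].replace("-", "")
                run_alleles.append(seg if seg else DEL)
            if len(set(run_alleles)) > 1:
                _append_fasta_site(sites, calls, run_alleles, chrom, j + 1 + offset)
            j = k
        else:
            if len(set(col)) > 1:
                _append_fasta_site(sites, calls, col, chrom, j + 1 + offset)
            j += 1
    return VariantSet(sites, names, calls)


def _append_fasta_site(sites, calls, alleles_per_seq, chrom, pos) -> None:
    tokens = [MISSING if a == "N" else a for a in alleles_per_seq]
    distinct = {t for t in tokens if not is_missing(t)}
    if len(distinct) < 2:
        return
    ref = _major_allele(tokens)
    alts = sorted(distinct - {ref})
    sites.append(VariantSite(chrom=chrom, pos=pos, ref=ref, alt=",".join(alts)))
    for row, t in zip(calls, tokens):
        row.append(t)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, format: str) -> Annotation:
    """Read GFF3 or custom BED4/BED6 annotation.

    BED coordinates (0-based half-open) are converted to 1-based inclusive.
    The BED name field "name type" is split on the first space; BED4 lines
    default to the + strand.  GFF3 transcript ids come from the Parent
    attribute (falling back to ID).
    """
    path = Path(path)
    if format == "gff":
        return _read_gff(path)
    if format == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gff(path: Path) -> Annotation:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    feats = []
    for f in db.all_features():
        parents = f.attributes.get("Parent", [])
        name = (f.attributes.get("Name") or f.attributes.get("ID") or [f.id])[0]
        feats.append(Feature(chrom=f.seqid, start=f.start, end=f.end,
                             strand=f.strand if f.strand in "+-" else "+",
                             name=name, type=f.featuretype,
                             transcript=parents[0] if parents else name))
    return Annotation(feats)


def _read_bed(path: Path) -> Annotation:
    feats = []
    for ln, line in enumerate(_text_lines(path), start=1):
        if line.startswith(("#", "track", "browser")):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) == 1:
            cols = line.split()
        if len(cols) not in (4, 6):
            raise ValueError(f"BED line {ln}: expected 4 or 6 columns, got {len(cols)}")
        try:
            start0, end0 = int(cols[1]), int(cols[2])
        except ValueError as e:
            raise ValueError(f"BED line {ln}: non-integer coordinates") from e
        name_field = cols[3].strip()
        name, _, ftype = name_field.partition(" ")
        strand = cols[5] if len(cols) == 6 else "+"
        feats.append(Feature(chrom=cols[0], start=start0 + 1, end=end0,
                             strand=strand, name=name, type=ftype or "region",
                             transcript=name))
    return Annotation(feats)


def feature_to_bed_fields(f: Feature) -> list[str]:
    """Inverse of the BED6 conversion (1-based inclusive -> 0-based half-open)."""
    return [f.chrom, str(f.start - 1), str(f.end), f"{f.name} {f.type}", "0", f.strand]


# ---------------------------------------------------------------------------
# accession metadata
# ---------------------------------------------------------------------------

def read_accession_table(path: str | Path, sep: str | None = None,
                         id_column: int | str = 0) -> AccessionTable:
    """Read a delimited accession-information table (header required).

    The accession IDs live in the first column by default.  Numeric columns
    parse as phenotypes/coordinates, non-numeric as group labels.
    """
    path = Path(path)
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty:
        raise ValueError("empty accession table")
    if isinstance(id_column, int):
        id_column = df.columns[id_column]
    df = df.set_index(id_column)
    df.index = df.index.map(str)
    for c in df.columns:
        converted = pd.to_numeric(df[c], errors="coerce")
        if converted.notna().sum() == df[c].notna().sum():
            df[c] = converted
    return AccessionTable(df)


# ---------------------------------------------------------------------------
# hapResult / hapSummary serialization
# ---------------------------------------------------------------------------

def write_hap(h: HapResult | HapSummary, path: str | Path) -> Path:
    """Serialize a haplotype table (tab-delimited; see module docstring)."""
    path = Path(path)
    is_summary = isinstance(h, HapSummary)
    lines = [
        f"# type={'hapSummary' if is_summary else 'hapResult'}",
        f"# haplotypes={h.n_hap}\tindividuals={h.n_ind}\tvariants={h.n_sites}",
    ]
    for label in HAP_HEADER_LABELS:
        vals = {
            "CHROM": [s.chrom for s in h.sites],
            "POS": [str(s.pos) for s in h.sites],
            "INFO": [s.info for s in h.sites],
            "ALLELE": [s.allele_str for s in h.sites],
        }[label]
        tail = ["", ""] if is_summary else [""]
        lines.append("\t".join([label] + vals + tail))
    if is_summary:
        for name, vec, accs, f in zip(h.hap_names, h.genotypes,
                                      h.accession_lists, h.freqs):
            lines.append("\t".join([name, *vec, ";".join(accs), str(f)]))
    else:
        for name, vec, acc in zip(h.hap_names, h.genotypes, h.accessions):
            lines.append("\t".join([name, *vec, acc]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_hap(path: str | Path) -> HapResult | HapSummary:
    """Re-import a serialized haplotype table; inverse of :func:`write_hap`."""
    lines = [ln.rstrip("\n") for ln in _text_lines(Path(path), keep_blank=False)]
    kind = "hapResult"
    body = []
    for ln in lines:
        if ln.startswith("#"):
            if "type=" in ln:
                kind = ln.split("type=", 1)[1].strip()
            continue
        body.append(ln.split("\t"))
    if len(body) < 4:
        raise ValueError("truncated haplotype file")
    labels = tuple(row[0] for row in body[:4])
    if labels != HAP_HEADER_LABELS:
        raise ValueError(
            f"first four row labels must be {HAP_HEADER_LABELS}, got {labels}")
    is_summary = kind == "hapSummary"
    extra = 2 if is_summary else 1
    n_sites = len(body[0]) - 1 - extra
    if n_sites < 1:
        raise ValueError("no variant columns found")
    chroms, poss, infos, alleles = (row[1:1 + n_sites] for row in body[:4])
    sites = [VariantSite.from_allele_str(c, int(p), a, info=i)
             for c, p, i, a in zip(chroms, poss, infos, alleles)]
    if is_summary:
        names, genos, acc_lists, freqs = [], [], [], []
        for row in body[4:]:
            names.append(row[0])
            genos.append(tuple(row[1:1 + n_sites]))
            acc_lists.append(row[1 + n_sites].split(";") if row[1 + n_sites] else [])
            freqs.append(int(row[2 + n_sites]))
        return HapSummary(sites, names, genos, acc_lists, freqs)
    names, genos, accs = [], [], []
    for row in body[4:]:
        names.append(row[0])
        genos.append(tuple(row[1:1 + n_sites]))
        accs.append(row[1 + n_sites])
    return HapResult(sites, names, genos, accs)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_hap(h: HapResult | HapSummary, path: str | Path, format: str) -> Path:
    """Export a haplotype table as HapMap text or a FASTA pseudo-alignment.

    ``hapmap``: one row per site, one genotype column per haplotype.
    ``alignment``: one record per haplotype, concatenating site alleles with
    each site's alleles gap-padded to a common length (a ``DEL`` allele
    becomes all gaps).
    """
    names, genotypes = _hap_rows(h)
    if not names or not h.sites:
        raise ValueError("cannot export an empty haplotype table")
    path = Path(path)
    if format == "hapmap":
        header = list(HAPMAP_META_COLS) + names
        lines = ["\t".join(header)]
        for j, s in enumerate(h.sites):
            meta = [f"{s.chrom}_{s.pos}", s.allele_str, s.chrom, str(s.pos),
                    "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            lines.append("\t".join(meta + [vec[j] for vec in genotypes]))
        path.write_text("\n".join(lines) + "\n")
        return path
    if format == "alignment":
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        widths = []
        for j, s in enumerate(h.sites):
            cand = [0 if a == DEL else len(a) for a in s.alleles] + \
                   [0 if v == DEL else len(v) for v in (vec[j] for vec in genotypes)]
            widths.append(max(cand))
        recs = []
        for name, vec in zip(names, genotypes):
            seq = "".join(_pad_allele(vec[j], widths[j]) for j in range(len(h.sites)))
            recs.append(SeqRecord(Seq(seq), id=name, description=""))
        SeqIO.write(recs, str(path), "fasta")
        return path
    raise ValueError(f"unknown export format {format!r}")


def _pad_allele(call: str, width: int) -> str:
    if call == DEL:
        return "-" * width
    if is_missing(call):
        return "N" * width
    if is_hetero(call):  # degenerate: keep first allele, note in docs
        call = call.split("/")[0]
    return call + "-" * (width - len(call))


def _hap_rows(h: HapResult | HapSummary) -> tuple[list[str], list[tuple[str, ...]]]:
    if isinstance(h, HapSummary):
        return list(h.hap_names), list(h.genotypes)
    names, genos, seen = [], [], set()
    for name, vec in zip(h.hap_names, h.genotypes):
        if name not in seen:
            seen.add(name)
            names.append(name)
            genos.append(vec)
    return names, genos


# ---------------------------------------------------------------------------
# VCF writing (used by the simulator and for re-emission round-trips)
# ---------------------------------------------------------------------------

def write_vcf(vs: VariantSet, path: str | Path) -> Path:
    """Emit a VariantSet as a minimal, pysam-readable VCF 4.2 text file.

    Heterozygous calls become ``0/1``-style unphased genotypes; calls not
    expressible against the site's ref/alt (e.g. ``DEL`` from a table)
    raise, since VCF has no such token.
    """
    path = Path(path)
    contigs = sorted({s.chrom for s in vs.sites})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                            "FILTER", "INFO", "FORMAT", *vs.accessions]))
    for j, s in enumerate(vs.sites):
        allele_index = {a: i for i, a in enumerate(s.alleles)}
        gts = []
        for acc in vs.accessions:
            call = vs.genotypes.at[acc, j]
            if is_missing(call):
                gts.append("./.")
            elif is_hetero(call):
                a, b = call.split("/")
                gts.append(f"{_gt_idx(a, allele_index, s)}/{_gt_idx(b, allele_index, s)}")
            else:
                i = _gt_idx(call, allele_index, s)
                gts.append(f"{i}/{i}")
        lines.append("\t".join([s.chrom, str(s.pos), s.info, s.ref, s.alt,
                                ".", "PASS", ".", "GT", *gts]))
    path.write_text("\n".join(lines) + "\n")
    return path


def _gt_idx(allele: str, allele_index: dict[str, int], s: VariantSite) -> int:
    try:
        return allele_index[allele]
    except KeyError:
        raise ValueError(f"call {allele!r} at {s.chrom}:{s.pos} is not among "
                         f"the site's alleles {s.alleles}") from None


def _text_lines(path: Path, keep_blank: bool = False):
    """Yield stripped lines from a plain or gzipped text file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line or keep_blank:
                yield line


__all__ = [
    "read_variants", "read_annotation", "read_accession_table",
    "write_hap", "read_hap", "export_hap", "write_vcf",
    "feature_to_bed_fields", "HAP_HEADER_LABELS", "HAPMAP_META_COLS",
]
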
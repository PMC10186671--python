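"""Figure rendering for haplotype results.

Six figure types: the haplotype genotype table, variants flagged on a gene
model, the haplotype network, an LD heatmap beneath a gene-model track, a
geographic pie map and haplotype-vs-phenotype boxplots with significance
brackets.  Output format (PNG/SVG/PDF) follows the file extension.  All
layouts are deterministic: the network layout takes a fixed seed.
"""

from __future__ import annotations

import json
from importlib import resources
from itertools import cycle
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import FancyArrow, Polygon, Rectangle, Wedge

from .ld import LDMatrix
from .model import Annotation, DEL, HapSummary, is_missing
from .network import HaploNetwork
from .phenogeo import GeoDistribution, PhenoComparison, significance_stars

#: Fixed colours for the common single-base alleles and deletions; longer
#: alleles cycle through a qualitative palette.
ALLELE_COLORS = {"A": "#4daf4a", "C": "#377eb8", "G": "#ff7f00",
                 "T": "#e41a1c", DEL: "#999999"}
_EXTRA_PALETTE = ("#984ea3", "#a65628", "#f781bf", "#17becf", "#bcbd22")

GROUP_PALETTE = ("#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
                 "#8c564b", "#e377c2", "#7f7f7f")


def allele_color_map(alleles) -> dict[str, str]:
    """Consistent allele -> colour mapping across all columns of a figure."""
    cmap = dict(ALLELE_COLORS)
    extra = cycle(_EXTRA_PALETTE)
    for a in alleles:
        if a not in cmap:
            cmap[a] = next(extra)
    return cmap


def _save(fig, out_path) -> Path:
    out_path = Path(out_path)
    fig.savefig(out_path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return out_path


def plot_hap_table(hs: HapSummary, out_path, show_info: bool = False) -> Path:
    """Table-like figure: one row per haplotype, allele-coloured site
    columns, frequency in the last column."""
    if hs.n_hap == 0 or hs.n_sites == 0:
        raise ValueError("cannot plot an empty haplotype summary")
    n_rows, n_cols = hs.n_hap, hs.n_sites
    fig, ax = plt.subplots(figsize=(1.0 * n_cols + 2.5, 0.45 * (n_rows + 3) + 1))
    all_alleles = sorted({g for vec in hs.genotypes for g in vec})
    cmap = allele_color_map(all_alleles)

    header_rows = [("POS", [str(s.pos) for s in hs.sites]),
                   ("ALLELE", [s.allele_str for s in hs.sites])]
    if show_info:
        header_rows.append(("INFO", [s.info for s in hs.sites]))
    y = 0
    for label, vals in header_rows:
        ax.text(-0.6, -y, label, ha="right", va="center", fontweight="bold")
        for j, v in enumerate(vals):
            ax.text(j + 0.5, -y, v, ha="center", va="center", fontsize=8)
        y += 1
    ax.text(n_cols + 0.6, -(y - 1), "freq", ha="left", va="center",
            fontweight="bold")
    for i, (name, vec, f) in enumerate(zip(hs.hap_names, hs.genotypes, hs.freqs)):
        row_y = -(y + i)
        ax.text(-0.6, row_y, name, ha="right", va="center")
        for j, g in enumerate(vec):
            color = "#dddddd" if is_missing(g) else cmap.get(g, "#dddddd")
            ax.add_patch(Rectangle((j, row_y - 0.4), 1, 0.8, facecolor=color,
                                   edgecolor="white"))
            ax.text(j + 0.5, row_y, g, ha="center", va="center", fontsize=8)
        ax.text(n_cols + 0.6, row_y, str(f), ha="left", va="center")
    ax.set_xlim(-2.5, n_cols + 2)
    ax.set_ylim(-(y + n_rows), 1)
    ax.axis("off")
    ax.set_title("Haplotype genotypes")
    return _save(fig, out_path)


def plot_variants_on_gene_model(ann: Annotation, hs: HapSummary, out_path) -> Path:
    """Exon rectangles on a genome line with one labelled flag per site.

    Both inputs must share a coordinate system (either chromosome-based or
    ATG-zeroed); if every site falls outside the annotation span a warning
    is drawn onto the figure.
    """
    transcripts: dict[str, list] = {}
    for f in ann.features:
        if f.type.lower() in ("exon", "cds"):
            transcripts.setdefault(f.transcript or f.name, []).append(f)
    if not transcripts:
        transcripts = {"region": list(ann.features)}
    span_lo = min(f.start for f in ann.features)
    span_hi = max(f.end for f in ann.features)
    positions = [s.pos for s in hs.sites]

    fig, ax = plt.subplots(figsize=(9, 1.2 + 0.8 * len(transcripts)))
    colors = cycle(GROUP_PALETTE)
    for row, (tid, feats) in enumerate(sorted(transcripts.items())):
        color = next(colors)
        y = -row
        ax.hlines(y, span_lo, span_hi, color="black", lw=1)
        for f in feats:
            ax.add_patch(Rectangle((f.start, y - 0.18), f.end - f.start + 1,
                                   0.36, facecolor=color, edgecolor="black", lw=0.4))
        ax.text(span_lo, y + 0.32, tid, fontsize=8, color=color)
    flag_y = 0.75
    for s in hs.sites:
        ax.add_patch(FancyArrow(s.pos, 0.2, 0, flag_y - 0.25, width=0.0,
                                head_width=0, color="black", lw=0.8))
        ax.text(s.pos, flag_y, f"{s.pos}({s.allele_str})", rotation=60,
                ha="left", va="bottom", fontsize=7)
    if positions and (max(positions) < span_lo or min(positions) > span_hi):
        ax.text(0.5, 0.5, "warning: all variants outside the annotation span",
                transform=ax.transAxes, color="red", ha="center")
    ax.set_ylim(-len(transcripts) + 0.4, 2.2)
    lo = min([span_lo] + positions)
    hi = max([span_hi] + positions)
    pad = 0.05 * (hi - lo + 1)
    ax.set_xlim(lo - pad, hi + pad)
    ax.get_yaxis().set_visible(False)
    ax.spines[["left", "top", "right"]].set_visible(False)
    ax.set_xlabel("position")
    return _save(fig, out_path)


def _pie_at(ax, x, y, r, fractions, colors) -> None:
    start = 90.0
    for frac, col in zip(fractions, colors):
        if frac <= 0:
            continue
        ax.add_patch(Wedge((x, y), r, start, start + 360 * frac,
                           facecolor=col, edgecolor="black", lw=0.5))
        start += 360 * frac


def plot_network(net: HaploNetwork, out_path, scale: float = 1.0,
                 seed: int = 42) -> Path:
    """Haplotype network: circle area ∝ frequency, pie sectors ∝ group
    composition, tick marks on each link counting mutation steps."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for l in net.links:
        g.add_edge(l.a, l.b, weight=l.steps)
    pos = nx.spring_layout(g, seed=seed, weight=None)

    all_groups = sorted({grp for d in net.groups.values() for grp in d})
    gcolor = {grp: GROUP_PALETTE[i % len(GROUP_PALETTE)]
              for i, grp in enumerate(all_groups)}
    max_f = max(net.freqs.values())

    fig, ax = plt.subplots(figsize=(7, 7))
    for l in net.links + net.alt_links:
        (x1, y1), (x2, y2) = pos[l.a], pos[l.b]
        style = "-" if l in net.links else "--"
        ax.plot([x1, x2], [y1, y2], style, color="grey", lw=1, zorder=1)
        # one tick per mutation step, perpendicular to the link
        dx, dy = x2 - x1, y2 - y1
        norm = np.hypot(dx, dy) or 1.0
        px, py = -dy / norm * 0.02, dx / norm * 0.02
        for k in range(1, l.steps + 1):
            t = k / (l.steps + 1)
            cx, cy = x1 + t * dx, y1 + t * dy
            ax.plot([cx - px, cx + px], [cy - py, cy + py], color="black",
                    lw=1, zorder=2)
    for n in net.nodes:
        r = scale * 0.12 * np.sqrt(net.freqs[n] / max_f)
        comp = net.groups.get(n, {"ungrouped": net.freqs[n]})
        total = sum(comp.values()) or 1
        fracs = [comp.get(grp, 0) / total for grp in all_groups]
        _pie_at(ax, *pos[n], r, fracs, [gcolor[grp] for grp in all_groups])
        ax.text(pos[n][0], pos[n][1] + r + 0.02, f"{n} (n={net.freqs[n]})",
                ha="center", fontsize=8)
    handles = [plt.Line2D([], [], marker="o", ls="", color=gcolor[grp], label=grp)
               for grp in all_groups]
    ax.legend(handles=handles, loc="best", fontsize=8)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title("Haplotype network")
    return _save(fig, out_path)


def plot_ld_heatmap(ld: LDMatrix, out_path, ann: Annotation | None = None,
                    measure: str = "r2") -> Path:
    """Triangular LD heatmap with a gene-model track and connector lines
    from each variant's genomic position to its matrix column."""
    mat = ld.matrix(measure).to_numpy()
    n = mat.shape[0]
    if n == 0:
        raise ValueError("empty LD matrix")
    fig, (ax_gene, ax_heat) = plt.subplots(
        2, 1, figsize=(7, 8), height_ratios=[1, 4], sharex=False)

    # heatmap (lower triangle)
    masked = np.ma.masked_invalid(np.tril(mat))
    im = ax_heat.imshow(masked, cmap="Reds", vmin=0, vmax=1, origin="upper")
    ax_heat.set_xticks(range(n), ld.labels, rotation=90, fontsize=7)
    ax_heat.set_yticks(range(n), ld.labels, fontsize=7)
    fig.colorbar(im, ax=ax_heat, shrink=0.7,
                 label="r²" if measure == "r2" else "D'")

    # gene model on top with connectors to the matrix columns
    site_pos = [int(lbl.rsplit(":", 1)[1]) for lbl in ld.labels]
    if ann is not None and len(ann):
        lo = min(min(f.start for f in ann.features), min(site_pos))
        hi = max(max(f.end for f in ann.features), max(site_pos))
        ax_gene.hlines(0.5, lo, hi, color="black", lw=1)
        for f in ann.features:
            if f.type.lower() in ("exon", "cds"):
                ax_gene.add_patch(Rectangle((f.start, 0.35),
                                            f.end - f.start + 1, 0.3,
                                            facecolor="#377eb8", edgecolor="black",
                                            lw=0.4))
    else:
        lo, hi = min(site_pos), max(site_pos)
        ax_gene.hlines(0.5, lo, hi, color="black", lw=1)
    for k, p in enumerate(site_pos):
        frac = (k + 0.5) / n
        x_col = lo + frac * (hi - lo)
        ax_gene.plot([p, x_col], [0.35, 0.0], color="grey", lw=0.7)
    ax_gene.set_ylim(0, 1)
    ax_gene.set_xlim(lo - 1, hi + 1)
    ax_gene.axis("off")
    return _save(fig, out_path)


def load_world_outline() -> list[list[tuple[float, float]]]:
    """Bundled schematic coastline polygons (synthetic, coarse)."""
    text = resources.files("haplokit.data").joinpath(
        "world_outline_synthetic.json").read_text()
    return [[(float(x), float(y)) for x, y in poly]
            for poly in json.loads(text)["polygons"]]


def plot_geo_map(gd: GeoDistribution, out_path, symbol_size: float = 1.0,
                 show_label: bool = True) -> Path:
    """World map with one haplotype-composition pie per location.

    Circle radius scales with the square root of the location's accession
    count, multiplied linearly by ``symbol_size``; with ``show_label`` the
    total count is printed inside each circle.
    """
    fig, ax = plt.subplots(figsize=(10, 5.5))
    for poly in load_world_outline():
        ax.add_patch(Polygon(poly, closed=True, facecolor="#f0ead8",
                             edgecolor="#999999", lw=0.6, zorder=0))
    colors = {n: GROUP_PALETTE[i % len(GROUP_PALETTE)]
              for i, n in enumerate(gd.hap_names)}
    max_total = gd.locations["total"].max()
    for _, row in gd.locations.iterrows():
        r = symbol_size * 6.0 * np.sqrt(row["total"] / max_total)
        fracs = [row[n] / row["total"] for n in gd.hap_names]
        _pie_at(ax, row["lon"], row["lat"], r, fracs,
                [colors[n] for n in gd.hap_names])
        if show_label:
            ax.text(row["lon"], row["lat"], str(int(row["total"])),
                    ha="center", va="center", fontsize=8, zorder=5)
    handles = [plt.Line2D([], [], marker="o", ls="", color=colors[n], label=n)
               for n in gd.hap_names]
    ax.legend(handles=handles, loc="lower left", fontsize=8)
    ax.set_xlim(-180, 180)
    ax.set_ylim(-75, 85)
    ax.set_aspect("equal")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return _save(fig, out_path)


def plot_pheno(pc: PhenoComparison, out_path, hide_ns: bool = False) -> Path:
    """Per-haplotype boxplots with pairwise significance brackets/stars."""
    names = sorted(pc.groups)
    if len(names) < 2:
        raise ValueError("need at least two haplotype groups to plot")
    data = [pc.groups[n] for n in names]
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 5))
    ax.boxplot(data, tick_labels=[f"{n}\n(n={len(v)})"
                                  for n, v in zip(names, data)])
    top = max(v.max() for v in data)
    span = top - min(v.min() for v in data) or 1.0
    h = top + 0.05 * span
    idx = {n: i + 1 for i, n in enumerate(names)}
    for _, row in pc.pairs.iterrows():
        stars = row["stars"] or significance_stars(row["p"])
        if hide_ns and not stars:
            continue
        x1, x2 = idx[row["hapA"]], idx[row["hapB"]]
        ax.plot([x1, x1, x2, x2], [h, h + 0.015 * span, h + 0.015 * span, h],
                color="black", lw=0.8)
        label = stars if stars else f"p={row['p']:.2g}"
        ax.text((x1 + x2) / 2, h + 0.02 * span, label, ha="center", fontsize=8)
        h += 0.08 * span
    ax.set_ylabel(pc.trait)
    ax.set_title(f"{pc.trait} by haplotype")
    return _save(fig, out_path)


__all__ = [
    "plot_hap_table", "plot_variants_on_gene_model", "plot_network",
    "plot_ld_heatmap", "plot_geo_map", "plot_pheno", "allele_color_map",
    "load_world_outline", "ALLELE_COLORS",
]
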
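# Methods

## Haplotype model

The unit of analysis is a candidate-gene region with an ordered set of
variant sites and a per-accession genotype call at each site.  A haplotype
is the exact genotype vector over those sites; two accessions share a
haplotype iff their vectors are string-identical at every site.  This is a
deliberate, assumption-free definition: no phasing, no imputation, no
clustering.  It presumes the panel is effectively inbred/homozygous — the
normal situation for germplasm collections — which is why the default
pipeline removes any accession carrying a heterozygous or missing call
before grouping (heterozygous effects are rarely interpretable at the
candidate-gene scale, and imputation is out of scope by design).  Both
removals can be disabled, in which case the `a/b` and `.` tokens
participate in vector equality like ordinary strings.

Groups are ordered by descending size (ties broken by first-seen accession
order, so the naming is deterministic and stable under re-runs) and named
`H001, H002, …`; the zero-padding grows past 999 haplotypes.  Names are
*never* reassigned by downstream filtering: removing rare haplotypes keeps
the surviving names, so `H003` means the same haplotype before and after
`filter_hap`.

A deletion genotype is written with the reserved allele string `DEL` and is
treated as an ordinary allele for grouping and distances.  Indel
coordinates and sizes are taken exactly as given in the input; no
re-left-alignment or normalization is attempted, so results can differ by
one base from tools that re-identify indels.

## Input conventions

* **VCF** (via pysam): homozygous GT → the allele string, mixed GT → a
  canonical heterozygous token, no-call → missing.  Phased `|` and
  unphased `/` separators are treated identically — only allele equality
  defines homozygosity.  Multi-allelic records stay one site with
  comma-separated alternates.
* **PLINK ped/map and aligned FASTA** carry no ref/alt designation; the
  reference allele is defined as the major allele (ties broken by allele
  string sort).  This only affects labelling, never grouping.
* **FASTA** sequences must be pre-aligned (equal length).  Site positions
  default to 1-based alignment-column indices, with an optional
  chromosome/offset to lift them to genomic coordinates.  Runs of adjacent
  columns with an identical gap pattern collapse into a single indel site
  whose gapped allele is `DEL`; `N` becomes missing.
* **Genotype table**: columns `CHROM POS REF ALT INFO` then one column per
  accession holding an allele string, `DEL`, `N`/empty for missing, or
  `a/b` for a heterozygote.  Calls are validated against the site's
  declared alleles.  (This dialect is this package's declared convention
  for table input.)
* **BED4/6**: 0-based half-open converted to 1-based inclusive; column 4 is
  split on the first space into feature name and type; BED4 strand
  defaults to `+`.
* **hapResult/hapSummary serialization** is tab-delimited with the fixed
  header rows `CHROM`, `POS`, `INFO`, `ALLELE` describing the sites, one
  row per individual (result) or per haplotype (summary, with member list
  and a frequency column).  The summary counts (haplotypes, individuals,
  variants) are written as `#`-prefixed comment lines so the body stays
  rectangular; they are recomputed and re-validated on load.  Files
  round-trip exactly.

## Region filtering

Region boundaries are inclusive on both ends (1-based VCF convention).  A
multi-base variant is "inside" a window or feature iff its POS (left
anchor) is inside — the simplest rule that is consistent across modes.
`stream_filter` processes VCF/PLINK files record-at-a-time, so peak memory
is independent of input size; its output is contractually identical to the
in-memory filter and that equivalence is tested.

## ATG-as-zero coordinates

The anchor is the first base of the start codon: the smallest CDS start on
`+` genes, the largest CDS end on `−` genes.  Transform: `pos − anchor` on
`+`; `anchor − pos` on `−`, with the site order reversed so positions stay
ascending.  Alleles are *not* reverse-complemented — only coordinates
change — so transformed genotypes remain directly comparable with the
source VCF.  The transform is exactly invertible given the anchor.

## Haplotype network

Link weight is the Hamming distance between genotype vectors: each
differing site counts one mutation step regardless of allele length (a
2 bp indel is one step).  The primary links are a minimum spanning tree
built with Kruskal's algorithm under a fixed edge order — ascending
distance, then the lexicographically smallest name pair — so the edge list
is fully deterministic.  Non-tree edges no longer than the longest tree
edge plus `epsilon` (default 0: tree only) are reported as flagged
alternative links, giving the user control over ambiguous topologies.  An
MST is the simplest structure consistent with a mutation-step network; it
can differ from statistical-parsimony networks on topologically ambiguous
data, and no median (inferred ancestral) vectors are added.

## Linkage disequilibrium

After the default heterozygote removal every individual is homozygous, so
each contributes a single gamete and haplotype frequencies are observed,
not estimated (no EM).  Per site, alleles are collapsed to biallelic
major-vs-rest (majority allele, ties by string sort); multi-allelic sites
therefore keep a dense matrix at the cost of lumping minor alleles.  With
major-allele frequencies p_A, p_B and joint frequency p_AB:

    D  = p_AB − p_A p_B
    r² = D² / (p_A(1−p_A) p_B(1−p_B))
    D′ = |D| / D_max,  D_max = min(p_A(1−p_B), (1−p_A)p_B)   if D > 0
                       D_max = min(p_A p_B, (1−p_A)(1−p_B))  if D < 0

Individuals with a residual heterozygous or missing call at either site of
a pair are dropped pairwise, not listwise.  Monomorphic pairs are NaN; the
diagonal is 1 by convention.

## Phenotype comparison

Per haplotype group, trait values outside `[Q1 − 3·IQR, Q3 + 3·IQR]`
(bounds inclusive) are removed first.  Quartiles use linear interpolation
between order statistics (numpy's default, R's type 7) — a convention
declared here so the bounds are reproducible.  Note the rule is a single
screening pass, not an iterated trim: on heavily contaminated samples a
second application could remove further points, so the screen is applied
exactly once.  Groups with fewer than `min_members = 5` individuals *after*
removal are excluded (the conservative order).  Every remaining pair is
tested two-sided; the default is Welch's t-test, with Wilcoxon rank-sum as
an option — both are exposed because neither is canonical for this design.
Raw p-values carry the star annotation (* < 0.05, ** < 0.01, *** < 0.001),
and a Benjamini–Hochberg-adjusted column is always emitted alongside for
transparency.

## Geographic distribution

Accessions of the `top_n` most frequent haplotypes (default 4 — more makes
the pies unreadable) are grouped by (longitude, latitude), optionally
rounded to a configurable number of decimal degrees to bin nearby
collection points; accessions without coordinates are logged and skipped.
The map background is a bundled, hand-drawn schematic coastline
(`world_outline_synthetic.json`) — deliberately coarse, for orientation
only, and requiring no network access.

## Synthetic data generator

`generate_dataset` emulates a candidate-gene resequencing panel: distinct
binary allele vectors planted over biallelic SNPs in a two-exon gene model,
accessions assigned multinomially with skewed frequencies (probability
∝ 1/rank, mimicking the strongly uneven haplotype frequencies of real
germplasm panels), heterozygous and missing calls injected independently
per call at the requested rates (defaults 2%, typical of array/NGS panels),
and a trait drawn as `effect_size × haplotype_index + N(0,1)` so
`effect_size = 0` is an exact null.  Coordinates scatter over five fixed
collection sites; groups are uniform over the given labels.  The truth
record stores the realized partition and frequencies.

What it does *not* emulate: linkage structure along the gene (sites are
exchangeable), population structure or kinship between accessions,
genotype-calling error correlated across sites, or realistic indels.
Passing tests therefore demonstrate correctness of the algorithms under
clean, known conditions — not robustness to confounded real-world panels.

## Problem sizes and numerical choices

The test-suite and acceptance runs use deliberately small instances —
panels of 40–100 accessions over 5–10 sites, networks of ≤6 haplotypes
(where exhaustive spanning-tree enumeration is feasible as an oracle),
200-replicate null calibration with two groups of 30 — chosen so every
oracle can be computed exactly and the whole suite re-runs in seconds.
LD closed forms are asserted to 1e−12; the null rejection rate is accepted
inside the exact binomial 95% interval.  Degenerate inputs fail loudly:
empty tables, all-accessions-filtered, monomorphic sites (NaN in LD),
mixed-strand CDS for the ATG anchor, malformed streamed records (reported
with line numbers).

## Known limitations

* Grouping is exact-match only; a single discordant call splits a
  haplotype rather than fuzzy-merging (by design, but worth knowing).
* The network has no inferred median vectors, so long links are not
  decomposed.
* The LD estimator requires effectively phased (homozygous) input; panels
  with substantial residual heterozygosity lose those individuals
  pairwise.
* The geographic map is schematic; it is not a substitute for a GIS
  rendering.
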
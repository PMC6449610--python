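# Methods

This note describes the statistical model behind `histofold`, the parameters
it exposes, what the synthetic-data generator does and does not emulate, and
the numerical conventions used throughout.

## 1. Differential-region model

**Region universe.** Peaks from both conditions of one mark are pooled and
merged whenever the gap between consecutive peaks on a chromosome is at most
`max_gap` (default 1000 bp, boundary inclusive, matching BedTools
`merge -d` semantics). Merging is idempotent and order-independent; the
implementation is a single sorted sweep, verified in the test suite against
an O(n²) transitive-closure oracle.

**Counting.** A fragment is counted in a region if they share ≥ 1 bp,
ignoring strand. Regions passed to the counter must be disjoint (merged
regions always are); a fragment spanning two separate regions is counted in
both. Counting uses two `searchsorted` calls per region over per-chromosome
sorted fragment start/end arrays, so it is O((n + m) log m).

**Signal and classification.** Per region and condition:

```
RPKM   = count × 1e9 / (region_length × library_size)
signal = max(RPKM_IP − RPKM_INPUT, 0)
fold   = (signal₂ + pseudocount) / (signal₁ + pseudocount)
```

A region is *increased* when `fold > fold_threshold` (default 2, strict),
*decreased* when `fold < 1/fold_threshold`, otherwise *unchanged*. Replicate
fragment files per condition/role are pooled (counts and library sizes sum)
before RPKM.

The pseudocount (default 1 RPKM) is a design choice: it stabilises folds for
near-zero signals and makes the classification exactly antisymmetric under a
condition swap (`fold → 1/fold`), a property the acceptance tests assert. It
also means very weak absolute changes cannot reach the threshold, which is
intended.

## 2. Annotation

Each region is represented by its integer midpoint `(start + end) // 2`.
Categories, in precedence order:

1. **Promoter** — within ±3 kb (`promoter_halfwidth`) of any TSS; distance
   binned ≤1 kb / 1–2 kb / 2–3 kb.
2. **5′UTR**, **3′UTR** — midpoint inside an annotated UTR.
3. **Exon**, then **Intron** — inside the gene body.
4. **Downstream** — within 3 kb (`downstream_len`) past the TTS, in the
   gene's orientation.
5. **Distal Intergenic** — everything else.

When several genes qualify at the same precedence level, the gene whose TSS
is nearest to the midpoint wins; exact ties break to the lexicographically
smaller `gene_id`. A six-way summary collapses the two UTR categories into
one. The nine-row distribution table reports counts and percentages overall
and separately for increased/decreased regions.

**Nearest TSS / signed distance.** Distance is `midpoint − TSS` in the
gene's orientation: positive when the midpoint lies downstream of the TSS
(for a − strand gene, downstream means decreasing coordinates). TSS of a −
strand gene `[start, end)` is `end − 1`. Regions on a chromosome with no
genes get no assignment.

**TSS metaprofiles.** Fragment coverage in 100 bp bins over ±5 kb around
every TSS, orientation-flipped for − strand genes, converted to RPKM per bin
and averaged within high/low expression strata (threshold 10 on
rlog-like values). An empty stratum is omitted with a warning; genes missing
from the expression table are an error.

## 3. Expression integration

**DE filter.** `padj < alpha` (default 0.01, strict); direction from the
sign of `log2fc`; `log2fc == 0` or missing `padj` is non-significant;
`padj` outside [0, 1] is rejected.

**Region→gene assignment.** Each *differential* region is assigned to the
single gene with the nearest TSS. Per gene and mark, four flags are kept:
increased/decreased at any distance, and the same restricted to
`|distance| ≤ proximal_bp` (default 1000). Up-regulated genes are grouped by
their *increased* flags, down-regulated genes by their *decreased* flags,
into neither / mark1 only / mark2 only / both — a 2×4 table whose rows
partition the DE genes exactly.

**Association test.** For a focus gene set (by default, up-regulated genes
with a proximal H3K4me3 gain), per-gene mean expression is computed in each
condition and compared with a paired two-sided Wilcoxon signed-rank test
(`scipy.stats.wilcoxon`; exact null distribution when n ≤ 25 and the
differences are untied — with n = 20 all-positive untied differences the
two-sided p is exactly 2⁻¹⁹). At least two genes are required; identical
conditions yield p = 1 with a warning. A paired t-test is available as an
alternative.

**Expression stand-in.** Full DESeq2/rlog fitting is out of scope. The
stand-in computes median-of-ratios size factors over genes with no zero
counts, then `log2(count / size_factor + 1)`. It reproduces the two
properties the pipeline relies on: library-depth invariance and a roughly
log-scale dynamic range.

## 4. Synthetic-data generator

The generator produces, from a single seed, a complete study: a GTF of gene
models, per-mark/per-condition peak BEDs, IP and INPUT fragment BEDs, an
RNA-seq count matrix with a DE table, and a truth table.

What it emulates:

- **Genes.** `n_genes` (150) non-overlapping genes of 2–8 kb with 8–20 kb
  spacing on `n_chroms` (2) chromosomes of 3 Mb, three exons each, UTRs at
  the oriented ends. 15 % of genes are truly up, 15 % truly down.
- **Background fragments.** Poisson(`background_rate × chrom_length`)
  200 bp fragments per library, uniform placement — sequencing noise.
- **Enriched regions.** 120 regions of 0.8–1.5 kb per mark. Increased
  regions (40 %) get IP enrichment fold U(4, 8) in condition 2 only;
  decreased (20 %) the mirror image; the rest get an equal fold U(2, 6) in
  *both* conditions — peaked but unchanged, so false-positive rates are
  measurable. Extra IP fragments are Poisson(`rate × length × (fold − 1)`).
- **Peaks.** Emitted wherever a condition's fold exceeds 1, with the true
  boundaries jittered by ±200 bp — peak-caller imprecision.
- **Promoter coupling.** With probability 0.8 an up-regulated gene receives
  a dedicated H3K4me3 region within ≤ 1 kb of its TSS that gains (fold ≥ 4)
  in condition 2, tying the chromatin truth to the expression truth.
- **RNA counts.** Gamma-Poisson (negative binomial, dispersion 0.05) counts
  for 6 + 4 samples, mirroring an unbalanced two-stage design; `padj` values
  are drawn below/above `alpha` according to truth rather than fitted.

Geometric guarantees that keep the truth identifiable: same-mark regions are
≥ 1.5 kb apart at the edges, so ±200 bp jitter can never close a gap below
the 1 kb merge threshold and fuse two truth regions; non-coupled regions are
placed ≥ 3.5 kb from every TSS, so a promoter-proximal gain is always a
coupled region.

What it does **not** emulate: read-level artefacts (GC bias, duplication,
mappability), fragment-length variation, broad/composite peak shapes,
between-replicate variability in ChIP efficiency (replicates are i.i.d.
draws), or a fitted DE model (p-values are simulated from truth). These are
acceptable because the pipeline under test consumes peak and fragment files,
not reads.

## 5. Numerical conventions and degenerate inputs

- Coordinates are 0-based half-open internally; GTF (1-based closed) is
  converted at the I/O boundary, and round-trips exactly.
- Percentages in reports are computed with `decimal` ROUND_HALF_UP to one
  decimal place, so 50 % boundaries round up deterministically.
- Report TSVs are sorted (chromosome, start) and floats written with six
  decimals; `manifest.json` has sorted keys and no timestamps — identical
  seeds therefore give byte-identical report directories.
- Empty peak lists yield an empty region set (valid); empty fragment
  libraries for a non-empty region set are an error (RPKM undefined).
- Malformed BED/GTF lines raise errors naming the file and line number.
  GTF features whose `gene_id` has no `gene` record get a synthesized gene
  body (with a warning); a missing strand is an error.
- A fixed problem size is used for the recovery benchmark — 500 regions
  at fold U(4, 8), 30 genes, coupling off — chosen so that sensitivity and
  false-increase rate are estimated on ~200 regions each; the generator
  defaults above are the package's reference study conditions.

## 6. Limitations

Signal is background-subtracted RPKM with a fixed pseudocount rather than a
count-model test (no per-region p-values or FDR); classification depends on
the 2-fold threshold. Annotation uses only the region midpoint, so a long
region spanning a promoter and an exon is counted once. Region→gene
assignment is nearest-TSS only, which ignores long-range enhancer contacts —
a known simplification for H3K27ac. The Wilcoxon test treats genes as
independent paired observations and per-gene condition means discard
within-condition variance.
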
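# Methods

## The model and its assumptions

The question the package answers is positional: are family-labelled genes
overrepresented among the genes lying inside the QTL regions of a trait?
The sampling model treats the genome as a finite population of N unique
protein-coding genes, s of which carry the family label, and the trait's
merged QTL regions as a fixed subset containing n of those genes. Under
the null hypothesis of no positional preference, the number x of family
genes inside the regions is hypergeometric: the family labels are
exchangeable across genes, and each gene occurs exactly once, so the draw
is without replacement. This gives

    var(x) = (n·s·r/N²)·((N−n)/(N−1)),   r = N − s,

and the Wald statistic z = (x/n − s/N)/(√var(x)/n), compared two-sided to
the standard normal. No continuity correction is applied. An exact
hypergeometric tail (`exact_hypergeom_pvalue`) is available as a
cross-check of the normal approximation but is never part of the screen.

Assumptions worth spelling out:

- **Unique genes.** Both n and x count unique gene IDs; transcript-level
  redundancy must be collapsed before counting (the readers enforce unique
  IDs). Without this, the without-replacement model would be wrong.
- **Fixed regions, random labels.** The regions are conditioned on; only
  the labelling is modelled as random. Spatial clustering of family genes
  (tandem arrays!) violates label exchangeability and makes the test
  anticonservative for families with strong clustering — the test answers
  "are there more family genes here than a uniform scatter would give",
  not "…than a clustered scatter would give".
- **Normal approximation.** The z-to-normal step is accurate when the
  expected count n·s/N is not too small. At the default genome scale
  (N≈28k, s≈290) traits with n ≥ ~2000 genes are well calibrated at both
  α=0.05 and α=0.001; traits near n≈500–1000 (expected count 5–10) are
  mildly anticonservative in the far tail (exact two-sided size up to
  ~0.004 at nominal 0.001). The exact-tail cross-check is the recommended
  companion for small traits.

## Pipeline stages and their contracts

1. **Ingestion** (`genome_model`). All intervals become 0-based half-open
   at the I/O boundary; GFF3 and the QTL TSV are 1-based inclusive on
   disk, BED and the gene TSV are half-open. Genes sort by (chromosome,
   start, end, gene_id); the ID tie-break makes downstream rank-based
   computations deterministic. Families are disjoint labels carried on
   genes; a gene listed under two families is rejected.
2. **Merging** (`qtl_processing`). Per trait (never across traits), the
   QTL interval union: overlapping or bookended intervals coalesce (in
   half-open terms `a.end == b.start` leaves no gap, so bookended
   intervals merge). Regions overlapping zero genes are then dropped, and
   n is the unique-gene count over the survivors. A trait left regionless
   is flagged and skipped by the screen, not an error.
3. **Intersection** (`interval_overlap`). A gene belongs to a region iff
   the half-open intervals share ≥1 bp (`max(starts) < min(ends)`);
   abutment is not overlap. The linear sweep requires sorted input and
   raises on violations rather than re-sorting, because silent re-sorts
   would mask caller bugs in rank-sensitive code. The sweep is tested for
   exact agreement with the naive all-pairs check on randomized instances.
   Strand is ignored throughout. A gene overlapping several traits'
   regions counts for each trait independently.
4. **Screen** (`enrichment`). `alpha_corrected = alpha_single/n_tests`
   with `alpha_single` defaulting to 0.025 and `n_tests` defaulting to the
   number of non-degenerate trait tests (overridable, e.g. fixed at 25 to
   give the conventional p < 0.001 screen). The degenerate case n = N
   (regions tiling the genome) has SE = 0 and is flagged rather than
   reported as infinite z.
5. **Duplications** (`duplication`). Tandem: two same-family genes on one
   chromosome with ≤ `max_intervening` (default 10) other annotated genes
   strictly between them in rank order, chained transitively into maximal
   blocks; "intervening" counts genes of any family, since the definition
   is positional. Because rank gaps grow monotonically along a
   chromosome, components are exactly maximal chains of consecutive
   same-family genes — the implementation exploits this; tests verify it
   against an all-pairs union-find oracle. Segmental pairs come from a
   precomputed table; Ks ≤ 1.0 is retained (strictly older pairs are
   discarded), then pairs must touch ≥1 family gene.
6. **Reports** (`report`). Chromosome density keeps full precision
   internally and rounds only at the table layer (1 decimal for
   family-gene shares, 2 for genome shares; `combined_share` sums at the
   printed precision, with the family-share sum rounded to an integer).
   Trait coverage deliberately counts **original database QTLs**, not
   merged regions — "4 of 5 QTLs contain a lectin" is a statement about
   catalogue entries — while the screen uses merged regions; a
   `use_merged` switch exposes the other convention.

## The synthetic-data generator

`simulate.generate` emulates exactly the structure the model assumes.
Genes are placed per chromosome as non-overlapping intervals (log-normal
lengths, mean 2.5 kb, σ_log 0.7; exponential inter-gene gaps scaled to the
chromosome length), so rank order is well defined. QTLs are placed per
trait with log-normal lengths (default mean 2 Mb) on chromosomes chosen
proportional to length. Family labels are then assigned to genes by
sampling without replacement: genes never move, so the gene content of
every region is fixed and x is the only random quantity. With all
placement weights at 1 the labelled set is a uniform subset — making x in
any fixed region exactly hypergeometric, the null of the test. A weight
λ > 1 on a trait multiplies its region genes' chances of receiving a
label (successive weighted draws), planting enrichment.

Tandem arrays are planted as runs of same-family genes with intra-array
rank gaps ≤ `intra_gap_max` and guard zones of `inter_gap_min` ranks that
exclude other labels of the same family, so the planted partition is
recovered exactly by the detector; duplicate-pair Ks values are uniform on
[0, 2] by default, spanning the 1.0 cutoff. One integer seed drives five
named `SeedSequence` child streams (genes, QTLs, tandem, labels, Ks), so
output files are byte-identical across runs.

`paper_replica_config` pins the genome-scale study conditions: 27,912
genes on the 12 IRGSP-1.0 chromosome lengths, 291 family genes across nine
families (GNA the largest at 135, LysM at 20, …), and 25 traits over the
four trait categories with 4–30 QTLs each — a realistic spread for a
curated QTL catalogue, giving merged trait contents of roughly 600–4,500
genes.

What the generator does **not** emulate: sequence content, real gene
density heterogeneity (clustering of genes in euchromatin), spatial
clustering of family members outside planted arrays, correlated QTL
placement across traits beyond what random overlap produces, and
transcript-level redundancy. Consequently, passing calibration here shows
the statistic is correct under its own model; it does not certify the
exchangeability assumption on a real genome, where tandem clustering is
the norm for lectin families.

## Validation studies (`calibration`)

Because labels move and genes do not, the null/alternative distribution of
x is studied by redrawing only the labelling over a genome generated once.
`null_calibration` pools ≥2000 trait-level tests under uniform labels and
compares the two-sided rejection count to the binomial acceptance region;
`planted_power` measures the detection rate of a λ=3 trait (~3,500 genes)
at the corrected threshold over 500 redraws. One subtlety: in the planted
configuration, other traits' regions share genomic territory with the
enriched trait's regions, so those traits genuinely contain up-weighted
genes and are *not* null — the λ=1 rejection rate is therefore measured
under uniform redraws on the same genome and trait set, the literal λ=1
condition.

## Numerical and design choices

- Coordinates: 0-based half-open everywhere internally; conversions only
  at I/O. Ties in gene coordinates break by gene_id.
- Chromosome names sort naturally (chr2 before chr10); the sweep engine
  only requires per-chromosome contiguity, not any particular chromosome
  order.
- Merging treats bookended intervals as one region (no base lies between
  them); this is the only defensible choice under half-open arithmetic
  and is applied consistently.
- `n_tests` is a parameter rather than always-auto because the number of
  tests a study "performed" can legitimately include traits that were
  later dropped; both conventions are one flag apart.
- Ks = 1.0 survives the age filter (only strictly greater is discarded);
  10 intervening genes link a tandem pair, 11 do not. Both boundaries are
  asserted in the acceptance suite.
- Degenerate inputs: empty QTL list per trait → error (not analyzable);
  trait regions with genes but no family genes → retained with x = 0;
  regionless traits after filtering → flagged skip; n = N → degenerate
  result excluded from the screen.

## Problem sizes

The test suite and the acceptance script run the genome-scale studies at
27,912 genes with 2,000 simulated trait tests for calibration and 500
redraws for power; the million-draw variance check uses 10⁶ hypergeometric
draws per sample size. These sizes keep the full validation under a minute
on one CPU while leaving the binomial acceptance regions narrow enough to
detect miscalibration of a few tenths of a percent.

## Known limitations

- The screen inherits the normal approximation's far-tail optimism for
  small traits; use the exact tail for n below ~1000 at strict levels.
- Trait labels are treated as exact strings; synonym collapsing must be
  supplied via the `trait_vocabulary` mapping at read time.
- Segmental duplication detection is out of scope — pairs are consumed,
  not inferred from synteny.
- The per-family × per-trait matrix is reported descriptively; the screen
  tests traits (all families pooled or one family at a time), and no
  FDR-style alternative to Bonferroni is offered.
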
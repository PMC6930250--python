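# Methods

## Scope and model

`mitosrna` analyses small-RNA-seq libraries against a circular
mitochondrial reference. The unit of analysis is the *unique sequence*
(15–27 nt after adapter removal), not the read: libraries are collapsed to a
sequence × library count matrix, and every downstream statement (alignment,
annotation, differential expression, clustering) is made about sequences.
A sequence is a mitosRNA iff it matches the mitochondrial genome with 100%
identity on either strand; no mismatches, gaps or NUMT (nuclear
mitochondrial pseudogene) screening are modelled, which is appropriate for
an error-intolerant exact-match regime and a curated reference, and is a
known limitation for real data with sequencing errors.

Coordinates are 0-based half-open on the heavy strand internally, with
GFF3's 1-based closed intervals converted at the I/O boundary. The heavy
strand is defined as the reference FASTA's forward strand and the light
strand as its reverse complement — a documented convention, since different
references orient the molecule differently. Circularity is handled by
searching the genome extended by the first `m − 1` bases (m = query
length), so origin-wrapping placements are found exactly once and reported
with `end > genome length`.

## Preprocessing

1. **Adapter trimming** removes everything from the leftmost position where
   a prefix of the adapter of ≥ `min_overlap` (default 6) nt matches the
   read through its end. Matching is exact; reads containing ambiguous
   bases are dropped with a logged count rather than resolved.
2. **Size selection** keeps 15–27 nt inclusive.
3. **Collapsing** produces the raw count matrix.
4. **Low-abundance filtering** keeps sequences with a summed raw count
   ≥ `min_total` (default 10) across libraries. The original analyses in
   this field rarely print their cutoff; 10 is a conventional choice and is
   configurable.
5. **Normalization** uses median-of-ratios size factors over the rows
   positive in every library; when no such row exists (pathological,
   usually tiny, inputs) the code falls back to column-total scaling with a
   warning. Normalization is scale-equivariant and leaves within-library
   proportions unchanged.

In the assembled pipeline, retention of genome-aligned sequences sits
between collapsing and the abundance filter, so the abundance filter and
size factors see only sequences that belong to the reference universe
(mitochondrial genome plus any decoy/nuclear contigs in the FASTA).

## Catalog and enrichment

Each hit is annotated by per-base feature membership. The overlap classes
are: `single_feature` (every base inside exactly the one feature — a
zero-extension allowance, so even a 1-nt protrusion into intergenic
sequence makes the hit `overlapping_features`, with `intergenic` recorded
as a pseudo-feature), `overlapping_features` (≥ 2 features and/or
intergenic bases), and `intergenic` (no feature at all). This reproduces
catalog tables in which the intergenic column is populated only for
overlapping rows. Multi-mapping sequences keep all placements but count
once in summaries via the primary hit (lowest heavy-strand start, heavy
before light on ties); a per-locus mode was considered and not built, as
toy and real mitochondrial genomes rarely multi-map at 15–27 nt.

Feature-type columns count each overlapped type once per sequence, so type
columns of overlapping rows can sum to more than the row count. Enrichment
compares the fraction of cataloged sequences touching each type against
the fraction of genome bases covered by that type, with a two-sided exact
binomial test per type and BH correction across types.

## Differential expression

The model is a per-sequence negative binomial with variance μ + αμ².
Dispersion is estimated by moments on normalized counts, pooling the
within-group variance across all treatment groups with ≥ 2 replicates:
α̂ = max(0, (v − m)/m²). The Wald statistic for each treatment-vs-t0
contrast is log₂FC/SE, where log₂FC = log₂((μ̂_b + c)/(μ̂_a + c)) with
pseudocount c = 0.5 (finite fold changes at zero counts) and the SE comes
from the delta method with Var(μ̂_g) = (μ̂_g + α̂μ̂_g²)/n_g. P-values are
two-sided normal, adjusted by Benjamini–Hochberg within contrast, with
NaNs (untestable rows) passed through. A sequence is called DE when its
mean normalized count across all of the stage's samples exceeds 25 and
some single contrast has |log₂FC| > 2 with padj < 0.01 — all strict, and
a sequence is DE overall if flagged in at least one stage.

This is a deliberately transparent simplification of the shrinkage-based
NB pipelines common in the field: no dispersion trend, no LFC or dispersion
shrinkage, no independent filtering. Correctness is therefore claimed via
planted-truth recovery on synthetic data (sensitivity, empirical FDR, and
null type-I control are part of the test suite), not via replication of
any particular tool's output on real data. Pairwise Wald contrasts against
t0 are the default reading of a "response to anoxia and recovery" design;
an omnibus test across treatments was considered and left out because the
per-contrast fold changes are what the heatmap and probe-design steps
consume.

Heatmap values are v_ij = log₂((x_ij + c)/(rowmean_i + c)) on normalized
counts — each sample relative to the sequence's mean across all samples —
with missing samples kept as missing.

## tRF profiling

- **Coverage** sums each sequence's normalized counts (over the selected
  samples) into every base of a feature window it covers; the window is
  the feature ± 5 nt flanks (configurable) so upstream/downstream
  extensions are visible, indexed 5′→3′ in the feature's own orientation.
- **End classes** use a tolerance τ = 2 nt (matching the planted jitter
  and the granularity at which upstream extensions are typically reported):
  a fragment whose 5′ end is within τ of the feature's 5′ end while its 3′
  end is not within τ of the feature's 3′ end is `five_prime`; symmetric
  for `three_prime`; both within τ → `full_length`; neither → `internal`.
  Light-strand features are handled by computing distances in the
  feature's orientation, making classification invariant to flipping a
  feature and reverse-complementing its reads.
- **Clustering** of heatmap rows is Lloyd's k-means with k-means++ seeding,
  Euclidean distance, 20 restarts and a fixed seed, with k = 3 by default
  (the number of broad expression patterns typically reported); missing
  values are imputed as 0 with a logged note.
- **Probe design** finds the longest substring common to all members of a
  fragment group (ties broken by the leftmost occurrence in the first
  sequence; members are passed in sorted order so the result is
  input-order free) and reports its reverse complement as the probe. The
  search enumerates substrings of the first sequence longest-first, which
  is complete because any common substring is a substring of the first
  member. Probe chemistry (LNA positions, melting temperature) is out of
  scope.
- **mitosRNA fraction** is the summed normalized count of mito-flagged
  sequences over that of all sequences within a sample group; its Pearson
  correlation against per-stage traits (anoxia LT₅₀, metabolic rate) uses
  the t transform with n − 2 df and requires ≥ 3 stages. Trait values are
  user-supplied — they come from physiological measurements, not from the
  sequencing data.

## Synthetic data

The generator emulates the study design end to end. `make_toy_genome`
places 5 tRNA (60–75 nt), 2 rRNA (120–180), 3 mRNA (150–250), one D-loop
(120–160) and one origin (30–40) feature on a random 2 kb circle with
random intergenic gaps, ~30% of tRNAs and ~20% of mRNAs on the light
strand — a miniature of the real gene-class layout. `plant_fragments`
expands each fragment group into 1–5 variants anchored at the declared end
(3′ variants all terminate at the feature's 3′ end and extend 0–jitter nt
upstream of the shared core, so every variant contains the core by
construction), with per-condition expected counts base_mean · 2^lfc.
`simulate_libraries` draws NB counts per variant per library
(α = 0 → Poisson; an exact-mean mode bypasses sampling), adds uniform
background reads from a 5 kb random decoy contig (so the genome-retention
and mito-subsetting steps are exercised), appends a fixed 12-nt adapter
(the first 12 nt of the TruSeq small-RNA 3′ adapter; real adapters vary
and the choice is arbitrary) and truncates to a 34-nt read length.

Defaults mirror the study conditions: 4 stages (D2, WS36, WS40, WS42) ×
5 treatments (t0, EA, LA, ER, LR) × 3 replicates (replicate depth is not
something these publications print; 3 is conventional for small-RNA-seq),
planted anoxia-induced 3′ tRNA fragments with |log₂FC| = 4 at long anoxia,
base mean 200 normalized counts and dispersion 0.1, plus null groups as
false-positive bait. The simulator has no sequencing-error model, no
quality-score realism and no NUMT contamination, so passing tests
demonstrate correct inference under the declared generative model, not
robustness to real-library artefacts.

The test suite and examples run the pipeline on a 2-stage × 5-treatment ×
3-replicate design with 100 background reads per library, and the DE
calibration studies use 1 000 sequences × 15 samples × 20 repeats — sizes
chosen so the whole suite completes in well under a minute of compute per
study while keeping Monte-Carlo standard errors small relative to the
margins being asserted.

## Numerical and degenerate-input choices

- BH adjustment enforces monotonicity by the running minimum from the
  largest p-value down and passes NaNs through untouched.
- All-zero rows (within the stage being tested) are excluded before
  dispersion estimation; rows with fewer than 2 replicates on either side
  of a contrast get NaN p-values but still report fold changes.
- `exact_align` of a query longer than the genome returns no hits; empty
  catalog subsets summarize to zero counts with percentages reported as
  0.0 and an explicit empty flag; enrichment on an empty catalog is an
  error.
- A degenerate probe core (no shared substring) is returned with length 0
  and flagged rather than raised, since downstream reporting can carry it.
- Pipeline outputs are staged in a `.partial` directory and moved into
  place on success, so failed runs leave no partial bundle; failures are
  re-raised tagged with the stage that produced them.
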
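# Methods

## Problem and model

`regulink` predicts which gene a conserved noncoding element (CNE) most
likely regulates, using only comparative genomics. The premise: functional
enhancer–target interactions are under negative selection against
rearrangements that would separate the pair or stretch the distance beyond
what *cis*-regulation tolerates. A CNE that stays within a bounded distance
of the same gene across many independently rearranged genomes is therefore
likely to regulate it, while genes that drift away in a substantial fraction
of lineages are likely bystanders.

The evidence model treats species as (approximately) independent witnesses.
For CNE *i* and candidate gene *g* in species *e*, exactly one status holds:
linked within the scaled radius (S1), present on the same chromosome beyond
it (S2), present on another chromosome or scaffold (S3), or not annotated
(S0). Two species-level covariates temper each witness:

- **R_e, synteny level** — the fraction of reference-adjacent gene pairs
  that remain direct neighbours in *e* (computed over the analysed gene
  set; 1 for the reference against itself, 0 when every ortholog is
  isolated). A genome that has barely rearranged cannot distinguish
  selection from inertia, so its S1 evidence is weighted by (1 − R_e).
- **C_e, coverage factor** — trust in absence calls. Low-coverage draft
  assemblies lose and mis-annotate genes, so their S0/S2/S3 penalties are
  scaled down by C_e (default mapping: finished/high-coverage 1.0, ~2x
  draft 0.5; any value in [0, 1] may be supplied in the species table).
  Over-fragmented assemblies can be excluded outright with a flag.

The raw linkage score is the sum of per-species weights (S1: +(1 − R_e);
S2: −0.5·C_e; S3: −1.0·C_e; S0: −0.25·C_e). The magnitudes of the three
penalties are the package's own calibration: broken-but-same-chromosome
linkage (S2) is weaker negative evidence than relocation to another
chromosome (S3), and absence (S0) is weakest because it frequently reflects
annotation failure rather than biology. All weights are configurable
(`LinkageWeights`); any scheme preserving the sign structure and the
S3 < S2 < S1 monotonicity yields the same rankings in the regimes the tests
cover. Raw scores are normalised to S_A ∈ (0, 1) with a sigmoid
1/(1 + exp(−k(raw − m))), k = 1 and m = the median raw score of the run —
strictly monotone, so ranking, tie structure and target selection do not
depend on the constants. Floating-point saturation at the extremes is
clipped back into the open interval.

Target selection keeps *all* families attaining the maximal S_A (ties are
real: regulatory blocks often hold bystander genes that never break away).
The relative score is the gap between the best and second-best *distinct*
S_A; with a single candidate it is undefined (reported as missing), and
with all candidates tied it is 0.

## Scanner

The scanner operates in alignment-column space, one block at a time; blocks
are syntenic units and are never stitched. Masked columns (exon or repeat
overlap, or a reference gap) are hard boundaries. A column is conserved iff
at least `min_species_beyond_ref` (7) non-reference species are aligned and
the substitution count is at most ceil(0.12 · n) with n the aligned rows
including the reference — at the 7-species minimum exactly one substitution
is allowed. Elements seed from 10-column windows with ≥ 9 conserved
columns (strictly overlapping windows union into one seed), extend outward
across non-conserved runs of at most 3 columns, stop at a longer run, a
masked column or the block edge, and are trimmed to conserved end columns.
An extended interval is kept only if a qualifying core window still fits
inside it. Fusion of same-species-set elements closer than 100 bp on the
reference additionally requires the two elements to be consecutive in every
shared species (no third called element between them); fusion is transitive
and idempotent.

Percent identity for the conservation score counts matches over columns
where both the reference and the species are non-gap, rounded to the
nearest integer before taking the per-group maximum; identities are scored
on the post-fusion element. A species belongs to an element's species set
if it is aligned (non-gap) over at least half of the element's columns.

Equivalence with a deliberately naive scalar enumerator (per-column
counting, exhaustive window scan, step-by-step extension walk) is asserted
over 1,000 random alignments of up to 1 kb in the acceptance suite.

## Functional overlap and enrichment

An element overlapping a signal peak by ≥ 1 bp scores the peak value
weighted by the covered fraction of the element, additively over peaks
(linear in peak values and invariant to splitting a peak into abutting
parts). A fused element overlaps a track iff any constituent CNE scores
positive. Enrichment curves use equal-count quantile bins of S_A (default
10; duplicate quantile edges collapse when scores tie heavily); empty bins
report a missing proportion rather than 0, and the fold change compares the
extreme bins, undefined when the bottom proportion is 0. Binning within
conservation strata is supported so the S_A–enrichment relationship can be
examined controlling for conservation.

## Interaction consistency

An element overlapping (≥ 1 bp) any anchor of a promoter-anchored
interaction pair is consistent when its best-target set intersects the set
of genes interacting through those anchors. The permutation null redraws,
per element and resample, k genes (its observed best-target count, capped
at the window size) uniformly **without replacement** — a gene set, not a
multiset, is compared — from all genes in a 2-Mb window centred on the
element. The reported bound is p = (r + 1)/(n_resamples + 1) with r the
number of resamples reaching the observed consistency count; when r = 0 the
result is additionally reported as p < 1/n_resamples. Per-element RNG
streams derive from (seed, CRC32(element_id)), so subsetting or reordering
elements never shifts other elements' draws and results are bit-identical
at a fixed seed. On small cases the null count distribution matches the
analytic Poisson-binomial with per-element match probability
1 − C(g−m, k)/C(g, k).

Because the count statistic is discrete and ties are counted as "reached",
the p-value is slightly conservative (super-uniform); the calibration check
in the acceptance suite uses enough elements and resamples that the
discreteness sits below the resolution of a Kolmogorov–Smirnov test at
2,000 draws.

## Synthetic data generator

The generator emulates exactly the statistical structure the score relies
on, with everything else kept minimal:

- **Geometry.** One reference chromosome, 60 genes at 200-kb spacing
  (12.2 Mb), 80 CNEs placed uniformly in intergenic space; half the CNEs
  are true enhancers assigned a target gene within 0.4 Mb. All coordinates
  and lengths sit on a 20-bp grid and per-species genome-size factors on a
  0.05 grid in [0.80, 1.00], so species coordinates are *exact* scalings of
  the reference: a gene inside the 1-Mb reference radius is inside the
  scaled radius of every unrearranged species, with no boundary jitter.
- **Rearrangement.** Each species draws Poisson(rate · genome Mb) events
  (inversions 60%, translocations to a new scaffold 20%, segment moves
  20%) with a default rate of 6 events/Mb — calibrated so that non-target
  genes lose linkage to a CNE in well over 30% of species, the regime in
  which conserved linkage is informative, while synteny levels spread over
  roughly 0.2–0.6. An event that would separate a protected
  enhancer–target pair (different chromosome, or beyond the radius) is
  undone and redrawn; protection lapses per species with probability 0.01
  (rare fixed violations).
- **Annotation dropout.** Gene loss probability 0.002 + 0.04·(1 − C_e);
  three species are ~2x drafts with C_e = 0.5. True targets of deeply
  conserved elements are rarely genuinely lost, and dropout concentrates
  in drafts, where the C_e correction absorbs it.
- **Sequence.** Alignment blocks cover each planted element with 40-bp
  flanks. Substitutions are i.i.d. per column at group-specific identities
  (0.98/0.95/0.92/0.88/0.82 inside elements, 0.55 in flanks) with 1%
  deletion gaps. The scanner consumes columns, not evolutionary realism —
  no indel model, no rate heterogeneity, no CpG effects.
- **Signals.** Peaks land on true enhancers with probability 0.9 and on
  background CNEs with probability 0.05 (uniform values 2–20); interaction
  pairs link 60% of true enhancers' elements to their targets' promoters.

What passing tests on this generator show — and what they do not: the
pipeline provably recovers planted structure under the stated noise model
(rearrangement, dropout, divergence), and every summary statistic is
re-derivable from the emitted standard-format files (`audit`). Real
alignments add alignment error, lineage-specific rate variation, segmental
duplication and annotation idiosyncrasies that the generator deliberately
omits, so recovery rates here bound what clean data allows, not what messy
data delivers.

Problem sizes throughout (60 genes, 80 CNEs, 20 species; 1,000 oracle
alignments; 2,000 calibration draws at 499 resamples) are chosen so the
full suite runs in minutes on one core while keeping every statistical
check well-powered.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; MAF start/size pairs are
  converted on read, BED-family formats pass through, and 1-based
  inclusive converters are provided.
- Negative-strand MAF rows keep native coordinates; conservation is
  evaluated in reference-column space, so strand never enters the scanner.
- CNE–gene distance is the closest-edge gap (0 when overlapping); "within
  the radius" is a strict inequality.
- With paralogs, the most favourable status applies — one preserved copy
  suffices to preserve regulation.
- H (the gene-pair total behind R_e) counts adjacent pairs within the
  analysed chromosome set.
- `merge_external` unions intervals over base positions, so book-ended
  intervals merge (as `bedtools merge` does); core-window seeding unions
  only strictly overlapping windows, since adjacent windows are joined by
  extension anyway.
- Degenerate inputs: empty interval files parse to empty lists; inverted
  records are rejected with a warning and counted, not fatal; an ortholog
  table referencing unknown species fails fast listing offenders; H = 0
  and non-positive genome sizes raise.

## Known limitations

- The exact published combination of status terms and sigmoid constants is
  not reproduced; the implemented scheme is a monotone-equivalent default
  with every constant exposed in configuration.
- The scanner calls elements within single alignment blocks only; elements
  spanning block boundaries in a fragmented alignment will be split.
- `R_e` uses annotated ortholog order, so assembly fragmentation deflates
  synteny estimates for otherwise conserved genomes — the C_e/exclusion
  machinery, not R_e, is the intended mitigation.
- The permutation null treats elements independently; spatially clustered
  elements sharing a window are resampled without dependence.
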
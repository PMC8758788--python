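# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention); GFF3 is
converted on read (1-based inclusive → half-open). One convention
everywhere removes the off-by-one class of bugs that plagues interval
code. Strand is carried but ignored by all overlap logic — LAD and DR
analysis is strand-agnostic. Chromosome names are taken verbatim from
input; no "chr" prefix normalization is attempted.

## DamID log-ratio

The lamina-contact signal is `log2((f·s_f + c)/(d·s_d + c))` per DpnI
(GATC) fragment, with fusion counts `f`, Dam-only counts `d`,
library-size scaling factors `s` that equalize the two track totals
(default on), and pseudocount `c = 1` read (default). Fragments with
zero counts in both tracks carry no information and are masked (NaN)
rather than imputed; with `c = 0` a zero denominator also masks the
fragment (never ±inf) and the mask count is surfaced as a warning.
Masked fragments never contribute to bins or segment means.

## Binning

Segmentation runs by default on fixed 2 kb bins of the fragment track
(`PipelineConfig.bin_size`; set-up also supports fragment-level input).
Bin values are per-base averages of the piecewise-constant fragment
track, i.e. fragment values weighted by the bases they contribute to the
bin. Rationale: at ~20 reads/fragment the per-fragment log-ratio noise
is ~0.8; averaging ~8 fragments brings it to ~0.3 against a planted LAD
step of 1.5, and an O(n²)-per-split segmentation on ~1000 bins per
2 Mb chromosome keeps the full four-condition analysis near a minute.
The trade is boundary resolution: called LAD edges are quantized to
~one bin, which is why downstream size filters (min DR size 5 kb)
deliberately exceed the bin size.

## Segmentation (CBS)

Per chromosome, recursive circular binary segmentation: among all arcs
`(i, j]` with both arc and complement at least `min_width` points
(default 2), take the arc maximising
`|mean(arc) − mean(rest)| / sqrt(1/k + 1/(n−k))`; accept the induced
breakpoints when a within-segment permutation test on the same max-arc
statistic gives `p = (exceedances+1)/(n_perm+1) < alpha`, then recurse
into the pieces (left to right, depth first — deterministic for a given
seed). Defaults: `alpha = 0.01`, `n_perm = 1000`. The sample scale
cancels between observed and permuted statistics, so the statistic is
left unstandardised by the variance. The permutation loop stops early
once enough exceedances have accrued to make rejection certain, which
makes the common "no further split" case cheap. The hot scan is
numba-compiled when numba is importable, with an equivalent vectorised
numpy fallback; both are checked against an exhaustive O(n²) scan in the
tests. An arc and its complement carry the same statistic and the same
cuts; ties between them are resolved by scan order and are immaterial.

At `alpha = 0.01` the per-segment false-split rate is ~1%, giving ≥95%
exactly-recovered three-segment profiles at noise σ = 0.2 over 100
replicates (asserted in tests). No post-hoc breakpoint pruning is
performed; the acceptance alpha is doing that job.

## LAD calls and metrics

Segments with mean log-ratio above 0 (the sign convention of
log2(fusion/Dam) makes 0 the natural contact threshold) become LAD
candidates; candidates separated by under `merge_gap = 5 kb` are merged
— LADs are defined over genomic space, so short data gaps or masked
runs do not split them — and merged candidates under
`min_lad_size = 10 kb` are dropped, matching the scale of mammalian
LADs. Metrics per condition: LAD count, % genome coverage, median size,
mean log-ratio inside vs outside (the last pair sanity-checks the sign
convention: inside must exceed outside).

## Differential regions and edge classes

For conditions A → B: `PI = merge(A \ B)` (periphery → interior, LAD
lost) and `IP = merge(B \ A)` (LAD gained), each filtered at
`min_dr_size = 5 kb`. The filter's purpose is to absorb segmentation
jitter: two independently segmented conditions disagree by about one
bin at shared LAD edges, producing slivers ≪ 5 kb that are not biology.
Edge classes for PI DRs are decided against the containing A-LAD within
`edge_tol` (default 256 bp, one mean fragment): equal to it →
whole_lad_loss; strictly interior → internal_loss; touching one end →
truncation. IP DRs abutting an A-LAD are expansions, otherwise de-novo
LADs. Because the printed per-LAD and per-DR denominators are both
defensible for "fraction truncated/expanded", the summary reports both.

"Retention" of an A-LAD in B is operationalised as reciprocal overlap
≥ 0.5 with some single B-LAD — a definition chosen here (none is forced
by the data) and exposed as `min_reciprocal_overlap`.

## Paralog specificity

Deviations of the single-knockdown and double-knockdown landscapes from
the wild-type adipocyte landscape are symmetric differences, size
filtered as DRs. Each connected affected region is classified:
single-KD deviation matching the double-KD deviation with Jaccard ≥ 0.5
("no further change when both paralogs are lost") → a-unique; deviation
present only in the double knockdown → b-unique; otherwise mixed. The
Jaccard threshold is a design choice exposed in config and recorded in
the output provenance block. Affected units may alternatively be
annotated loci (a flag), since a region- vs locus-based count is a
genuine ambiguity.

## Positional classes and knockdown dependence

A locus overlapping a PI DR by ≥1 bp is released, an IP DR recruited
(double overlap → larger side, flagged ambiguous); a non-overlapping
locus within `proximity_window = 5 kb` is proximal — kept as a distinct
class because promoter-adjacent recruitment without gene-body overlap
is a real regulatory mode. A normally released locus still overlapping
a knockdown-condition LAD fails to release under that knockdown; a
normally recruited locus absent from knockdown LADs fails to recruit.
Flags are evaluated independently per knockdown and only on
released/recruited loci.

## Expression filters and concordance

The package consumes a DE table from any upstream tool and implements
only post-fit filters: |log2FC| ≥ 0.5 (1.4-fold, boundary inclusive),
adjusted p < 0.05, and — where an intensity is present — intensity
≥ 6.5 on the log2 scale. The record schema carries one intensity value
per locus; a per-sample minimum rule cannot be expressed in it and is
out of contract. Concordance cross-tabulates released/recruited against
up/down/ns; loci absent from the DE table count as ns and are reported.

## miRNA qPCR stage

Step 1: per plate, ΔCt = Ct − geometric mean of the housekeeping Cts on
that plate (geometric mean computed on the Ct values directly; Ct is
already a log-scale quantity, and the choice is documented because no
canonical definition exists). Step 2: quantile normalization across
plates — each plate's sorted values are replaced by the across-plate
mean of order statistics; plates with missing wells map through
fractional ranks against the mean quantile curve, ties average, missing
values stay missing. Housekeeping rows are the reference, not assays:
they keep their plate-normalized ΔCt and do not enter the quantile
step or the ranking. Per assay, a plain two-sided two-sample t-test
(unmoderated; variance moderation would need shrinkage settings that
cannot be pinned down) on knockout vs control ΔCt; ΔΔCt =
mean(KO) − mean(control), fold change `2^(−ΔΔCt)`; rank ascending by p
with ties broken by |ΔΔCt| then assay id. Selection is the union of
rank ≤ ceil(0.15·n) and fold ≥ 2 or ≤ 0.5 (boundaries inclusive). Raw p
is used for ranking (an adjusted-p column is a one-liner away but the
ranking contract is raw). Quantile normalization compresses extreme
planted effects toward the bulk (the reference curve averages shifted
and unshifted plate minima), so recovered fold changes for planted
2.8-fold assays land around 2–2.8; recovery is therefore measured as
planted assays entering the selected set with the right direction.

## Phenotype computations

Stress-test traces: phases are delimited by the injection times
(basal | oligomycin | FCCP | rotenone+antimycin A); phase summaries are
means of all measurements in the phase (median available). Parameters
follow the standard arithmetic: non-mito = rot/AA floor; basal and
maximal are floor-subtracted; ATP-linked = raw basal − raw oligomycin
(raw-phase arithmetic — the wording "drop in OCR following oligomycin"
pins the minuend to the raw basal phase, and the identities
proton_leak = basal − ATP-linked then hold exactly by construction);
spare capacity = maximal − basal. Negative ATP-linked or proton leak is
returned flagged, not clipped. Pyruvate dependency is the per-parameter
difference vehicle − UK5099. GTT AUC is the trapezoid over the sampled
grid (0, 15, 30, 60, 120 min in the standard protocol). Droplet areas
bin left-closed right-open with an open-ended last bin and sub-first-
edge values in the first bin, so counts conserve n; per-animal
frequencies then aggregate as group mean ± SEM. FISH distances compare
by unpaired two-sided Student's t (pooled variance default, Welch by
flag) with a Tukey box summary (whiskers at the most extreme points
within 1.5·IQR).

## Synthetic data: what it emulates, and what it does not

The generator is a pure function of (spec, seed). Defaults define the
study conditions: a 3 × 2 Mb genome tiled into geometric-length GATC
fragments (mean 256 bp, min 4 bp, boundaries snapped to fragments); 10
LADs per chromosome at 44% coverage, one purpose-built 30 kb LAD per
chromosome serving as a whole-LAD-loss candidate; differentiation
changes totalling 3.9% of the genome lost (3 whole-LAD deletions, 10
edge truncations, 2 off-centre 10 kb internal holes) and 4.1% gained
(10 edge expansions, 4 de-novo 30 kb LADs), leaving retention at 0.90
by construction; knockdown reversions planted with paralog structure
(6 a-unique, 9 b-unique, 4 mixed events; mixed events revert 40% in the
single knockdown so their planted Jaccard of 0.4 sits clear of the 0.5
decision line); 100 genes (20 released with exactly 35%
knockdown-dependent, 10 recruited, 6 proximal at 3 kb offsets, the rest
far from any DR), 45 enhancers (30 recruited, 10 of them
knockdown-dependent), 8 miRNA loci; expression tables in which exactly
10% of repositioned genes change concordantly plus three decoys that
each fail exactly one DE filter; a Ct matrix of 12 up + 9 down planted
miRNAs (|ΔΔCt| = 1.5) among 300 nulls and 4 housekeeping assays over
5+5 plates; OCR traces from phase means (100, 40, 150, 10) with σ = 3;
FISH distances and GTT curves from separated group distributions.
Counts are negative binomial (mean 20/fragment, size 10) with a +1.5
log2 fusion enrichment inside LADs; `noise_free=True` replaces sampling
with deterministic means for exactness tests.

Loci are placed with ≥2.5 kb margins from event boundaries so that
~1-bin segmentation jitter cannot flip a positional class; this is a
property of the planted geometry, chosen from the known bin size, not a
tuning against observed failures.

Not emulated: mappability/GC bias, replicate structure, Hi-C-style
compartment correlations, fragment-level count correlation, read-level
errors, plate-position effects. Passing tests therefore demonstrate
correctness of the computations and recoverability under the stated
noise model — not robustness to artefacts real DamID data can carry.

## Problem sizes and tolerances

The default synthetic analysis (4 conditions × 3 chromosomes × ~1000
bins, n_perm = 1000) runs in about a minute with numba; the test suite
shares one analysed bundle (noisy) plus one noise-free bundle across
tests. Planted-truth recovery is asserted at: LAD coverage ±2
percentage points, % genome lost/gained ±0.5 points, knockdown-
dependent fraction exact on the noise-free spec, planted-LAD Jaccard
≥ 0.9. Numerical ties in selection and ranking all have deterministic
tie-breaks (documented above) so repeated runs are bit-identical for a
fixed seed.

## Known limitations

- No replicate model or per-DR significance: the DR caller is a set
  difference of point estimates, as in the source protocol.
- Boundary placement is bin-quantized; sub-bin edge precision requires
  fragment-level segmentation (supported, slower).
- Quantile normalization attenuates large planted qPCR effects (see
  above); fold-change-based selection alone under-recovers, which is
  why the procedure's union with rank selection matters.
- The per-base bitmap oracle and exhaustive CBS scans bound test
  genomes/tracks to small sizes; correctness at scale rests on the
  algebraic identity of the implementations, not on big-input tests.
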
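# Methods

## Coordinate model

Feature coordinates are 1-based inclusive (GFF convention) on the rCRS
mitochondrial reference (L = 16,569). Cleavage is localised to *junctions*:
the bond between positions `s−1` and `s`, written as the integer `s` with
valid range [2, L]. A fragment "processed at `s`" either starts at `s` or
ends at `s−1`; the two stack modes are pooled. The genome is treated as
linear — there is no wrap-around junction at 1/L, and the control region
(which spans the origin in reality) absorbs the artificial break: junctions
upstream of MT-TF or downstream of the last annotated gene classify as
control region.

## Fragment reconstruction

Short reads: fragments are rebuilt from the leftmost mate of each properly
paired, uniquely mapped pair as the outer span `[POS, POS + TLEN − 1]`, so
the unsequenced inner gap counts as covered. "Uniquely mapped" is
operationalised as MAPQ equal to the aligner's unique value (default 255,
STAR's convention; configurable, or disabled). Duplicates are retained; both
strands are pooled. Pairs with TLEN = 0 and fragments running past the contig
end (circular-origin pairs) are skipped and tallied in a QC dictionary.

Long reads: one fragment per primary alignment with MAPQ strictly above 30,
the end taken from the reference-consuming CIGAR span. Reads with
supplementary segments elsewhere in the mitochondrial genome (SA tag) are
removed. Removing reads with an equal-or-better nuclear alignment requires a
caller-supplied read→MAPQ table, because a single-contig stream cannot
self-detect nuclear hits; when the table is absent the filter is skipped with
a warning.

## Event counting and the cleavage ratio

Per junction: `n_start[s]` (fragments starting at `s`), `n_end_before[s]`
(ending at `s−1`) and `n_span[s]` (start ≤ s−1 and end ≥ s). The three are
mutually exclusive per fragment and sum to the junction's coverage. Counting
is linear-time via start/end histograms and prefix sums; tests verify exact
agreement with a brute-force per-fragment enumeration.

`ratio[s] = (n_start + n_end_before) / coverage`, undefined (NaN, never 0)
at zero coverage so that presence filters can distinguish no-signal from
no-data. The ratio is a *proxy* for the cleavage rate, not an estimate of
it: under the generator below, a per-molecule cleavage probability f yields
an expected ratio of roughly `2f / (1 + f)` (each cut molecule contributes
two processed fragments; only uncut molecules span). The tested contract is
monotonicity in f, not identity.

## Discovery

Per sample, candidate junctions have ratio > 0.1 at ≥ 20× coverage. The
cohort union of detections is clustered transitively within 5 bp and each
cluster is represented by its highest-ratio junction (cohort-mean ratio;
ties to the lower coordinate). A sample "has" a peak if any cluster member
was detected in it; presence is computed over samples with a defined ratio
at the representative junction, with a 50% default threshold. Detection
before merging, and presence counted on cluster membership, is the reading
of the procedure most consistent with requiring a peak to be present in at
least half the cohort; the thresholds are applied per sample, not to a
pooled cross-sample mean.

## Boundary regions and the background model

Each selected gene contributes a 5′ junction (`start`) and a 3′ junction
(`end + 1`). Two gene-end junctions describe the same boundary region when
one falls within the other's ±3 bp window; the merged region is anchored at
the downstream gene's 5′ junction. On the packaged annotation this gives
exactly 28 distinct mRNA/rRNA boundary regions: the 1-bp-overlapping
MT-ATP6/MT-CO3 pair and the abutting MT-ND5/MT-ND6 pair each collapse to a
single region, while gene pairs with widely separated ends — including the
overlapping MT-ATP8/MT-ATP6 (46 bp apart) and MT-ND4L/MT-ND4 (7 bp apart)
pairs — retain two distinct internal boundaries. An alternative rule that
collapses *every* overlapping pair to one junction was considered and
rejected: it merges regions that are biologically and positionally distinct
and yields 26.

The background model pools, over samples and 100 random junctions more than
50 bp from every boundary window, the maximum defined ratio within ±3 bp of
each junction (mirroring the boundary peak extraction, for comparability).
Each boundary is tested with a one-sided Welch t-test (per-sample window
peak ratios vs the pooled background) at α = 0.05 / 28. Welch rather than
pooled-variance because the two pools differ greatly in size and variance.
When both inputs are exactly constant the t statistic is undefined; by
convention p = 0 if the boundary mean exceeds the background mean and p = 1
otherwise, with a warning — this only arises on degenerate synthetic input.

Site classification precedence: exact boundary junction > within 10 bp of a
boundary window > containing feature (smallest feature wins on overlaps).
The class set is closed (boundary/near-boundary/mRNA/rRNA/tRNA/control
region), so junctions in the few short inter-gene gaps (e.g. the WANCY
cluster spacers) take the nearest gene's biotype; this keeps classification
total over all L−1 junctions.

## Validation rules

* Replication: a discovery site replicates if an independent cohort's site
  list (same parameters) has a junction within a match window (default 0,
  exact).
* Ribo-depleted rule: validated if *any* sample's ratio exceeds 10% at *any*
  junction within 3 bp.
* Long-read rule: read start/end counts are pooled per position; positions
  with ≥ 200 supporting reads **and** in the top 1/50 of all L positions
  (ties at the quantile kept, zero-support positions included in the
  denominator) are transcript termini; a site is validated when a terminus
  lies within 3 bp of either base flanking the junction. Before this
  comparison, sites within 3 bp of the strand-aware interval 10–15 bp
  downstream of any gene's 5′ end are masked, because direct-RNA nanopore
  sequencing truncates mitochondrial transcripts there.
* Overall: ribo-depleted OR (unmasked) long-read.

## Association statistics

`linear_association` is OLS of ratio on predictor plus covariates and an
intercept (statsmodels), with the slope's two-sided p and `min(1, p·m)`
Bonferroni adjustment; genotypes enter as additive dosages 0/1/2 so QTL
mapping is the same operation. Cross-cohort intersection keeps pairs
significant after correction in both cohorts with the same sign of effect.

Mediation uses the product-of-coefficients estimator: a from `M ~ X (+C)`,
b from `Y ~ X + M (+C)`, ACME = a·b, with a percentile bootstrap over
individuals (default 1000 resamples) for the CI and a two-sided bootstrap
tail probability for p. The bootstrap inner loop uses normal-equation OLS in
numpy for speed; point estimates are cross-checked against statsmodels in the
tests. Under the complete null (a = b = 0) the percentile interval of a
product is conservative — measured rejection ≈ 0.2% at nominal 5% over 500
replicates — so the calibration tests assert coverage at least nominal and
rejection at most α, and power/recovery under true mediation.

The knock-down comparison is a one-tailed Welch t-test (default direction:
knock-down < control).

## Synthetic data generator

Per sample, `depth` full-length polycistronic molecules span [1, L]. Each
molecule is cut independently at each truth junction with its cleavage
probability f (cleavage before fragmentation, the biological order). Each
resulting molecule is chopped left-to-right into fragments with lengths drawn
from a normal distribution clipped to bounds (defaults: mean 180 bp, sd 40,
min 50, max 400 — a typical 100 bp paired-end library); a sub-minimum
trailing remnant is merged into the last fragment so molecule termini are
always represented. Expected coverage at every junction is therefore ≈ depth.
Fragments can be emitted as properly paired SAM (MAPQ 255, POS/TLEN
consistent with extraction, reads sorted by coordinate) and round-trip the
short-read extractor exactly. The long-read profile generator tallies the
terminal positions of cleaved molecules directly.

Cohorts layer a dosage model (`f = base + β·dosage + noise`, clipped to
[0, 1], dosage ~ Binomial(2, maf)), a toy expression matrix, standard-normal
covariate ("PEER-like") columns, and an X→M→Y mediation chain, and write all
sidecar TSVs plus a truth JSON.

What is *not* modelled, and what that implies: polyA selection (the
real cohorts' libraries were polyA-enriched; any resulting site-level bias is
invisible to these tests), sequence-dependent fragmentation bias (e.g.
AT-rich breakpoints that could create reproducible artefacts), RNA
degradation, sequencing error, and nanopore truncation mechanics (the
truncation mask is exercised with synthetic termini, not a mechanistic
model). Passing tests therefore demonstrate correctness of the inference
machinery under idealised random fragmentation, not robustness to these
real-data artefacts. One generator-specific artefact is worth noting: because
chopping proceeds left-to-right from each molecule terminus, the first
breakpoint's distance is distribution-concentrated, producing a faint "echo"
wave downstream of true termini; at the default fragment geometry it stays
near the ~2% background and an order of magnitude below the detection
threshold.

## Problem sizes and numerical choices

The heavier simulation checks use cohorts of 20 samples at 300× with five
planted sites across ten seeds, 2000-replicate null calibrations for the
t-test and OLS, and 500-replicate bootstrap-mediation calibrations with 200
resamples each — sizes chosen to keep Monte-Carlo error around the asserted
tolerances (3σ binomial bands). Background SD uses ddof = 1. Peak ties break
toward the lower coordinate everywhere. All stochastic operations accept
either an integer seed or a numpy Generator and reproduce byte-identical
outputs under a fixed seed.

## Known limitations

Reported site coordinates follow this package's junction convention (the
bond index equals the first base of the downstream fragment); coordinates
reported by other tools may be offset by one. Strand-aware counting is
not implemented beyond pooling (an explicitly documented simplification —
the ratio definition is strand-agnostic). Circular-origin read pairs are
dropped rather than unwrapped. The cleavage ratio saturates (`2f/(1+f)`)
and compresses differences at high f; comparisons across samples at a site
are meaningful, absolute rates are not.
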
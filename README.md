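# mitocleave

Inference of human mitochondrial RNA cleavage sites and per-sample cleavage
rates from standard RNA-seq data, by exploiting read-end "stacking".

## The problem

The human mitochondrial genome (rCRS, 16,569 bp; 13 mRNAs, 22 tRNAs, 2 rRNAs)
is transcribed as long polycistronic RNA that must be cleaved — largely at the
tRNAs that punctuate the transcript — to release functional gene products.
Library fragmentation during RNA-seq cuts RNA at essentially random
positions, but the genuine 5′/3′ termini of transcripts present in the sample
are shared across many molecules, so aligned read ends pile up ("stack") at
true cleavage positions. `mitocleave` turns that signal into a per-junction
statistic, discovers and validates cleavage sites across cohorts, and relates
per-sample cleavage rates to genotype and gene expression. It is intended for
researchers analysing bulk (or pooled single-cell) RNA-seq cohorts with
mitochondrial coverage.

## The statistic

Coordinates are 1-based; a *junction* `s` is the bond between reference
positions `s−1` and `s`. From properly paired, uniquely mapped reads, each
fragment is reconstructed as the outer mate span `[POS, POS + TLEN − 1]`.
At junction `s`, with

- `n_start[s]` — fragments starting exactly at `s`,
- `n_end[s]` — fragments ending exactly at `s−1`,
- `n_span[s]` — fragments covering the bond without ending at it,

the **cleavage ratio** is

```
r(s) = (n_start[s] + n_end[s]) / (n_start[s] + n_end[s] + n_span[s])
```

i.e. the processed fraction of all fragments across the site. Candidate sites
are junctions with `r > 0.1` at ≥ 20× coverage, merged within 5 bp (keeping
the highest-ratio junction as the peak) and retained when present in ≥ 50% of
samples. Gene boundaries are tested against an empirical background (peak
ratios at 100 random junctions > 50 bp from any boundary) with one-sided
Welch t-tests, Bonferroni-corrected for the 28 mRNA/rRNA boundaries.
Downstream, cleavage ratios serve as quantitative traits: OLS association
with expression or genotype dosages (with covariates such as PEER factors),
cross-cohort intersection requiring a consistent direction of effect,
percentile-bootstrap mediation (ACME = a·b), and one-tailed knock-down
comparisons.

A synthetic-data module generates polycistronic cohorts with known
site-specific Bernoulli cleavage, random fragmentation and paired-end SAM
output, so the whole pipeline is testable without controlled-access data.

## Worked example

Simulate a 10-sample cohort with cleavage planted at two real junction
coordinates — 4263 (the MT-ND1/MT-TI boundary) and 9207 (the tRNA-less
MT-ATP6/MT-CO3 boundary) — then discover and classify sites:

```python
import numpy as np
from mitocleave import (SimulationTruth, simulate_sample, count_site_events,
                        compute_ratio_track, cross_sample_filter, load_annotation,
                        enumerate_boundaries, classify_site, sample_background_sites,
                        estimate_background, boundary_test)
from mitocleave.site_discovery import sites_to_frame

truth = SimulationTruth(sites=[(4263, 0.55), (9207, 0.45)], depth=300)
rng = np.random.default_rng(7)
tracks = [compute_ratio_track(count_site_events(simulate_sample(truth, f"S{i:02d}", rng)))
          for i in range(10)]
sites = cross_sample_filter(tracks)

genes = load_annotation()
boundaries = enumerate_boundaries(genes, ("mRNA", "rRNA"))
for s in sites:
    s.classification, s.boundary_distance = classify_site(s.junction, genes, boundaries)
print(sites_to_frame(sites).to_string(index=False))
```

```
 junction  representative_ratio  presence_fraction  mean_coverage classification  boundary_distance provenance
     4263              0.706897                1.0          464.2 exact_boundary                  0  discovery
     9207              0.625179                1.0          436.5 exact_boundary                  0  discovery
```

Both planted junctions are recovered exactly, in every sample, and classified
as exact gene boundaries. The representative ratio exceeds the per-molecule
cleavage probability because every cut molecule contributes two processed
fragments (one ending, one starting) but only uncut molecules span the bond:
with cleavage probability f the expected ratio is roughly `2f / (1 + f)`.

Testing the MT-ATP6/MT-CO3 boundary against the genome-wide background:

```python
background_sites = sample_background_sites(boundaries, n=100, min_dist=50, rng_seed=7)
background = estimate_background(tracks, background_sites)
print(f"background mean={background.mean:.3f} sd={background.sd:.3f}")
atp6_co3 = next(b for b in boundaries if b.junction_site == 9207)
res = boundary_test(atp6_co3, tracks, background, n_boundaries_for_correction=28)
print(f"MT-ATP6/MT-CO3 boundary: t={res.t:.1f} p={res.p:.3g} significant={res.significant}")
```

```
background mean=0.023 sd=0.008
MT-ATP6/MT-CO3 boundary: t=97.7 p=2.86e-15 significant=True
```

The random-fragmentation baseline sits near 2%, far below the planted signal.

The same operations are exposed as a CLI:

```bash
mitocleave simulate -o sim/ --n-samples 10 --seed 7
mitocleave ratios sim/S000.fragments.tsv -o S000.ratios.tsv
mitocleave discover *.ratios.tsv -o sites.tsv
mitocleave run --config run.yaml
```

## Layout

- `mitocleave.annotation` — rCRS gene table / GFF loading, boundary regions,
  site classification, background sampling
- `mitocleave.fragment_ends` — SAM/BAM fragment-end extraction (short & long
  read), per-junction event counting
- `mitocleave.cleavage_ratio` — the ratio track
- `mitocleave.site_discovery` — detection, peak merging, presence filter,
  background model, boundary tests
- `mitocleave.validation` — cohort replication, ribo-depleted and long-read
  validation rules, nanopore truncation masking
- `mitocleave.association` — OLS association, Bonferroni, cohort
  intersection, bootstrap mediation, knock-down comparison
- `mitocleave.simulate` — the synthetic cohort generator
- `mitocleave.pipeline` / `mitocleave.cli` — orchestration and the
  `mitocleave` command

See `docs/methods.md` for the model, parameter choices and limitations.
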
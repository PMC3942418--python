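# microttr

Temporal turnover analysis for microbial community time series, built around
the kind of year-long monthly 16S surveys run on activated-sludge
bioreactors. Given a samples × taxa OTU count table, a taxonomy map and a
table of environmental/operational covariates, the package answers three
questions a microbial ecologist asks of such a series:

1. **How fast do taxa turn over?** The taxa–time relationship (TTR) models
   observed richness *S* as a power law of the observation window *T*,
   *S = cT^w*; the exponent *w* (slope of the log–log regression) measures
   temporal turnover, computed for the whole community and per phylum, with a
   contrast between the *k* most abundant ("dominant") and *k* rarest phyla.
2. **How fast does the fingerprint drift month to month?** Moving-window
   analysis: the percent change between consecutive months is
   100 · (1 − *r*), with *r* the Pearson correlation of adjacent
   relative-abundance profiles; its mean ± SD is the monthly change rate Δt.
   A Sørensen presence/absence similarity matrix is exported for ordination.
3. **What explains the variance?** Canonical correspondence analysis (CCA,
   implemented from the chi-square eigen-formulation), Monte-Carlo forward
   selection of covariates, and variance partitioning of explained inertia
   among wastewater (W), operational (O) and reactor-scale (S) covariate
   groups.

Upstream utilities cover read QC (drop sequences with more than one
ambiguous base or shorter than 150 bp), seeded rarefaction to a common
library size (multivariate hypergeometric subsampling), rank collapsing and
per-rank richness summaries. A seeded synthetic generator
(`microttr.synthetic_data`) emulates the study design — 12 monthly samples
per reactor at 13 422 reads, ~15 phyla with a strongly skewed abundance
distribution, persistent dominant-phylum taxa vs transient rare taxa, and a
seasonal temperature partially coupled to composition — so every stage is
testable without sequence data.

## Worked example

The numbered scripts under `analysis/` run the whole study design on
synthetic data:

```bash
python analysis/01_simulate.py --seed 1      # two reactors -> results/data/
python analysis/02_richness.py --seed 1
python analysis/03_ttr.py --seed 1
python analysis/04_moving_window.py --seed 1
python analysis/05_ordination.py --seed 1
```

`03_ttr.py` prints, for seed 1:

```
full: w = 0.366, c = 1040.2, r^2 = 0.985 (sliding windows)
  dominant mean w = 0.174 < rare mean w = 0.660
lab: w = 0.395, c = 994.5, r^2 = 0.973 (sliding windows)
  dominant mean w = 0.202 < rare mean w = 0.683
```

The full-scale reactor (higher taxon persistence) turns over more slowly
than the lab-scale reactor (*w* 0.366 < 0.395), and dominant phyla turn over
more slowly than rare ones — the two qualitative signatures the analysis is
designed to detect. `04_moving_window.py` shows the same ordering in the
monthly change rate (Δt 31.4 % ± 14.8 % for full vs 42.6 % ± 16.4 % for
lab), and `05_ordination.py` selects the seasonal temperature covariate
(p = 0.002 at 499 permutations) and partitions explained inertia among the
W/O/S groups.

The same steps run on real data by pointing the scripts (or
`microttr.run_pipeline`) at your own tab-separated count, taxonomy and
covariate tables; see the format notes in `microttr/community_io.py`.

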
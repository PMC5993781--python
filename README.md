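# gutdyn

Analysis pipeline for longitudinal infant gut microbiota cohorts: given
near-daily OTU counts from a dozen infants across the first year of life,
it quantifies how strongly age structures each infant's community, whether
the infants' microbiotas converge on one another as they mature, when that
convergence accelerates, which taxa drive it, and which infants share
phylum-level dynamics. It is written for microbial ecologists working with
dense 16S time series; because such cohorts ship as raw sequence archives
behind heavyweight upstream pipelines, the package includes a first-class
synthetic-cohort generator so every stage is testable at desk scale.

## What it computes

- **Normalization** — common scaling: counts c in a library of size L
  become round(c·S/L) with S the smallest library size; relative
  abundances, rank aggregates, prevalence spectra, Shannon diversity.
- **Beta diversity** — Bray–Curtis, Σ|x−y|/Σ(x+y), and generalized UniFrac,

      d = [Σ_b L_b (p+q)^α |p−q|/(p+q)] / [Σ_b L_b (p+q)^α],  α = 0.5,

  with branch masses p, q accumulated in one post-order traversal.
- **Ordination & inference** — Kruskal nMDS (stress-1, own
  pool-adjacent-violators core), one-factor PERMANOVA (pseudo-F, R²,
  seeded add-one permutation p), OLS axis-vs-age regression, and fixed-df
  cubic B-spline smooths (df = 9) with analytic 95% bands.
- **Convergence** — each infant's series interpolated to 365 pseudo-days
  with an fmm-end-condition cubic spline (negatives clipped, compositions
  renormalized); all pairwise contemporaneous distances; per-infant and
  grand means; the accelerated-convergence window read off the smoothed
  grand mean's derivative; taxon–convergence correlations; a Welch t-test
  comparing twin-pair to twin-to-other distances.
- **Trajectory clustering** — normalized DTW (symmetric2 step pattern, no
  warping window, /(n+m)) between infants' raw phylum series, averaged
  over the four dominant phyla, clustered by complete linkage with newick
  export.

See `docs/methods.md` for the model, parameter meanings, and numerical
choices.

## Worked example

The numbered drivers under `analysis/` run the full study on a simulated
cohort and write tables under `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_temporal_structure.py
python analysis/03_convergence_window.py
python analysis/04_phylum_clustering.py
```

Output (seed 1):

```
cohort: 2777 samples, 150 OTUs, 12 infants -> results/cohort
axis-1 vs age: mean R2 = 0.95 (range 0.92-0.97); age is the main structuring factor within every infant
PERMANOVA by infant: R2 = 0.23 (BC) / 0.21 (gUniFrac), p = 0.001 for both: infants remain individually distinct despite the shared dynamics
excluded late starters: ['ID8'] (11 infants retained)
grand-mean distances decline over the year (slope -4.31e-04/day, R2 = 0.65, p = 5.7e-85)
accelerated convergence window: pseudo-days 24-91
top-20 OTUs hold 46.0% of abundance; strongest in-window anticorrelation: OTU1 (Bifidobacterium), r = -0.97 - the bloom drives convergence
twins: mean pair distance is 0.27 lower than twin-to-others (Welch t = -69.1, p = 0.0e+00)
first (tightest) merge: ['ID10', 'ID11'] at height 0.0134 - the planted twins track each other
```

Reading this: each infant's first ordination axis is essentially a clock
(R² ≥ 0.92), yet infants stay individually distinguishable (PERMANOVA
R² = 0.23, the smallest possible p at 999 permutations). The cohort's mean
contemporaneous Bray–Curtis distance falls through the year, fastest over
pseudo-days 24–91 while the planted *Bifidobacterium*-like bloom rises
(correlation −0.97 inside the window), and the simulated twin pair is both
far closer to each other than to anyone else and the tightest merge of the
DTW dendrogram.

The same stages are scriptable via the `gutdyn` CLI (`simulate`,
`normalize`, `distance`, `ordinate`, `permanova`, `converge`,
`dtw-cluster`; every subcommand takes `--seed` where randomness occurs and
`--log-level` for timestamped stderr logs).

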
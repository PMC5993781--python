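# Methods

`gutdyn` analyses longitudinal infant gut microbiota cohorts: an OTU count
table over near-daily stool samples from ~12 infants across the first year
of life, with sample metadata (infant, day of life), a taxonomy map, and a
rooted phylogeny over the OTUs. Because raw sequence data and the upstream
bioinformatics (read processing, OTU picking, tree inference) are out of
scope, a synthetic-cohort generator provides inputs with the statistical
structure the analyses assume, including planted signals whose recovery the
test suite checks.

## Normalization

Library sizes are equalized by common scaling: every count c in a library
of size L becomes round(c · S/L), with S the smallest library size in the
table (overridable). This reproduces the expectation of infinitely repeated
rarefaction without discarding reads. Rounding is half-away-from-zero —
"round to the closest integer" does not fix the half case, so we state one;
halves are measure-zero in practice. Relative abundances are plain row
normalizations; taxon aggregates sum feature columns within a rank, keeping
"unclassified" as its own column. OTU prevalence is assessed on the
*unscaled* counts (scaling can erase singletons). Shannon diversity is
reported in nats.

## Beta diversity

Bray–Curtis: Σ|x−y| / Σ(x+y). Generalized UniFrac over a rooted tree with
branch lengths: with p, q the fractions of each community descending from a
branch,

    d(x, y) = Σ_b L_b (p+q)^α |p−q|/(p+q)  /  Σ_b L_b (p+q)^α ,

summing over branches with p+q > 0 (branches carrying no mass lie outside
the formula's domain and enter neither sum). α = 1 is the abundance-weighted
normalized form; the pipeline default α = 0.5 moderates the dominance of
abundant lineages. Branch masses are accumulated once per tree in a
post-order traversal (a branch × OTU indicator table), so a 365-point
profile over 55 infant pairs costs one matrix product per infant rather
than per-pair tree walks; tests verify equivalence against a brute-force
per-branch enumeration on an independently parsed tree. Trees whose root
has exactly three children are treated as unrooted serializations and
midpoint-rooted (with a logged warning); higher-degree roots are genuine
polytomies and kept.

## Ordination and inference

Non-metric MDS follows Kruskal: initialize from classical (metric) scaling,
then alternate (i) monotone regression of configuration distances onto the
rank order of the dissimilarities — our own pool-adjacent-violators
routine, with ties in the dissimilarities broken by the current
configuration distances (the "primary" tie approach, favouring
monotonicity) — and (ii) a Guttman majorization step, accepted only if
Kruskal stress-1 does not increase (step halving otherwise, so stress is
non-increasing across accepted iterations). Coordinates are centered, axes
ordered by variance, and the sign of each axis fixed so its correlation
with sample index is non-negative; downstream regressions report R², which
is sign-invariant. Stopping: relative stress change < 1e-7 or 300
iterations.

PERMANOVA: SS_total = (1/n)Σ_{i<j} d²; SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²;
pseudo-F = (SS_among/(a−1))/(SS_within/(n−a)); group labels are permuted
uniformly with a seeded generator and the p-value uses the add-one
convention (1 + #{F* ≥ F})/(1 + n_perm), so p is never exactly 0 and has
resolution 1/(n_perm+1) (1/1001 at the conventional 1000 permutations). The
permutation inner loop is jitted (a pure-Python fallback remains), which
keeps 999 permutations over ~2,800 samples near 10 s on one CPU.

Smooth trends use an *unpenalized* cubic B-spline regression with a fixed
number of basis functions (df, default 9; df ≥ 4 is required for a cubic
basis), interior knots at quantiles of the distinct predictor values, and
analytic pointwise 95% bands from the OLS covariance. This plays the role
penalized additive models usually play, but with the smoothness pinned by
df the fit is deterministic and exact for cubic polynomials; R² is reported
the same way (1 − RSS/TSS).

## Pseudo-day interpolation

Each infant's composition series is interpolated feature-by-feature with a
cubic spline using the Forsythe–Malcolm–Moler end conditions (the boundary
third derivative comes from the exact cubic through the four points at each
end), evaluated at 365 equally spaced pseudo-days spanning that infant's
own [first, last] sampled day. Tests verify the coefficients against R's
`stats::spline(method = "fmm")` to machine precision, and exactness on
global cubics. Duplicate-day samples are averaged before fitting; at least
4 distinct days are required. Negative interpolated values are clipped to
zero and each grid row renormalized to sum 1 — distances on unnormalized
clipped vectors would be inconsistent across metrics. Interpolation
operates on relative abundances, since every downstream quantity is
relative. A `grid="calendar"` option evaluates at integer days 1–365
instead (extrapolating with the boundary cubics) for sensitivity checks;
the per-infant grid is the default because near-full-year coverage makes a
pseudo-day ≈ a calendar day while guaranteeing equal-length series.

Infants whose sampling begins on or after day 54 are excluded from the
convergence analysis (they cannot contribute to the early pseudo-days);
the generator plants one such infant by default to exercise the rule.

## Convergence profile and window detection

At each pseudo-day the distance between every unordered infant pair is
computed; per-infant means (mean distance to all others) and their grand
mean summarize cohort-level similarity. The three aggregation levels agree
by construction to 1e-12 and the identity is asserted on every simulated
cohort. The grand mean is fitted with the 9-df smooth; the *convergence
window* is the maximal contiguous run of grid points containing the
derivative's argmin on which the fitted derivative stays below
`slope_fraction` (default 0.1) × the most negative derivative — i.e. at
least 10% of the steepest descent. The window is absent when the profile
never descends. Two numerical guards: (i) the search is restricted to
interior grid points (3% trimmed at each end) because the spline derivative
is one-sided and variance-inflated at the boundary; (ii) the detector is a
design of this package — the study it emulates read its window off a fitted
curve by eye — so `slope_fraction` and df are exposed. At df = 9 the
detected window edges carry an uncertainty of roughly one knot spacing
(~10–15 days for a 70-day feature), which is why cross-seed recovery is
asserted to ±15 pseudo-days.

The overall convergence trend is an OLS of the grand mean on pseudo-day
index. Taxon–convergence correlations are Pearson correlations between a
feature's cohort-mean abundance and the grand-mean distance across the
in-window pseudo-days (cohort means rather than per-pair values; the
alternative reading is noted in output headers). Features with zero
in-window variance are reported missing with a warning.

## Twin similarity

Sample 1 is the 365 pseudo-day distances between the twins; sample 2 pools,
for each twin, the per-pseudo-day mean distance to all non-twin infants
(2 × 365 values). A one-sided Welch t-test asks whether the twin-pair
distances are smaller. The pseudo-days are autocorrelated, so the nominal
sample size is optimistic and the p-value should be read qualitatively —
a caveat inherited from treating grid points as observations.

## Trajectory clustering

Dynamic time warping uses absolute-difference local costs and the
symmetric2 step pattern, D(i,j) = min(D(i−1,j)+c, D(i,j−1)+c,
D(i−1,j−1)+2c) with D(1,1) = c(1,1) and no global path constraint; the
normalized distance divides by n+m, the normalization this step pattern
admits ("normalized to series length" does not fix a formula; /(n+m) is the
standard choice and is configurable in spirit via the raw distance also
being returned). DTW runs on the raw observed per-infant phylum series —
unequal lengths are DTW's purpose — and the infant × infant matrix is the
arithmetic mean over the four dominant phyla (Actinobacteria,
Bacteroidetes, Firmicutes, Proteobacteria), restricting to taxa present in
all individuals. The inner recursion is jitted.

Complete-linkage agglomeration merges the pair of clusters with the
smallest maximum pairwise distance; ties are broken by the lexicographically
smallest pair of cluster ids so the merge sequence is deterministic.
Heights are non-decreasing (asserted), and the dendrogram exports to newick
with branch length = parent merge height − child merge height.

## The synthetic cohort

The generator emulates, per infant i, OTU o, day t ∈ 1..365, with
τ = (t−183)/182:

    logit(i,o,t) = base(o) + shared_slope(o)·τ
                   + g(t)·[static(i,o) + wiggle(i,o,t)]
                   + bloom(o)·exp(−(t−c)²/(2w²)),

compositions being the softmax over OTUs. The pieces and their defaults:

- **base(o)**: log(phylum fraction / phylum size) + N(0, 1.2). Phylum
  fractions default to the dominance structure of real first-year cohorts
  (Bacteroidetes 0.325, Actinobacteria 0.162, Firmicutes 0.356,
  Proteobacteria 0.156 after renormalizing the published 0.323/0.161/
  0.354/0.155 means, which sum to 0.993 because minor phyla are dropped).
- **shared_slope(o)** ~ N(0, 1.5), clipped at ±2 sd: a cohort-wide
  developmental drift, making age the main structuring factor within every
  infant. The clip matters: an unbounded tail draw would concentrate every
  infant's year-end composition on one OTU and collapse distances there.
- **static, wiggle**: each infant's persistent offsets ~ N(0, 1.2) and a
  natural cubic spline through independent N(0, 1.2) knot draws every 30
  days (knots extend past day 365 so the terminal interval is regular) —
  autocorrelated, stationary individuality without a Gaussian-process
  dependency.
- **g(t) = (1−r) + r·exp(−(t−1)/120)** with r = 0.5: individual components
  decay by half over the year with a 120-day timescale. This is what makes
  contemporaneous distances decline overall; the decelerating form mirrors
  real profiles (decline early, flatten late) and avoids a spurious
  year-end collapse that a linear decay produces through the saturating
  distance scale.
- **bloom**: a Gaussian bump (center day 95, half-width 35, peak boost 3.5
  logits) on the designated Actinobacteria OTU ("OTU1", genus
  *Bifidobacterium*), shared by the cohort; softmax renormalization
  depresses all other taxa inside the window, including a compensatory
  Firmicutes decline. The bloom OTU's baseline is structural
  (log-fraction + 2.0) rather than drawn, its shared slope is zero (the
  bump *is* its shared dynamic), and it carries only half of each infant's
  idiosyncratic noise — a cohort-coherent physiological response. No
  quantitative effect size exists to copy for the bloom; these values are
  arbitrary by design and chosen once so the planted window is a clear,
  recoverable feature.
- **Sampling**: days included independently at rate 0.65 within each
  infant's own [first, last] range (first ∈ 1–9, last ∈ 352–365; one
  infant, "ID8", starts at day 54), ~224 samples/infant. Library sizes are
  log-normal with mean ≈ 1,642 reads and CV 0.33 — the field cohort's
  164,215 ± 54,438-read libraries scaled down ×100 for desk-scale runtime;
  `SimulationConfig.paper_scale()` restores 1736 OTUs and full-size
  libraries. Counts are Dirichlet-multinomial with concentration 200 ×
  latent composition (visible but not overwhelming overdispersion).
- **Twins**: "ID10"/"ID11" share one latent draw plus independent N(0,
  0.25) knot/static noise. A `strong_trend()` preset (shared drift 2.5,
  individuality 0.8) exaggerates temporal structure for sensitivity
  checks.

Everything is deterministic given the seed (independent seeded streams for
tree, latent, and sampling). *Planted ground truth*: the convergence window
implied by the generator is defined as the window the detector finds on the
noise-free latent compositions themselves; recovery tests compare windows
detected from sampled counts against this planted window's midpoint (±15
pseudo-days over seeds). The Gaussian bloom's *peak* day is not that
midpoint — distances fall while the bloom rises, so the descent is centred
near center − half-width.

What the generator does **not** emulate: sequence-level artefacts (chimeras,
primer bias), antibiotic perturbations as a mechanistic process, travel or
diet covariates, taxon interactions/competition beyond compositional
renormalization, and phylogenetic signal in the *dynamics* (the tree only
groups phyla into clades). Passing recovery tests therefore show the
pipeline recovers structure of this planted kind at realistic noise and
sampling density — not that real cohorts contain such structure.

## Problem sizes and runtime choices

Default analyses run on the desk-scale cohort (12 infants, 150 OTUs,
~2,800 samples): the full test suite completes in ~2 minutes and the
acceptance script in ~1 minute on one CPU. The generalized-UniFrac
PERMANOVA in the analysis drivers and acceptance script uses every 3rd
sample (~930), a size at which the branch-mass matrix products stay cheap;
the Bray–Curtis PERMANOVA uses all samples.

## Known limitations

- The twin t-test inherits pseudo-day autocorrelation (above).
- nMDS convergence is to a local stress minimum; the classical-scaling
  start is deterministic and good in practice, but no restarts are done.
- The unpenalized df-9 smooth can oscillate near sharp features and its
  derivative is unreliable at the grid boundary (hence the interior trim).
- Common scaling discards sub-integer information for rare OTUs
  (round(0.05) = 0); prevalence is therefore computed pre-scaling.
- The window detector's extent (not its location) is sensitive to
  `slope_fraction` when the profile has long shallow descents.
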
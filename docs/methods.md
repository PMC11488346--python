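# Methods

## Cell tables and conventions

The unit of analysis is a table of segmented cell centroids from one mIF
sample, with one hard phenotype call per cell and a region annotation from
`{TC, IM, other}` (tumour core, invasive margin, everything else — finer
annotations are collapsed to `other`). Coordinates are continuous centroids
in µm with arbitrary origin; exports in pixel units are rescaled on load by
a per-sample `pixel_to_um` factor, since segmentation software does not
standardize units. All geometry is centroid-to-centroid: the proximity
radius is not a membrane distance. Rows with non-finite coordinates are
dropped at load time and counted, never silently imputed. Whether spatial
metrics are computed slide-wide or within a region is left as an explicit
parameter (`filter_by_region`), not fixed.

## Effective score and effective percentage

For central phenotype C, surrounding phenotype S and radius r (default
20 µm):

- ES(C→S) = #{surrounding cells within r of central cells} / n_C
- EP(C→S) = #{central cells with ≥ 1 S-neighbor within r} / n_C

Numerical conventions, chosen once and fixed:

- **Counting mode.** "Number of surrounding cells" is ambiguous when one S
  cell lies within r of several C cells. `sum_neighbors` (default) counts
  every (C, S) pair, making ES the mean S-neighbor count per C cell — a
  smooth statistic with the exact CSR expectation λ_S πr² on a torus.
  `unique_neighbors` counts each S cell at most once (then
  ES ≤ n_S / n_C). Both are exposed; analyses where the distinction
  matters should report both.
- **Inclusive radius.** A cell at exactly r is a neighbor. The boundary is
  a measure-zero event for continuous coordinates, but a deterministic rule
  is needed for reproducibility.
- **Self-pairing.** When C = S a cell never counts itself; duplicate
  coordinates remain distinct cells.
- **Undefined metrics.** With n_C = 0 the ratio is undefined and propagates
  as NaN (`UndefinedMetricError` at the lowest level). Substituting 0 would
  bias group contrasts toward "no proximity" exactly in the samples where
  the phenotype is absent.
- **Edge effects.** No edge correction is applied on real slides (counts
  near the window edge are biased low, identically in all samples compared
  at the same radius). A torus mode exists so simulation-based expectations
  are exact; it is the default in the simulators.
- **EP ≤ min(1, ES)** holds in `sum_neighbors` mode, since every central
  cell contributing to EP contributes at least 1 to the ES numerator.

The fixed-radius search uses a k-d tree (periodic boxes for the torus);
its equivalence to an all-pairs brute-force scan is asserted in the test
suite for both boundary modes.

## Synthetic tissue

No public per-cell mIF data accompanies the studies this pipeline targets,
so the simulator generates the same kind of table from point processes with
known structure. It emulates centroid-plus-label geometry only — no marker
intensities, no segmentation error, no tissue architecture (vessels,
follicles, necrosis), and spatial homogeneity within the window. Passing
tests therefore demonstrate correctness of the statistics under a known
generative model, not robustness to segmentation or gating artefacts.

- **CSR null**: independent homogeneous Poisson patterns per phenotype.
- **Attraction**: a Thomas cluster process — Poisson(λ_c) parents of one
  phenotype, each with Poisson(µ) offspring of the other phenotype,
  isotropic Gaussian(σ) displacements, plus an independent offspring
  background λ_bg. Chosen because its CSR limit (µ = 0) and first-order
  intensity (λ_bg + λ_c µ on the torus) are analytic, giving closed-form
  checks. Mean ES(parent→offspring) increases in µ and decreases in σ,
  which the suite verifies by Monte Carlo.
- **Repulsion**: cross-type Matérn-II thinning — CSR for two phenotypes,
  uniform birth marks, and deletion of the later-born member of every
  cross-type pair closer than the hard-core radius, judged on the unthinned
  pattern. This guarantees exactly zero surviving cross-type pairs below
  the hard-core distance, so EP = 0 there by construction.

Windows default to 1000 × 1000 µm. On the torus, offspring displacements
wrap; without it they are discarded when outside the window (border
thinning — a small intensity deficit near edges, documented rather than
corrected). Cohorts draw per-sample seeds from
`SeedSequence(master, spawn_key=(index,))`, so any subset of samples is
reproducible independent of generation order.

Default study conditions (fixed before any measurement, stated here as the
package's reference scenario): parent intensity 2 × 10⁻⁴ cells/µm²
(≈ 200 parents per window), µ = 6, σ = 5 µm, offspring background
1 × 10⁻⁴; cohort contrasts use 15 samples per arm, mirroring a typical
30-sample mIF cohort split by metastasis status.

## scRNA-seq quality control

Per-cell metrics: detected genes, total UMIs, mitochondrial UMI fraction
(`MT-` prefix rule by default, explicit list override). Removal rule:
`n_genes < 200`, `n_genes > 5000`, `mito_fraction > 0.10`, or
`total_umi < 500`, with strict inequalities (a cell at exactly a cutoff is
kept, consistent with "fewer than" / "more than" phrasing). The UMI rule is
interpreted as a minimum *total* library size; the alternative reading (a
mitochondrial-UMI count rule) is subsumed by the fraction cutoff, and both
thresholds are configurable precisely because conventions differ. Removed
cells carry the list of violated rules; the filter is idempotent and the
gene axis is never touched. The count simulator draws log-normal library
sizes, a shared Dirichlet gene-propensity vector, and per-cell Beta
mitochondrial shares (mean 5%, with an optional "dying" subpopulation at
mean 30%) — enough structure to exercise every rule, not a model of real
expression covariance.

## Statistical tests

- **Mann–Whitney U.** For n_a + n_b ≤ 12 the permutation distribution of
  the midrank U statistic is enumerated in full (≤ 924 assignments). The
  enumeration is exact with or without ties, so the exact path is used for
  all small samples rather than only tie-free ones; with ties present a
  large-sample tie-corrected approximation would otherwise be applied to
  tiny samples, where it is least reliable. Larger samples use the normal
  approximation with tie and continuity corrections. Two-sided p-values
  count assignments at least as far from n_a n_b / 2 as observed (the U
  distribution is symmetric under exchangeability). A paired Wilcoxon
  signed-rank companion covers matched designs.
- **Label-permutation association.** Within one sample, phenotype labels
  are shuffled over fixed coordinates; p = (1 + #{ES* ≥ ES}) / (1 + n_perm)
  (add-one estimator: valid, never zero). The default alternative is
  attraction; two-sided uses absolute deviation from the permutation mean.
  The null conditions on the observed geometry, which has a known power
  consequence: when nearly all cells of the surrounding type are clustered,
  shuffled labels also land in clusters and the null ES distribution is
  itself inflated, so single-sample detection is easiest when a diffuse
  background of the surrounding type exists. Group-level contrasts are the
  more powerful design for cohort questions.
- **Multiplicity.** Benjamini–Hochberg across phenotype pairs (step-up with
  monotonicity enforcement, via the standard statsmodels routine).
- **Correlations.** Spearman by default (infiltrate proportions are skewed
  and monotone association is the question); Pearson optional. Constant
  input raises an undefined-correlation error.
- **2×2 tables.** Fisher's exact test (two-sided by the probability-mass
  convention) is the default whenever any expected count is below 5;
  Pearson chi-square with optional Yates correction otherwise. On the
  reconstructed 20-patient response table `[[4, 5], [1, 10]]` (44.4% vs
  9.1% responders) the Fisher path gives p = 0.127 while neither chi-square
  variant does — the test suite pins this distinction, since published
  reports often name the test family loosely.
- **Survival.** Kaplan–Meier product-limit estimation and the two-group
  log-rank test (lifelines). The median is the earliest time the curve
  reaches 0.5 *or below* — including exact-0.5 plateaus — and is undefined
  (NaN) when the curve never crosses 0.5.

## Validation studies (experiments module)

Three simulation studies tie everything together and back the acceptance
checks; their problem sizes are the package's reference settings:

- **CSR closed forms**: 200 torus replicates at surrounding intensity
  10⁻³ cells/µm², r = 20 µm; mean ES must fall within 3 Monte-Carlo
  standard errors of λπr² = 1.2566 and mean EP within 3 SE of
  1 − exp(−λπr²) = 0.7154.
- **Cohort power**: 25 replicate cohorts of 15 vs 15 samples, µ = 6 vs
  µ = 0 at σ = 5 µm; the Mann–Whitney ES contrast at α = .05 detects the
  difference in well over 80% of replicates.
- **Null calibration**: 200 CSR tables (500 × 500 µm, both intensities
  10⁻³), 199 permutations each; the rejection rate at α = .05 sits at the
  nominal level within binomial error (a long-run estimate over 600 tables
  gives ≈ 5.5%).

## Known limitations

- Hard phenotype calls only; marker co-expression must be resolved
  upstream.
- No edge correction for real (non-torus) slides; comparisons should use a
  common window geometry.
- The Matérn-II thinning judges conflicts on the unthinned pattern (classic
  type-II), which thins somewhat more aggressively than iterative schemes.
- The simulator's homogeneous intensities ignore tissue architecture;
  region-stratified analyses on real data should expect within-region
  heterogeneity the tests here do not model.
- Survival tooling covers two-group KM/log-rank only; regression-style
  survival modelling (Cox, cutpoint optimization) is out of scope.
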
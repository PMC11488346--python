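# spatprox

Spatial proximity statistics for phenotype-labelled cell tables, built for
quantifying the tumour microenvironment from multiplex immunofluorescence
(mIF) slides — e.g. gastric tumours and their peritoneal metastases — plus
the surrounding analysis stages such studies need: single-cell RNA-seq
quality-control filtering, between-group statistics, and small-cohort
response/survival comparisons. A point-process tissue simulator with known
ground truth makes every stage testable without imaging data.

## Who it is for

Computational pathology / tumour-immunology analysts who have per-cell
segmentation exports (inForm-style CSVs with centroid coordinates and one
phenotype call per cell, e.g. `panCK+`, `FAP+`, `CD68+`, `CD3+`, `CD31+`,
`MUC1+`, optionally annotated as tumour core `TC` / invasive margin `IM`)
and want reproducible co-localization statistics and cohort contrasts.

## The statistics

For a *central* phenotype and a *surrounding* phenotype at a fixed radius
r (default 20 µm, the standard cell-interaction distance):

- **Effective score** — ES = (number of surrounding cells within r of
  central cells) / (number of central cells). In the default
  `sum_neighbors` mode this is the mean neighbor count per central cell,
  with closed-form CSR expectation λπr² for surrounding intensity λ
  (cells/µm²); the `unique_neighbors` mode counts each surrounding cell at
  most once.
- **Effective percentage** — EP = fraction of central cells with at least
  one surrounding cell within r; CSR expectation 1 − exp(−λπr²).

Higher ES/EP means closer co-distribution of the two cell types. Distances
are Euclidean centroid-to-centroid, the radius is inclusive, and a missing
central phenotype yields NaN, never 0. Significance comes from a
label-permutation test (shuffle phenotype labels over fixed coordinates);
cohort arms are compared per phenotype pair with Mann–Whitney U
(exact permutation enumeration for n ≤ 12) and Benjamini–Hochberg control
across pairs. The scRNA-seq stage removes cells with fewer than 200 or more
than 5000 detected genes, more than 10% mitochondrial UMIs, or fewer than
500 total UMIs. Cohort post hoc tools cover response-rate 2×2 tables
(Fisher exact / chi-square) and Kaplan–Meier / log-rank survival.

## Worked example

Simulate a slide where FAP+ fibroblasts cluster around panCK+ tumour cells
(Thomas process, six offspring per parent at σ = 5 µm, on a diffuse
background) with an unrelated CD68+ population, then quantify proximity:

```python
import spatprox as sp

spec = sp.AttractionSpec("panCK+", "FAP+", parent_intensity=2e-4,
                         mean_offspring=6.0, dispersion=5.0,
                         offspring_background=3e-4)
cfg = sp.TissueSimConfig(seed=7, window=(1000.0, 1000.0), boundary="torus",
                         attraction=spec,
                         background_intensities={"CD68+": 4e-4})
tissue = sp.simulate_attraction(cfg)
print("cells per phenotype:", sp.phenotype_counts(tissue))

q = sp.ProximityQuery("panCK+", "FAP+", radius=20.0,
                      boundary="torus", window=(1000.0, 1000.0))
res = sp.proximity(tissue, q)
print(f"ES = {res.es:.2f}, EP = {res.ep:.2f}")

null_q = sp.ProximityQuery("panCK+", "CD68+", radius=20.0,
                           boundary="torus", window=(1000.0, 1000.0))
print(f"null pair ES = {sp.proximity(tissue, null_q).es:.2f}")

test = sp.permutation_association(tissue, q, n_perm=999, seed=1)
print(f"attraction permutation test: p = {test.p_value:.3f}")

table = sp.ResponseTable([[4, 5], [1, 10]])   # responders / non-responders
print("response rates:", table.response_rates())
print(f"Fisher exact p = {sp.fisher_exact(table).p_value:.3f}")
```

Output:

```
cells per phenotype: {'FAP+': 1557, 'CD68+': 407, 'panCK+': 199}
ES = 8.25, EP = 1.00
null pair ES = 0.56
attraction permutation test: p = 0.001
response rates: (44.4, 9.1)
Fisher exact p = 0.127
```

Each tumour cell has on average 8.25 fibroblasts within 20 µm — far above
the ≈ 0.6 a random arrangement of the same cell numbers would give (the
unrelated CD68+ pair sits right at its CSR expectation of 0.50) — and every
tumour cell has at least one fibroblast neighbor; the permutation test
confirms the attraction. The 2×2 example contrasts objective response rates
of 44.4% vs 9.1% between two arms of a 20-patient cohort; Fisher's exact
test gives p = 0.127.

A thin CLI wraps the same functions: `spatprox simulate` (config →
per-sample CSVs + manifest), `spatprox qc` (count matrix → filtered matrix +
report), `spatprox posthoc` (cohort CSV → response/survival summary).

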
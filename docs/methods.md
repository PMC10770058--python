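# Methods

## Model

A multi-slice spatial omics dataset is `N` cells with expression over
`G` genes, coordinates in 2 or 3 dimensions (micrometers after the
dataset's `unit_scale` is applied), and a `slice_id` assigning each cell
to one tissue section. Slices have independent coordinate frames; no
spatial relation between cells of different slices is ever used.

The pipeline has four stages.

**1. Cell states.** A discrete state label `g_1 … g_C` per cell, either
computed (total-count normalization to the median per-cell total, log1p,
PCA to ≤ 50 components, 15-nearest-neighbor graph, Leiden modularity at
resolution 2) or adopted from a provided annotation. Resolution 2 is
deliberately fine-grained: over-splitting a true cell type costs nothing
downstream (the ring counts just split across two columns), while
merging distinct types destroys the compositional signal. When a
trustworthy annotation exists, providing it is preferred — it is faster
and immune to expression-clustering noise.

**2. Multi-range context.** Around each cell, `S` concentric rings of
width `R` collect the same-slice cells at distance `[(s−1)R, sR)`
(half-open; a pair at exactly `R` belongs to ring 2; the index cell
itself, at distance 0, sits in ring 1 unless `self_in_first_ring=False`).
The representation matrix `M` counts states per ring, columns ordered
range-major: column `(s−1)·C + c` is state `g_c` in ring `s`. For
array-like spot data (Visium, ST) rings are instead exact hop-`s` shells
of the per-slice `nn`-nearest-neighbor lattice graph, union-symmetrized,
which reproduces the hexagonal (nn = 6) and square (nn = 4) lattice
shells. Spatial queries use a k-d tree but are semantically identical to
brute force — the test suite asserts exact integer equality against an
independent all-pairs implementation.

**3. Domains.** `M` is normalized per cell to the median row total,
log1p-transformed, PCA-reduced, and clustered with Leiden
(RBConfiguration quality, seeded) on a 15-nearest-neighbor graph built
from all slices jointly. Joint clustering is what makes domain labels
comparable across slices and keeps clustering granularity consistent.
UMAP of the same embedding is available for visualization only and is
never used for clustering.

**4. Interpretation and cohorts.** Per-domain one-vs-rest Wilcoxon
rank-sum tests over the `S·C` columns of `M` give ranked `(state, ring)`
signatures. Patients are represented by their domain-proportion vectors;
group structure is examined by PCA with per-component two-sample t-tests
and by stratified k-fold cross-validated classification.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `R` | 15 µm | ring width; the cross-technology median 1-NN cell distance. `estimate_radius` recomputes the pooled per-slice median for new data. |
| `S` | 6 (single-cell res.) | number of rings; 2 for Visium/ST lattices, 4 for bead arrays. Context reach is `S·R` = 90 µm at defaults. |
| `nn` | 6 (Visium), 4 (ST) | lattice-hop ring construction for spot arrays. |
| state resolution | 2.0 | Leiden resolution for computed cell states (intentionally fine). |
| domain resolution | 0.5 | used when no expected domain count is given. |
| `target_k` | — | expected number of domains; triggers `res_search`. |
| `n_neighbors` | 15 | kNN graph size for both clustering steps. |
| `target_total` | median row total | normalization target before log1p (both expression and `M`). |

## res_search

The expected-domain-count search bisects the Leiden resolution in
[0.01, 10]: too few clusters raises the lower bound, too many lowers the
upper. Cluster count is near-monotone in resolution, but not strictly,
so after 30 iterations without an exact hit the run with the closest
count (ties to the smaller resolution) is returned with `inexact=True`.
The flag — not attainment — is the contract: some counts are genuinely
unattainable within bounded resolution.

## Numerical and determinism choices

- PCA is a full SVD with each component's largest-magnitude loading made
  positive, so embeddings are bitwise reproducible across runs.
- Leiden uses a fixed seed; cluster IDs are relabeled by size
  (descending, ties by smallest member index) and emitted as
  `"D0", "D1", …`. Label alignment across *different* runs is not
  attempted — all metrics are permutation-invariant.
- NMI is computed from the empirical contingency table with natural
  logs (the base cancels). If either partition has zero entropy, NMI is
  1 when the partitions are identical as set partitions, else 0.
- PAS neighbor queries are per slice, self-excluded, with distance ties
  broken by cell index; slices smaller than `k+1` cells fall back to
  `k_eff = n−1` with a proportionally scaled threshold.
- Wilcoxon rank-sum p-values are exact (via the Mann–Whitney null
  distribution) when both groups have ≤ 25 observations and the feature
  is tie-free, otherwise the normal approximation with tie and
  continuity corrections; the reported score is always the signed
  standardized statistic, so ranking is consistent across both regimes.
  Benjamini–Hochberg adjustment is applied within each domain (the
  multiplicity procedure is switchable off).
- Cohort cross-validation refits the PCA projection inside each training
  fold when `n_pcs` is set, so held-out patients never influence the
  projection.
- Degenerate inputs: an all-zero context row (isolated cell) passes
  through the embedding as zeros with a warning; identical embedding
  rows short-circuit to a single state; duplicate coordinates yield
  zero 1-NN distances with a warning, not an error.

## Synthetic tissue: what it does and does not emulate

`generate_layered_tissue` emulates laminar tissue: each slice is a
rectangle cut into horizontal layers (the planted domains), each layer
has its own mixing proportions over a shared state alphabet, and each
state has a mean expression profile with Poisson (or negative binomial)
count noise. The default fixture is 3 slices × 5 layers × 400 cells,
layer thickness 400 µm and width 1020 µm, giving ~15 µm median
nearest-neighbor spacing — the same neighborhood statistic the 15 µm
default radius is built on; compositions give each layer a dominant
state (0.65) over a shared background (0.20). These defaults are
calibrated so that the planted structure is recoverable by the method
(the generator's contract includes end-to-end recovery at NMI ≥ 0.9),
while boundary cells — whose rings genuinely straddle two layers —
remain the dominant error source, as in real laminar tissue.

The adversarial variant gives layers 2 and 4 *identical* compositions
and thinner geometry (170 µm) so that the 90 µm context reach sees the
flanking layers: a single 15 µm ring cannot distinguish them, multi-range
context can. This is the construction that separates `S=6` from the
`S=1` single-range ablation.

Not emulated: gene–gene correlation within states, segmentation noise,
curved or discontinuous domain geometry, cross-slice batch effects
(batch integration is exposed only as a pre-embedding hook), and
realistic cell-type hierarchies. Passing tests therefore demonstrate
correctness of the machinery and recoverability of compositional
structure, not performance on any real tissue.

## Known limitations

- Robustness to cell-state label noise is bounded by ring population:
  at ~15 µm spacing a full 6-ring context holds only ~25 cells, so when
  half the labels are randomized the compositional signal halves while
  multinomial counting noise is unchanged. On the default fixture the
  recovery NMI drop stays below ~0.13 up to noise level 0.3 but reaches
  ~0.4 at level 0.5, with errors spread through layer interiors — an
  information limit of per-cell hard assignment from small contexts, not
  an implementation artifact. Denser data (larger ring populations)
  degrade more slowly.
- Ring widths are isotropic and fixed; adaptive or anisotropic
  neighborhoods are out of scope.
- `res_search` assumes near-monotonicity of cluster count in
  resolution; strongly non-monotone instances end with `inexact=True`.
- UMAP determinism holds for a fixed seed on a fixed platform; exact
  coordinates may differ across BLAS/numba builds.
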
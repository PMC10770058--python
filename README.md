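# mender-spatial

Multi-range cell-context representation and **multi-slice spatial domain
identification** for spatially resolved single-cell and spot-based omics
data, with evaluation metrics, domain signatures, and cohort-level
patient stratification — all testable on built-in synthetic tissue.

## The problem and the method

Tissues are organized into *spatial domains*: recurrent regions (cortical
layers, tumor niches) composed of multiple cell states in a characteristic
spatial arrangement. Given several tissue sections ("slices") with a cells
× genes expression matrix, per-cell coordinates and a `slice_id`, the goal
is to label every cell with a domain such that labels mean the same thing
on every slice.

The method (MENDER, *multi-range cell-context deciphering*) represents
each cell by the composition of its neighborhood at several distance
ranges. With cell states `g_1 … g_C` (from Leiden clustering of expression
at resolution 2, or from a provided annotation), `S` concentric rings of
width `R` are built around each *index cell* `i` from the cells of the
same slice only, and the representation matrix `M ∈ Z+^{N×(S·C)}` counts

```
M[i, (s−1)·C + c] = |{ j : (s−1)·R ≤ Dist(i,j) < s·R,
                        slice_j = slice_i,  cell_j = g_c }|
```

`R` defaults to 15 µm — the empirical median nearest-neighbor distance
across single-cell resolution spatial technologies (the bundled
`estimate_radius` recomputes it for new data) — and `S` to 6 for
single-cell resolution data (2 with lattice-hop rings for Visium/ST, 4
for bead arrays). Rows of `M` are normalized, log1p-transformed, reduced
by PCA and clustered jointly across slices with Leiden on a kNN graph
(default resolution 0.5, or `res_search` bisection when the expected
number of domains `k` is known). Because every slice contributes rows to
one matrix, domain labels align across slices with no post-hoc matching.

Evaluation uses NMI `= MI(P,T)/√(H(P)·H(T))`, ARI, and PAS (fraction of
cells whose label differs from ≥ 6 of their 10 nearest same-slice
neighbors). Columns of `M` are interpretable `(state, ring)` features, so
one-vs-rest Wilcoxon rank-sum tests yield readable *spatial signatures*
per domain. For cohorts, each patient is summarized by their vector of
domain proportions, embedded with PCA and classified with cross-validated
stock classifiers.

## Worked example

```python
import mender
from mender.synthetic import TissueSpec, generate_layered_tissue

ds, truth, states = generate_layered_tissue(TissueSpec(seed=1))   # 3 slices, 5 layers
result = mender.run_mender(ds, mender.MenderParams(target_k=5, seed=1))
print(result.n_domains, round(result.resolution_used, 3))
print(round(mender.nmi(result.labels, truth), 3),
      round(mender.pas(result.labels, ds.coords_um(), ds.slice_id), 3))
```

prints

```
5 0.634
0.935 0.012
```

— the pipeline recovered the 5 planted layers (NMI 0.935 against the
ground truth; a perfect labeling would be 1.0) with high spatial
continuity (PAS 0.012; lower is better — the truth labels themselves score
≈ 0.016 because layer-boundary cells have mixed neighborhoods).

The same run is available from the shell:

```bash
mender simulate --out tissue.h5ad --seed 1
mender run --input tissue.h5ad --outdir out --target-k 5 \
       --state-column cell_state --seed 1
mender estimate-radius --input tissue.h5ad
```

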
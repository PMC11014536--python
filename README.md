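# sizedeconv

Cell-size-aware reference-based deconvolution of bulk RNA-seq.

## The problem

Reference-based deconvolution estimates the cell-type composition of a bulk
RNA-seq sample from cell-type-specific expression profiles. The standard
linear model,

```
Y_{G×J} = Z_{G×K} · P_{K×J}
```

with bulk expression `Y` (G marker genes × J samples), signature matrix `Z`
(per-type mean expression from single-cell/nucleus data) and proportions `P`
(columns on the simplex), implicitly assumes every cell type contributes the
same amount of mRNA per cell. It does not: larger cells carry more
transcripts. Solving the naive model therefore returns the **RNA fraction**
per type, not the **cell fraction** — large cell types (neurons in cortex)
are systematically over-predicted and small ones (glia) under-predicted.

The fix is a per-type cell-size scale factor vector `s` applied column-wise
to the signature:

```
Y = Z · diag(s) · P,        Z' = Z · diag(s)
```

Solving `Y = Z' · P` by non-negative least squares (NNLS) and renormalizing
each sample's coefficients to sum to one yields cell-fraction estimates.
Because of the renormalization, only the ratios of `s` matter. For human
cortex a neuron:glia factor ratio of 10:3 is a reasonable default; size
factors from imaging or marker-expression measurements plug in as a simple
two-column table.

The package also provides the machinery to study this correction: Mean Ratio
marker selection (`mean_k(g) / max_{k'≠k} mean_{k'}(g)`), signature building
from labelled single-cell counts, batch-wise count downsampling, pseudobulk
simulation with known proportions, term-shuffling robustness experiments, an
algorithm-adapter registry (NNLS built in; other deconvolution methods
register through the same size-aware interface), and RMSE/bias/correlation
evaluation against known compositions.

## Worked example

```python
import sizedeconv as sd

# synthetic single-nucleus dataset: 2 types (neuron, glial), 40 markers each,
# 500 cells/type, NB counts, true sizes neuron=10 / glial=3
sc, Z_true, s = sd.synth_sc(sd.SynthConfig(seed=1))

markers = sd.mean_ratio_markers(sc, n_per_type=40)     # 80 marker genes
Z = sd.build_signature(sc, genes=markers.genes)        # 80 x 2 signature

# 17 mixtures with the neuron proportion spanning 25% .. 80%
P = sd.proportion_grid(17, 0.25, 0.80, type_ids=["neuron", "glial"])
Y = sd.pseudobulk(Z, s, P)

naive = sd.deconvolute(Y, Z)          # assumes equal cell sizes
aware = sd.deconvolute(Y, Z, s)       # size-factor scaled

print("unscaled pooled RMSE", sd.rmse(P, naive.proportions))
print("scaled   pooled RMSE", sd.rmse(P, aware.proportions))
```

prints

```
unscaled pooled RMSE 0.2458667537631115
scaled   pooled RMSE 2.0748541817894375e-16
```

Ignoring cell sizes misestimates every mixture by ~0.25 on average — for an
equal neuron/glia mixture the naive estimate is (0.77, 0.23), the RNA
fraction `(s∘p)/(s·p)` — while the size-aware solve recovers the known
proportions to machine precision. The same workflow is available from the
shell via the `sizedeconv` command (`synth`, `markers`, `signature`,
`pseudobulk`, `deconvolute`, `shuffle`, `benchmark` subcommands).

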
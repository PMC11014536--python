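# Methods

## Model

A bulk RNA-seq sample is modelled as a non-negative linear mixture of
cell-type expression profiles weighted by cell-type abundance *and* per-cell
mRNA content:

```
Y = Z · diag(s) · P
```

- `Y` (G × J): bulk expression over G marker genes and J samples;
- `Z` (G × K): signature matrix — arithmetic mean expression of each marker
  gene over the cells of each type, computed from labelled single-cell or
  single-nucleus counts;
- `s` (length K, strictly positive): cell-size scale factors, proportional to
  the total mRNA content of one cell of each type;
- `P` (K × J): cell-type proportions, each column non-negative and summing
  to one.

Estimation solves, per sample, the non-negative least-squares problem
`argmin_{q≥0} ‖y − Z·diag(s)·q‖₂` with the Lawson–Hanson active-set solver
(scipy's `nnls`, solver-default convergence tolerance), then renormalizes
`q` to the simplex. Renormalization makes the estimates invariant to any
global rescaling of `s` (a tested property), so scale factors are used
exactly as supplied, with no internal normalization — only their ratios
matter. A sample whose raw coefficient vector is identically zero (e.g. an
all-zero bulk column) has no defined direction; it is mapped to the uniform
vector and flagged in `degenerate_samples` rather than producing NaNs.

When `s` is omitted the signature is used as-is, which amounts to assuming
equal cell sizes. On noiseless consistent pseudobulk with full-column-rank
`Z`, the size-unaware estimate has the closed form

```
p̂ = (s ∘ p) / (s · p)
```

— the RNA fraction per type. This oracle (`expected_unscaled_estimate`) is
exact and is used throughout the tests to validate the solver path
independently. For K=2 with factors (10, 3), the per-sample error
`7p(1−p)/(7p+3)` peaks near a true large-type proportion of p ≈ 0.35 and
grows monotonically with the size ratio.

## Marker selection

For each gene g and target type k the Mean Ratio is
`mean_k(g) / max_{k'≠k} mean_{k'}(g)`; the top n genes per target type
(default 40) are kept and the final marker panel is the union across types.
The statistic is scale-invariant, so it gives identical selections on raw
counts and on globally rescaled data; it is computed on whatever expression
representation is supplied (counts or batch-adjusted log-normalized values),
with no hidden normalization. Tie policy, chosen for determinism: genes with
zero off-target expression have infinite ratio and rank above all finite
ratios; ties (infinite or exact finite ties) are broken by descending
target-type mean, then lexicographic gene id. An optional cross-run filter
(`concordant_markers`) keeps (gene, type) pairs selected in at least m of n
per-sample runs; it is off by default because it only applies when several
independent selection runs exist.

## Batch downsampling and bulk QC

`downsample_batches` equalizes sequencing depth across batches within each
cell type: the batch library size is the **median** per-cell total count in
the batch × type stratum (median rather than mean, for robustness to outlier
cells — the summary statistic is otherwise an open choice), and every cell
in a batch is binomially thinned with retention probability
`L_min / L_batch`, capped at 1. Thinning never increases a count and
preserves the expected expression profile shape.

`qc_filter_bulk` retains bulk samples with at least 38,750 total counts over
the marker panel and at most 30 zero-expression markers (both thresholds
inclusive and configurable); markers absent from the bulk matrix count as
zero-expression markers. `normalize_bulk` provides RPKM
(`counts·10⁹ / (libsize · length)`) and CPM (`counts·10⁶ / libsize`) with an
optional `log2(x + pseudocount)` transform.

## Pseudobulk simulation and shuffle experiments

`pseudobulk` computes `Y = Z·diag(s)·P` exactly (no noise is added at this
stage; stochasticity enters through the single-cell generator that produces
`Z`). `proportion_grid` builds evenly spaced mixture series — the benchmark
default is 17 mixtures with the first type spanning 0.25–0.80, so grid
results approximate, but do not exactly reproduce, studies built on
irregular empirical mixtures.

Shuffle experiments separate the five terms of the generative equation into
a pseudobulk side (`Z_pb, S_pb, P_pb`) and a deconvolution side
(`Z_dc, S_dc`). Each term is bound to the base sample ("matched"), to a
seeded draw from the other library samples ("shuffle", without replacement
and never the base sample itself), or to a fixed sample id (the
held-constant term). Truth is always `P_pb`; each run records RMSE and
per-type signed errors. The number of repetitions is a configuration knob
(default: one run per library sample) as no canonical value exists.

## Synthetic single-cell generator

`synth_sc` draws negative-binomial counts (genes × cells) with:

- `n_genes = 200`, `n_types = 2` (labels neuron/glial), `markers_per_type =
  40`, `cells_per_type = 500`, `marker_fold_change = 8` — enough genes that
  markers must be found among a majority of background genes, and enough
  cells that signature noise is ~4% per gene mean;
- `nb_mean = 5.0`: background mean per gene per cell, a typical magnitude
  for moderately expressed genes in shallow snRNA-seq; marker genes of type
  k have mean `nb_mean · fold_change · s_k` in their own type (larger cells
  carry proportionally more transcripts of their marker genes) and
  `nb_mean` elsewhere;
- `nb_dispersion = 2.0`: the NB size parameter, shared across genes
  (variance `μ + μ²/2`, i.e. strongly overdispersed, as in real droplet
  data); a single shared parameter is the simplest model consistent with an
  NB count distribution;
- size factors default to neuron 10 / glial 3, the cortical contrast the
  method targets;
- two sequencing batches with library-size multipliers (0.8, 1.2) — mean 1,
  so per-type expected means equal the generating signature — and three
  donors, assigned round-robin, emulate batch depth differences and
  multi-donor structure.

Everything is reproducible from a single integer seed. What the generator
does **not** emulate: gene-length effects, per-gene dispersion variation,
dropout beyond NB sampling, correlated gene programs, ambient RNA, or
donor-specific expression shifts. Tests passing on this generator therefore
establish correctness of the estimation machinery and its bias-correction
algebra, not performance on real tissue, where reference mismatch and
technology effects dominate.

## Evaluation

Error is `|P_known − P_pred|` elementwise; RMSE for sample j is
`sqrt(Σ_k (P_known[k,j] − P_pred[k,j])² / K)`. The headline aggregate is the
pooled RMSE over all K·J entries (for K=2 the per-sample and pooled
conventions coincide in expectation; per-sample values are also emitted
because they localize the error). Signed bias (predicted − known) is
reported per type to expose the over/under-prediction asymmetry, and
Pearson r per type requires ≥3 samples and non-degenerate variance
(degenerate types yield NaN, not an exception). `aggregate_neuron_k3`
collapses an {Excit, Inhib, glial} composition to {neuron, glial} by summing
the two neuronal rows.

## Problem sizes and numerical choices

The bundled study uses the generator defaults above (1,000 cells, 200 genes,
17 mixtures): large enough that marker selection is non-trivial and
recovery noise is measurable, small enough that the full suite runs in
seconds. Proportion columns are validated to sum to 1 within 1e-8; exact
round trips are asserted at 1e-8, closed-form oracle agreement at 1e-8,
scale-factor invariance at 1e-10, and the size-aware solve on consistent
pseudobulk recovers proportions at machine precision (~1e-16). Matrices are
dense internally; sparse single-cell input is densified only for the marker
subset in use. Alignment always follows the signature matrix's gene and
type order, making every pipeline deterministic for a fixed seed.

## Known limitations

- The built-in solver treats samples independently; cross-sample weighting
  schemes are an adapter concern (third-party algorithms are supported as
  registered adapters, not reimplemented).
- Batch correction beyond downsampling (e.g. empirical-Bayes location/scale
  adjustment) is expected upstream.
- Gene-level identifiers only; no transcript or probe support.
- Scale factors are consumed as a table; estimating them from imaging is out
  of scope.
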
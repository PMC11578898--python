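# Methods

## Scope and model

`autoqc` decides, per sample, which droplets of a single-cell RNA-seq count
matrix are usable cells. The decision is driven entirely by the joint
distribution of eight per-cell QC metrics; gene-expression structure is
deliberately ignored so that the same procedure applies to any tissue or
protocol. The underlying model is that within one sample each metric's
values are a finite mixture of roughly Gaussian modes — one (or more) for
intact cells and others for failure modes such as debris (low counts),
dying cells (high mitochondrial fraction) or nuclei/ambient contamination
(shifted spliced fraction) — and that droplets sharing a failure mode also
co-locate in the 8-metric space.

Upstream steps are consumed, not reproduced: ambient-RNA estimation,
spliced/unspliced quantification and doublet scoring arrive as per-cell
inputs. When an input is absent the corresponding metric is missing (NaN),
excluded from mixture fits, median-imputed for the metric-space embedding
only, and treated as a pass in the per-cell conjunction — absence of
evidence never fails a cell.

## Pipeline and numerical choices

1. **Metrics.** Natural log is used for both `log1p` transforms. Gene-set
   matchers default to human symbols: prefix `MT-` (mitochondrial),
   prefixes `RPS`/`RPL` (ribosomal proteins), regex `^HB[ABDEGMQZ]`
   (haemoglobin, excluding the HBP pseudogenes); all are configurable for
   other species. A cell with zero total counts is marked invalid and fails
   outright. `percent_spliced` with spliced + unspliced = 0 is missing, not
   zero.
2. **QC clustering.** Metrics are standardized per sample (zero mean, unit
   variance; zero-variance or all-missing metrics are dropped — if none
   remain the sample is degenerate and rejected with a reason rather than an
   exception). The symmetrized Euclidean 15-NN graph is partitioned by
   Leiden (RBConfiguration quality, resolution 0.2, seeded, iterated to
   convergence). "Low resolution" is intentional: the voting step only needs
   clusters coarse enough to isolate failure modes. Samples with fewer than
   max(k+1, 10) cells are degenerate. The 2-D layout attached to results is
   diagnostic only and defaults to PCA of the standardized metric space
   (deterministic and cheap); UMAP is available via `layout="umap"`.
3. **Mixture fits.** Each decision metric is fitted in one dimension —
   axis-aligned thresholds are the point; a joint 4-D mixture could not
   yield per-metric cut-offs. EM uses 3 restarts, tolerance 1e-4, up to 200
   iterations, seeded. Component count k is scanned over 1..10 and chosen by
   minimum BIC, `(3k−1)·ln n − 2·logLik`, ties toward smaller k; a fixed-k
   mode (historically k = 10, an intentional overfit) is kept and feeds the
   identical interval-extraction rule, which on well-separated data yields
   the same verdicts as the automatic mode. Candidate k values exceeding the
   number of distinct values, or whose fit fails, are skipped with a logged
   warning; at least 50 finite values are required per metric, otherwise the
   metric is dropped from the decision set.
4. **Pass intervals.** Components are sorted by mean. Those whose mean lies
   inside the metric's guidance anchor become pass components; if none
   does, the single component nearest the anchor interval is taken. The
   weighted component densities are evaluated on a 1,000-point uniform grid
   over the observed data range; each point is labelled with its argmax
   component (ties toward the lower-mean component), and the pass interval
   is the maximal contiguous pass-labelled run containing the
   highest-weight pass component's mean. Runs touching a grid edge extend
   to ±∞ on that side, so a single dominant healthy component passes
   everything. For two equal-variance components this reproduces the
   closed-form equal-density crossing `(μ₁+μ₂)/2 + σ²·ln(w₁/w₂)/(μ₂−μ₁)` to
   within one grid step. Default anchors: counts ≥ ln 251, genes ≥ ln 101,
   mito ∈ [0, 20], spliced ∈ [50, 97.5].
5. **Boundary semantics.** Interval membership is closed; the cluster vote
   passes at fraction ≥ 0.5 exactly; the sample filter rejects on strictly
   fewer than 10% or strictly fewer than 100 passing cells, so 100 cells at
   exactly 10.0% are kept. The doublet gate is strictly greater than 0.25
   on a provided score; missing scores leave cells untouched.
6. **Determinism.** One user seed feeds a seed sequence from which each
   stage (clustering, mixtures, layout) draws its own sub-seed (< 2³¹).
   Reruns with the same seed and config produce byte-identical per-cell
   CSVs and report JSON; for that reason wall-clock timings are logged to
   stderr and never written into the report.

## Label transfer

The uncertainty-weighted kNN vote uses a Gaussian kernel with adaptive
bandwidth equal to the k-th-neighbour distance (k = 30 by default); this is
one reasonable reading of "weighted kNN uncertainty" — the exact kernel is
an interpretation, documented here, and swapping it for inverse-distance
weights only requires replacing one function. When all k distances are zero
the weights are uniform (the vote is unanimous in the self-transfer case,
giving uncertainty 0). Vote ties break toward the lexicographically
smallest label and are logged. The unknown threshold is the empirical 90th
percentile (linear-interpolation convention) of uncertainty computed
separately per user-supplied group — stratification matters because, e.g.,
tumour cells legitimately sit at higher uncertainty than normal cells and
would otherwise absorb the entire flagged decile. "Greater than" is strict.
Unknown cells are repaired by Leiden clustering of the query embedding at
resolution 1 and majority vote of the confident cells per cluster; clusters
with no confident member stay unknown and are surfaced in the output —
resolving them needs marker genes and is out of scope. The covariate
diagnostic is ordinary least squares of each latent dimension on one
covariate (categoricals one-hot encoded, first level dropped), reporting
per-dimension R²; correlated covariates can explain the same variance, so
the values are not additive across covariates.

## What the synthetic generator does and does not emulate

The generator plants populations that differ exactly in the metrics the
pipeline thresholds: good cells (total counts log-normal(8.5, 0.4) ≈ 5,000,
mito fraction Beta(2, 38) ≈ 5%), debris (log-normal(5.0, 0.5) ≈ 150
counts), dying cells (Beta(16, 24) ≈ 40% mito), soup-heavy droplets
(ambient fraction Beta(8, 12) ≈ 40%) and doublets (element-wise sums of two
good cells with doublet scores Beta(20, 5)). Gene counts are multinomial
conditional on the drawn total, over a power-law expression profile whose
mitochondrial mass is rescaled to the cell's drawn mito fraction — totals
and fractions are therefore exactly controllable, which keeps
planted-truth recovery tests sharp. The standard sample is 1,500 / 300 /
200 / 100 / 100 cells over 2,000 genes; at these sizes the full pipeline
runs in a few seconds and the good vs dying mito distributions overlap by
well under 5%, so thresholding is well-posed by construction.

Deliberately absent: biological heterogeneity (cell types, cell cycle),
batch effects, gene-level spliced/unspliced counts, and negative-binomial
overdispersion beyond what the multinomial induces. Passing tests therefore
demonstrate that the machinery recovers planted metric structure, not that
any particular real tissue separates as cleanly; on real data the margins
between modes are narrower and the cluster vote does correspondingly more
of the work.

## Known limitations

- Metrics are thresholded marginally; a cell jointly aberrant but
  marginally unremarkable is caught only if its QC cluster fails.
- The fixed-k overfit mode relies on the same interval-extraction rule as
  the automatic mode; with many redundant components the extracted boundary
  can sit a few grid steps from the automatic one even when verdicts agree.
- Group quantile thresholds flag ≈10% of every group as unknown by
  construction, including groups that were transferred perfectly.
- Sample-level decisions are per sample by design; no information is pooled
  across samples, so systematically poor studies must be caught by the
  sample filter, not by cross-sample comparison.
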
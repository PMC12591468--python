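# Methods

## The model

`cytocomm` treats a cytokine-stimulated signaling pathway as a noisy
communication channel. Each of the M stimulation conditions (by default
M = 6: unstimulated baseline, IL-4, IL-2, IL-10, IL-6, IFNγ) is a
hypothesis H_i whose "codeword" is the K-dimensional pattern of
phospho-protein readouts it evokes (K = 6: pSTAT1, pSTAT3, pSTAT4,
pSTAT5, pSTAT6, pSMAD2/3). A cell's measured response is the codeword
corrupted by molecular noise; the question is how reliably the condition
can be identified from the response alone.

### Preprocessing

Raw fluorescence is heavy-tailed, approximately log-normal. Channel k of
each cell is transformed as

    x(k) = ln(d(k) − α(k) + 1),

where α(k) is the minimum of channel k pooled over all cells, treatments
and subjects of one (cell type, donor category) group. The shift makes
the log argument ≥ 1, so transformed values are nonnegative with an
exact zero at the pooled minimum. Two conventions are fixed here and
recorded in output provenance:

- *natural* logarithm (densities are base-free; only the monotone map
  matters, but the convention must be pinned down);
- the offset is pooled across treatments and across subjects within the
  donor category, so a single transform applies to all M hypotheses of a
  group — a treatment-dependent transform would distort the detector's
  comparison between hypotheses. Per-subject pooling is available by
  passing a one-sample group to `compute_offsets`. Donor categories
  (HD, BC, HD+rux) each form their own pooling group.

### Per-hypothesis density model

Transformed responses under H_i are modeled as a two-component
multivariate Gaussian mixture with full covariances,

    p(x | H_i) = ρ_i N(x; m1_i, Σ1_i) + (1 − ρ_i) N(x; m2_i, Σ2_i),

capturing the common bimodality of responder / non-responder
subpopulations. Fitting is EM (scikit-learn `GaussianMixture`) with
k-means++ initialization, `n_init = 5` seeded restarts, convergence
tolerance 1e−6, at most 500 iterations, and a ridge of 1e−6 × (mean
per-channel variance) on covariance diagonals. These EM hyperparameters
are declared package defaults chosen for reproducibility and robustness
to near-singular channels, not values with any empirical meaning; every
fit records its seed, iteration count, convergence flag and
log-likelihood. Component 1 is, by convention, the component with the
larger mixing weight (ties broken by larger first-channel mean), which
stabilizes serialization; the density is invariant under label swap.

Mixture densities are evaluated with Cholesky factorizations and
log-sum-exp, using the correctly normalized K-dimensional Gaussian
density (2π)^(−K/2) det(Σ)^(−1/2) exp(−½ quadratic form).

### Detection and the probability of error

With equiprobable hypotheses P(H_i) = 1/M, the Bayes-optimal detector is
maximum likelihood: decide the H_i maximizing p(x | H_i). Every measured
cell of every condition is pushed through the detector in one
deterministic pass, accumulating an M×M count matrix Q with entry
(i, j) = number of cells of true condition j decided as i. Exact
log-density ties (a measure-zero event for distinct fits, but routine
when models coincide) resolve to the lowest hypothesis index.

Conditional probabilities are estimated per true condition,
Q_ij = Q(i, j)/N_j, so each column sums to 1 regardless of per-condition
cell-count imbalance. The overall error probability is reported under
two weightings:

- `equiprobable` (default): Pe = 1 − (1/M) Σ_j Q_jj, matching the equal
  priors of the detector;
- `empirical`: Pe = 1 − Σ_j Q(j, j)/N, weighting conditions by observed
  cell counts.

The two coincide for balanced counts. Evaluation is resubstitution by
default — models classify the cells they were fitted on — which is the
convention this style of analysis uses; an optional held-out split
(`holdout_fraction`) is provided for bias control but off by default.

Pairwise (two-ligand) error rates are computed by re-running the
detection restricted to each pair {i, j} with equal priors over the
cells of those two conditions (default), not by renormalizing the M-ary
confusion matrix; the renormalized variant is exposed as
`method="renormalize"` for comparison. For display, −log10(Pe) is used
with the convention that Pe = 0 maps to the sentinel 6 (and 6·ln 10 on
the natural-log scale), giving perfectly discriminated samples a finite
bar.

### Signal-to-noise ratio

The mixture SNR sums, over hypotheses, the mixture-weighted squared
norms of the component means (signal power, an uncentered second moment
in the transformed space — not variance about a grand mean) over the
mixture-weighted covariance traces (noise power):

    SNR = Σ_i [ρ_i ‖m1_i‖² + (1−ρ_i) ‖m2_i‖²]
        / Σ_i [ρ_i Tr(Σ1_i) + (1−ρ_i) Tr(Σ2_i)].

For K = 1 this reduces to the univariate mixture form, and for ρ ∈ {0,1}
to the plain Σ‖m‖²/ΣTr(Σ). The baseline hypothesis is included in both
sums — it is one of the M signals of the detection problem — with
`include_baseline=False` available for sensitivity analysis. SNR is
dimensionless; SNR_dB = 10·log10(SNR). A centered alternative (variance
of the means about their grand mean) would also be defensible but is not
what this statistic is; it is deliberately not implemented as a default.

### Cohort summaries

Group comparisons are two-sided unpaired Welch t-tests per cell type and
metric (−log10 Pe and SNR), with p-values adjusted across the family of
cell types per metric by Holm's method (uniformly valid without
independence assumptions; Šidák and Benjamini–Hochberg are options, and
a pooled-variance t-test is available via `equal_var=True`). The
error-profile heatmap matrix is cell types × subjects of −log10(Pe)
(sentinel applied), row-z-scored (population SD, ddof = 0; constant rows
are set to zero and flagged), with hierarchical clustering orders from
Euclidean distance and average linkage — common heatmap defaults,
recorded in provenance. The package emits plot-ready matrices and
linkage orders, not rendered figures.

## Inclusion filter

Populations (subject × cell type) with fewer than 200 cells are
excluded. The filter is applied per treatment jointly: a population
failing the threshold in *any* of the M conditions is dropped whole,
because the detector requires all M response matrices. The threshold and
the per-treatment reading are configurable (`min_cells`).

## Synthetic data generator

No measurement data ship with the package; the generator produces
cohorts with known ground truth that emulate the real data's structure:

- M = 6 conditions × K = 6 channels; per-population cell counts drawn
  uniformly from 200–5000 per treatment (configurable);
- log-space two-component mixtures per condition: a bright responder
  component (ρ = 0.7, mean 4.0 on non-signature channels, covariance
  0.25 with equicorrelation 0.2) shifted on the pathway's canonical
  channel(s) (IL-4 → pSTAT6 +2.0; IL-2 → pSTAT5 +2.0; IL-10 → pSTAT3
  +1.4; IL-6 → pSTAT3 +2.0 and pSTAT1 +0.6; IFNγ → pSTAT1 +2.2 and
  pSTAT3 +0.6), and a dim, broader non-responder component (mean 1.5,
  covariance 0.5) carrying 30% of the shift. IL-6/IL-10 share pSTAT3, so
  discrimination is genuinely imperfect: the default HD-like arm sits at
  Pe ≈ 0.26 — inside the range real populations span;
- raw-scale values are exp(log-space draw) + 1.0, giving log-normal-like
  fluorescence over a small additive floor. The dim component mimics
  unstimulated cells near autofluorescence and anchors the pooled
  per-channel minimum near the generation floor, so the pipeline's
  log-shift transform (whose offsets are realized data minima, not the
  generation constants) inverts generation only approximately. Recovery
  tests therefore compare fitted means against the *expected transformed
  means* E[ln(exp(Z) + c)], evaluated channel-wise by Gauss–Hermite
  quadrature (`adjusted_true_means`);
- cohort effects: means scaled by s and covariances inflated by f per
  arm — defaults s = 1, f = 1 for the HD-like arm and s = 0.6, f = 2 for
  the BC-like arm, a deliberately strong constructed deficit (SNR scales
  as s²/f ≈ 0.18×) so the qualitative HD/BC contrast is a property of
  the construction, not of tuning;
- per-subject seeds derive from the master seed by SHA-256 hashing of
  (seed, cohort, subject), keeping subjects reproducible yet independent.

The generator does **not** emulate spectral spillover, doublets, gating
errors, debris, or between-channel heteroscedasticity beyond the mixture
covariances. Passing tests on synthetic cohorts demonstrate the
correctness of the estimators under the stated generative model, not the
biological conclusions one would draw from real measurements.

Two detector-independent oracles support testing: a Monte-Carlo Bayes
error computed by direct raw-density comparison against the true models
(no fitting, no log-sum-exp), and the closed-form binary Gaussian error
Φ(−δ/2σ).

## Numerical choices and degenerate inputs

- Covariances must be symmetric within 1e−8 and positive-definite after
  regularization; Cholesky failure raises a decomposition error rather
  than silently pseudo-inverting.
- EM on fewer than 2(K+1) rows is refused; 500 identical rows with
  `reg=0` raise a degenerate-covariance error.
- A hypothesis with zero evaluated cells makes conditional probabilities
  undefined and is an error, not a NaN.
- Zero total noise power is an error; SNR_dB of 0 maps to −∞ only when
  the caller opts in.
- All randomness flows from explicit seeds; two runs with one config and
  master seed produce byte-identical output files (timings are logged,
  never written into results).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` size their simulations to run
comfortably on one CPU: 2 000–20 000 cells per condition for the
chance-level and closed-form checks, 50 replicates × 5 000 cells for EM
recovery, 100 master seeds × 20 subjects per arm × 250 cells per
treatment (single-restart EM, tolerance 1e−3, pairwise matrices off) for
the cohort-contrast property, and 30 master seeds in the acceptance
script. These sizes are the package's own verification choices; the
statistics they probe are insensitive to them beyond the quoted
standard errors.

## Known limitations

- Resubstitution optimistically biases Pe for small populations; the
  held-out option trades bias for variance and is off by default.
- The two-component mixture is fixed; no model selection over component
  counts is attempted.
- The SNR definition mixes signal "power" across hypotheses in the
  transformed space; it is a descriptive fidelity index, not a channel
  capacity, and no mutual-information quantities are computed.
- Upstream steps (compensation/unmixing, gating) are out of scope; the
  package consumes already-gated per-cell tables.
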
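# cytocomm

Communication-theoretic quantification of cytokine ligand-discrimination
specificity in immune cells, from gated phospho-flow cytometry tables.

Immune cells must identify which cytokine they are seeing from the
pattern of transcription-factor phosphorylation it evokes. `cytocomm`
treats each stimulation condition as a codeword transmitted through a
noisy channel and asks how often an optimal receiver would misidentify
the ligand. It is intended for analysts working with per-cell
phospho-readout tables (e.g. pSTAT1/3/4/5/6 and pSMAD2/3 responses to
baseline, IL-4, IL-2, IL-10, IL-6 and IFNγ) who want per-sample,
per-cell-type specificity metrics that can be compared across donors,
cohorts and perturbations (e.g. JAK1/2 inhibition).

## Model

For one subject and cell type, raw per-cell responses d are log-shift
transformed, x = ln(d − α + 1), with α the per-channel minimum pooled
over the (cell type, donor category) group. Each condition H_i
(i = 0..M−1, H_0 = baseline) is fitted with a two-component multivariate
Gaussian mixture

&nbsp;&nbsp;&nbsp;&nbsp;p(x | H_i) = ρ_i 𝒩(x; m1_i, Σ1_i) + (1−ρ_i) 𝒩(x; m2_i, Σ2_i).

The maximum-likelihood detector decides argmax_i p(x | H_i) for every
cell; counting decisions into an M×M confusion matrix Q gives the
conditional misidentification probabilities Q_ij = P(decide H_i | H_j)
and the overall **probability of error**

&nbsp;&nbsp;&nbsp;&nbsp;P_e = 1 − Σ_j P(H_j) Q_jj,&nbsp;&nbsp;P(H_j) = 1/M,

plus pairwise two-ligand error rates. Signal fidelity is summarized by
the mixture **signal-to-noise ratio**

&nbsp;&nbsp;&nbsp;&nbsp;SNR = Σ_i [ρ_i‖m1_i‖² + (1−ρ_i)‖m2_i‖²] / Σ_i [ρ_i Tr Σ1_i + (1−ρ_i) Tr Σ2_i],

reported linearly and in dB. See `docs/methods.md` for conventions,
numerical choices and the synthetic-data generator.

## Worked example

Generate a ground-truth-known synthetic cohort (two subjects per arm,
the BC-like arm constructed with reduced mean separation s = 0.6 and
doubled noise f = 2), analyze it, and summarize:

```sh
cytocomm simulate --seed 5 --n-subjects 2 2 --cells 500 --out cohort/
cytocomm analyze --manifest cohort/manifest.yaml --seed 1 --out out/
cytocomm summarize --results out/results.json --out summary/
```

`out/results.csv` then holds one row per subject × cell type:

```
subject_id,cohort,pe_equiprobable,neglog10_pe,snr,snr_db
HD000,HD,0.254,0.5951...,50.941...,17.070...
HD001,HD,0.2613...,0.5828...,49.547...,16.950...
BC000,BC,0.5106...,0.2918...,12.549...,10.986...
BC001,BC,0.5016...,0.2995...,12.588...,10.999...
```

Read: healthy-donor-like samples misidentify the ligand for about 25% of
cells (P_e ≈ 0.26, −log10 P_e ≈ 0.6) at SNR ≈ 17 dB, while the harder
BC-like arm errs on half of cells at ≈ 11 dB — the generator's
constructed deficit, recovered by the pipeline. `analyze` also writes
one pairwise −ln/raw error matrix CSV per sample and full provenance
(offsets, seeds, EM convergence) in `results.json`; `summarize` writes
the row-z-scored −log10(P_e) clustering matrix with linkage orders and a
Welch-t/Holm group-comparison table. Samples with P_e = 0 are displayed
as −log10(P_e) = 6 by convention.

The same workflow applies to real exports: point the manifest at your
per-subject × treatment × cell-type CSV files (header = channel names,
one row per gated cell); populations with fewer than 200 cells in any
treatment are excluded.

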
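"""Per-sample and cohort-level orchestration.

For each subject x cell type the pipeline runs: log-shift transform (with
offsets pooled over the sample's cell type x cohort group) -> per-hypothesis
two-component mixture fit -> maximum-likelihood detection over all cells ->
overall and pairwise error probabilities -> mixture SNR. Cohort summaries
cover the derived display matrices (row-z-scored -log10 Pe for clustering)
and Welch t-test group comparisons with Holm adjustment.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .datamodel import Cohort, CohortDataset, SampleDataset
from .detection import (
    SENTINEL_NEGLOG10,
    ErrorSummary,
    HypothesisModelSet,
    estimate_confusion,
    error_probability,
    neglog_display,
    pairwise_error_matrix,
)
from .errors import InsufficientGroupError
from .gmm import DEFAULT_MAX_ITER, DEFAULT_N_INIT, DEFAULT_TOL, fit_gm2
from .preprocess import TransformParams, offsets_for_samples, transform_sample
from .snr import SnrResult, snr_gm
from .synthetic import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class AnalysisSettings:
    """Tunable knobs of one analysis run; recorded in result provenance."""

    seed: int = 0
    n_init: int = DEFAULT_N_INIT
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    reg: float | None = None
    weighting: str = "equiprobable"
    min_cells: int = 200
    include_pairwise: bool = True
    pairwise_method: str = "binary"
    holdout_fraction: float = 0.0  # 0 = resubstitution (default evaluation scheme)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DetectionResult:
    """Pe, SNR and provenance for one subject x cell type."""

    subject_id: str
    cohort: str
    cell_type: str
    error_summary: ErrorSummary
    pe_empirical: float
    snr: SnrResult
    n_cells: dict[int, int]
    treatment_labels: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def pe(self) -> float:
        return self.error_summary.pe

    @property
    def neglog10_pe(self) -> float:
        return neglog_display(self.pe, base=10)

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "cohort": self.cohort,
            "cell_type": self.cell_type,
            "pe_equiprobable": self.error_summary.pe,
            "pe_empirical": self.pe_empirical,
            "neglog10_pe": self.neglog10_pe,
            "snr": self.snr.snr_linear,
            "snr_db": self.snr.snr_db,
        }
        for i, lbl in enumerate(self.treatment_labels):
            row[f"n_cells_{lbl}"] = self.n_cells[i]
        return row


def run_sample_analysis(sample: SampleDataset, offsets: TransformParams,
                        settings: AnalysisSettings | None = None,
                        ) -> DetectionResult:
    """Full detection analysis of one sample; deterministic given settings.seed."""
    settings = settings or AnalysisSettings()
    t0 = time.perf_counter()
    transformed = transform_sample(sample, offsets)

    eval_data = transformed
    fit_data = transformed
    if settings.holdout_fraction > 0:
        fit_data, eval_data = {}, {}
        for i, X in transformed.items():
            rng = np.random.default_rng(derive_seed(settings.seed, "split", i))
            perm = rng.permutation(X.shape[0])
            n_fit = max(int(round((1 - settings.holdout_fraction) * X.shape[0])), 1)
            fit_data[i] = X[perm[:n_fit]]
            eval_data[i] = X[perm[n_fit:]]

    models = []
    for i in sorted(fit_data):
        models.append(
            fit_gm2(
                fit_data[i],
                seed=derive_seed(settings.seed, sample.subject_id,
                                 sample.cell_type, i),
                reg=settings.reg,
                n_init=settings.n_init,
                tol=settings.tol,
                max_iter=settings.max_iter,
                hypothesis_index=i,
            )
        )
    model_set = HypothesisModelSet(models)
    cm = estimate_confusion(eval_data, model_set, sample.treatment_labels)
    summary = error_probability(cm, weighting=settings.weighting)
    pe_emp = error_probability(cm, weighting="empirical").pe
    if settings.include_pairwise:
        summary.pairwise_pe = pairwise_error_matrix(
            eval_data, model_set, method=settings.pairwise_method
        )
    snr = snr_gm(model_set)
    elapsed = time.perf_counter() - t0
    logger.info("analyzed %s/%s/%s in %.2fs (pe=%.4g, snr_db=%.2f)",
                sample.cohort.value, sample.subject_id, sample.cell_type,
                elapsed, summary.pe, snr.snr_db)
    return DetectionResult(
        subject_id=sample.subject_id,
        cohort=sample.cohort.value,
        cell_type=sample.cell_type,
        error_summary=summary,
        pe_empirical=pe_emp,
        snr=snr,
        n_cells=sample.n_cells,
        treatment_labels=sample.treatment_labels,
        provenance={
            "offsets": offsets.to_dict(),
            "settings": settings.to_dict(),
            "fit_meta": {m.hypothesis_index: dict(m.fit_meta) for m in models},
        },
    )


def run_cohort_analysis(dataset: CohortDataset,
                        settings: AnalysisSettings | None = None,
                        ) -> list[DetectionResult]:
    """Analyze every sample, pooling transform offsets per (cell type, cohort).

    A failing sample is reported (logged with its context) and skipped, never
    silently dropped; its error is re-raised at the end if nothing succeeded.
    """
    settings = settings or AnalysisSettings()
    results: list[DetectionResult] = []
    first_error: Exception | None = None
    for (cell_type, cohort), group in dataset.group_by("cell_type", "cohort").items():
        offsets = offsets_for_samples(group, scope_key=(cell_type, cohort))
        for sample in group:
            try:
                results.append(run_sample_analysis(sample, offsets, settings))
            except Exception as exc:  # report with context, keep going
                logger.error("sample %s/%s/%s failed: %s", cohort,
                             sample.subject_id, cell_type, exc)
                first_error = first_error or exc
    if not results and first_error is not None:
        raise first_error
    return results


def results_to_table(results: Sequence[DetectionResult]) -> pd.DataFrame:
    """Tidy one-row-per-sample table of the scalar results."""
    return pd.DataFrame([r.to_row() for r in results])


@dataclass
class CohortSummaryTable:
    """Plot-ready matrices for the cohort-level error-profile heatmap."""

    matrix: pd.DataFrame          # cell_type x subject, -log10(Pe) with sentinel
    zscored: pd.DataFrame         # row-z-scored version (constant rows -> 0)
    row_order: list[str]
    col_order: list[str]
    constant_rows: list[str]
    missing: list[tuple[str, str]]


def build_cluster_matrix(results: Sequence[DetectionResult],
                         metric_col: str = "neglog10_pe",
                         ) -> CohortSummaryTable:
    """Cell-type x subject matrix of -log10(Pe), row-z-scored and
    hierarchically clustered (Euclidean distance, average linkage).

    Subjects missing a cell type are flagged and excluded from clustering.
    Constant rows cannot be z-scored; they are set to zero and flagged.
    """
    df = results_to_table(list(results))
    if df["subject_id"].nunique() < 2 or df["cell_type"].nunique() < 2:
        raise ValueError("clustering needs at least 2 subjects and 2 cell types")
    mat = df.pivot_table(index="cell_type", columns="subject_id",
                         values=metric_col, aggfunc="first")
    missing = [
        (ct, subj)
        for ct in mat.index for subj in mat.columns
        if pd.isna(mat.loc[ct, subj])
    ]
    complete = mat.dropna(axis=1)
    means = complete.mean(axis=1)
    sds = complete.std(axis=1, ddof=0)
    constant = sds.index[sds == 0].tolist()
    if constant:
        logger.warning("degenerate clustering rows (constant): %s", constant)
    safe_sd = sds.replace(0.0, 1.0)
    z = complete.sub(means, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    if z.shape[0] >= 2 and z.shape[1] >= 2 and float(z.to_numpy().std()) > 0:
        row_order = [z.index[i] for i in
                     leaves_list(linkage(z.to_numpy(), method="average",
                                         metric="euclidean"))]
        col_order = [z.columns[i] for i in
                     leaves_list(linkage(z.to_numpy().T, method="average",
                                         metric="euclidean"))]
    else:
        logger.warning("matrix is constant; clustering order is input order")
        row_order, col_order = list(z.index), list(z.columns)
    return CohortSummaryTable(
        matrix=mat, zscored=z, row_order=row_order, col_order=col_order,
        constant_rows=constant, missing=missing,
    )


def compare_groups(results: Sequence[DetectionResult], group_a: str, group_b: str,
                   metrics: tuple[str, ...] = ("neglog10_pe", "snr"),
                   adjust: str = "holm", equal_var: bool = False,
                   ) -> pd.DataFrame:
    """Per-cell-type two-sided unpaired t-tests between two cohorts.

    Welch's t-test by default (``equal_var=True`` for the pooled-variance
    variant); p-values are adjusted across the family of cell types
    separately for each metric (Holm default; 'sidak' and 'fdr_bh'
    available).
    """
    df = results_to_table(list(results))
    rows = []
    cell_types = sorted(df["cell_type"].unique())
    for metric in metrics:
        metric_rows = []
        for ct in cell_types:
            a = df.loc[(df.cohort == group_a) & (df.cell_type == ct), metric]
            b = df.loc[(df.cohort == group_b) & (df.cell_type == ct), metric]
            if len(a) < 2 or len(b) < 2:
                raise InsufficientGroupError(
                    f"cell type '{ct}': groups must each have >= 2 samples "
                    f"(got {len(a)} vs {len(b)})"
                )
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            if np.isnan(p):  # zero variance in both groups with equal means
                t, p = 0.0, 1.0
            metric_rows.append(
                {
                    "metric": metric,
                    "cell_type": ct,
                    "mean_a": float(a.mean()),
                    "mean_b": float(b.mean()),
                    "n_a": len(a),
                    "n_b": len(b),
                    "t": float(t),
                    "p_raw": float(p),
                }
            )
        p_adj = multipletests([r["p_raw"] for r in metric_rows], method=adjust)[1]
        for r, pa in zip(metric_rows, p_adj):
            r["p_adj"] = float(pa)
        rows.extend(metric_rows)
    out = pd.DataFrame(rows)
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    out.attrs["adjust"] = adjust
    return out
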
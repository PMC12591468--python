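"""Reading, writing and filtering of gated per-cell response tables.

One CSV file holds the cells of a single subject x treatment x cell type:
a header row of channel names and one row per gated cell. A YAML/JSON
manifest maps sample metadata to the M per-treatment files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DEFAULT_PANEL,
    DEFAULT_TREATMENTS,
    ChannelPanel,
    Cohort,
    CohortDataset,
    ResponseMatrix,
    SampleDataset,
)
from .errors import (
    DuplicateKeyError,
    EmptyInputError,
    IncompleteSampleError,
    ParseError,
    PanelMismatchError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Populations with fewer cells than this in any treatment are excluded.
DEFAULT_MIN_CELLS = 200


def read_response_csv(path: str | os.PathLike, panel: ChannelPanel = DEFAULT_PANEL,
                      treatment_index: int = 0) -> ResponseMatrix:
    """Read one per-cell response table.

    Columns are reordered to the panel order; extra columns (surface
    markers etc. carried along by flow exports) are ignored with a warning.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    missing = [c for c in panel.channel_names if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing channel column(s) {missing}")
    extra = [c for c in df.columns if c not in panel.channel_names]
    if extra:
        logger.warning("%s: ignoring %d non-panel column(s): %s", path, len(extra), extra)
    sub = df[list(panel.channel_names)]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric or missing value at data row {r}, "
            f"column '{panel.channel_names[c]}'",
            row=int(r),
        )
    return ResponseMatrix(numeric.to_numpy(dtype=float), treatment_index, panel)


def write_response_csv(matrix: ResponseMatrix, path: str | os.PathLike) -> None:
    """Write a response matrix in the same dialect :func:`read_response_csv` reads."""
    pd.DataFrame(matrix.values, columns=list(matrix.panel.channel_names)).to_csv(
        path, index=False
    )


def assemble_dataset(files: Mapping[int, str | os.PathLike], *, subject_id: str,
                     cohort: Cohort | str, cell_type: str,
                     panel: ChannelPanel = DEFAULT_PANEL,
                     treatment_labels: tuple[str, ...] = DEFAULT_TREATMENTS,
                     ) -> SampleDataset:
    """Read the M per-treatment files of one sample into a :class:`SampleDataset`."""
    M = len(treatment_labels)
    keys = [int(k) for k in files]
    if len(set(keys)) != len(keys):
        raise DuplicateKeyError(f"duplicate treatment index in {sorted(keys)}")
    missing = sorted(set(range(M)) - set(keys))
    if missing or len(keys) != M:
        raise IncompleteSampleError(
            f"sample {subject_id}/{cell_type}: expected treatments 0..{M - 1}, "
            f"missing {missing or sorted(set(keys) - set(range(M)))}"
        )
    responses = {
        int(i): read_response_csv(p, panel=panel, treatment_index=int(i))
        for i, p in files.items()
    }
    return SampleDataset(subject_id, Cohort(cohort), cell_type, responses,
                         treatment_labels)


@dataclass
class FilterReport:
    """Populations removed by the minimum-cell-count filter."""

    min_cells: int
    dropped: list[dict] = field(default_factory=list)
    n_kept: int = 0

    @property
    def empty_result(self) -> bool:
        return self.n_kept == 0


def filter_min_cells(dataset: SampleDataset | CohortDataset,
                     min_cells: int = DEFAULT_MIN_CELLS,
                     ) -> tuple[SampleDataset | CohortDataset | None, FilterReport]:
    """Apply the minimum-population-size inclusion rule.

    A population (subject x cell type) is kept only if it has at least
    ``min_cells`` cells in *every* treatment; the detector needs all M
    conditions, so a population failing in any one of them is dropped whole.
    Returns the filtered dataset (``None`` for a dropped single sample)
    and a report of the dropped populations.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    report = FilterReport(min_cells=min_cells)

    def keep(s: SampleDataset) -> bool:
        if s.min_cells() >= min_cells:
            return True
        report.dropped.append(
            {
                "subject_id": s.subject_id,
                "cohort": s.cohort.value,
                "cell_type": s.cell_type,
                "min_treatment_cells": s.min_cells(),
            }
        )
        return False

    if isinstance(dataset, SampleDataset):
        kept = dataset if keep(dataset) else None
        report.n_kept = int(kept is not None)
        return kept, report
    filtered = CohortDataset([s for s in dataset if keep(s)])
    report.n_kept = len(filtered)
    if report.empty_result:
        logger.warning("filter_min_cells(%d) removed every population", min_cells)
    return filtered, report


def load_manifest(path: str | os.PathLike,
                  ) -> tuple[ChannelPanel, tuple[str, ...], list[dict]]:
    """Load a dataset manifest (YAML or JSON).

    The manifest holds optional ``panel`` and ``treatments`` lists plus a
    ``samples`` list; each sample entry gives subject_id, cohort, cell_type
    and a ``files`` mapping of treatment index -> CSV path (relative paths
    are resolved against the manifest location).
    """
    path = os.fspath(path)
    with open(path) as fh:
        doc = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    if not isinstance(doc, dict) or "samples" not in doc:
        raise SchemaError(f"{path}: manifest must be a mapping with a 'samples' list")
    panel = ChannelPanel(tuple(doc.get("panel", DEFAULT_PANEL.channel_names)))
    treatments = tuple(doc.get("treatments", DEFAULT_TREATMENTS))
    base = os.path.dirname(os.path.abspath(path))
    entries = []
    for rec in doc["samples"]:
        files = {
            int(i): p if os.path.isabs(str(p)) else os.path.join(base, str(p))
            for i, p in rec["files"].items()
        }
        entries.append(
            {
                "subject_id": str(rec["subject_id"]),
                "cohort": str(rec["cohort"]),
                "cell_type": str(rec["cell_type"]),
                "files": files,
            }
        )
    return panel, treatments, entries


def read_manifest_dataset(path: str | os.PathLike) -> CohortDataset:
    """Assemble every sample listed in a manifest into a :class:`CohortDataset`."""
    panel, treatments, entries = load_manifest(path)
    samples = [
        assemble_dataset(
            e["files"],
            subject_id=e["subject_id"],
            cohort=e["cohort"],
            cell_type=e["cell_type"],
            panel=panel,
            treatment_labels=treatments,
        )
        for e in entries
    ]
    return CohortDataset(samples)
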
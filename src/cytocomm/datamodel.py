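"""Core data containers for gated per-cell phospho-response tables.

A *sample* is one subject x cell type; it holds one response matrix per
stimulation condition (hypothesis). Treatment index 0 is always the
unstimulated baseline; the default order of the remaining conditions is
IL-4, IL-2, IL-10, IL-6, IFN-gamma, and this order is recorded in output
metadata so confusion matrices are comparable across runs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import PanelMismatchError

#: Default readout panel: five phosphorylated STATs plus phosphorylated SMAD2/3.
DEFAULT_CHANNELS = ("pSTAT1", "pSTAT3", "pSTAT4", "pSTAT5", "pSTAT6", "pSMAD2/3")

#: Default hypothesis order: H0 baseline, then the five cytokines.
DEFAULT_TREATMENTS = ("untreated", "IL-4", "IL-2", "IL-10", "IL-6", "IFNg")


class Cohort(str, enum.Enum):
    """Donor category: healthy donor, breast cancer, or JAK1/2-inhibited HD."""

    HD = "HD"
    BC = "BC"
    HD_RUX = "HD_RUX"


@dataclass(frozen=True)
class ChannelPanel:
    """Ordered set of K readout channels."""

    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self):
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if len(names) < 1:
            raise ValueError("panel needs at least one channel")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    @property
    def K(self) -> int:
        return len(self.channel_names)


DEFAULT_PANEL = ChannelPanel()


@dataclass
class ResponseMatrix:
    """Per-cell raw fluorescence for one treatment: N_i cells x K channels."""

    values: np.ndarray
    treatment_index: int
    panel: ChannelPanel = DEFAULT_PANEL

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array of shape (n_cells, K)")
        if self.values.shape[1] != self.panel.K:
            raise PanelMismatchError(
                f"matrix has {self.values.shape[1]} columns but panel has "
                f"K={self.panel.K}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response matrix contains non-finite entries")
        if self.treatment_index < 0:
            raise ValueError("treatment_index must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class SampleDataset:
    """All M treatment responses for one subject x cell type."""

    subject_id: str
    cohort: Cohort
    cell_type: str
    responses: dict[int, ResponseMatrix]
    treatment_labels: tuple[str, ...] = DEFAULT_TREATMENTS

    def __post_init__(self):
        self.cohort = Cohort(self.cohort)
        self.treatment_labels = tuple(self.treatment_labels)
        if self.M < 2:
            raise ValueError("a sample needs at least two treatment conditions")
        expected = set(range(self.M))
        if set(self.responses) != expected:
            raise ValueError(
                f"responses must cover treatment indices 0..{self.M - 1}"
            )
        panels = {rm.panel.channel_names for rm in self.responses.values()}
        if len(panels) != 1:
            raise PanelMismatchError("all treatments must share one channel panel")

    @property
    def M(self) -> int:
        return len(self.treatment_labels)

    @property
    def panel(self) -> ChannelPanel:
        return self.responses[0].panel

    @property
    def n_cells(self) -> dict[int, int]:
        return {i: rm.n_cells for i, rm in self.responses.items()}

    def min_cells(self) -> int:
        """Smallest per-treatment cell count (governs the inclusion filter)."""
        return min(rm.n_cells for rm in self.responses.values())


@dataclass
class CohortDataset:
    """A collection of samples spanning subjects, cohorts and cell types."""

    samples: list[SampleDataset] = field(default_factory=list)

    def __post_init__(self):
        seen: set[tuple[str, str, str]] = set()
        for s in self.samples:
            key = (s.cohort.value, s.subject_id, s.cell_type)
            if key in seen:
                raise ValueError(f"duplicate sample {key} within cohort dataset")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def group_by(self, *keys: str) -> dict[tuple, list[SampleDataset]]:
        """Group samples by attribute names, e.g. ``group_by('cell_type', 'cohort')``."""
        out: dict[tuple, list[SampleDataset]] = {}
        for s in self.samples:
            k = tuple(
                getattr(s, key).value if key == "cohort" else getattr(s, key)
                for key in keys
            )
            out.setdefault(k, []).append(s)
        return out

    def subset(self, cohort: Cohort | str | None = None,
               cell_type: str | None = None) -> "CohortDataset":
        picked = [
            s for s in self.samples
            if (cohort is None or s.cohort == Cohort(cohort))
            and (cell_type is None or s.cell_type == cell_type)
        ]
        return CohortDataset(picked)
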
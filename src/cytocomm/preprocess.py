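"""Log-shift transform of raw fluorescence.

Raw phospho-readouts are heavy-tailed (approximately log-normal). Each
channel k is mapped to x = ln(d - alpha_k + 1), where alpha_k is the
minimum of channel k pooled over every cell, treatment and subject of one
(cell type, donor category) group. The shift guarantees the log argument
is >= 1, so transformed values are nonnegative with an exact zero at the
pooled minimum. "log" is the natural logarithm throughout: downstream
mixture densities are base-free, only the monotone mapping matters, but
the convention is fixed here.

The offset is pooled across treatments (a treatment-dependent transform
would distort comparisons between hypotheses) and, by default, across
subjects within the donor category.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datamodel import ChannelPanel, ResponseMatrix, SampleDataset
from .errors import EmptyInputError, OffsetViolationError, PanelMismatchError


@dataclass(frozen=True)
class TransformParams:
    """Per-channel offsets alpha for one (cell type, cohort) pooling group."""

    alpha: np.ndarray
    scope_key: tuple[str, str]  # (cell_type, cohort)
    channel_names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        if self.alpha.ndim != 1 or not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha must be a finite 1-D vector")
        if len(self.channel_names) != self.alpha.shape[0]:
            raise ValueError("alpha length must match the channel panel")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "scope_key": list(self.scope_key),
            "channel_names": list(self.channel_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformParams":
        return cls(np.asarray(d["alpha"], float), tuple(d["scope_key"]),
                   tuple(d["channel_names"]))

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TransformParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compute_offsets(group: Iterable[ResponseMatrix],
                    scope_key: tuple[str, str] = ("", "")) -> TransformParams:
    """Pooled per-channel minima over all matrices of one pooling group."""
    matrices = list(group)
    if not matrices:
        raise EmptyInputError("cannot compute offsets from an empty group")
    panels = {m.panel.channel_names for m in matrices}
    if len(panels) != 1:
        raise PanelMismatchError("offset group mixes channel panels")
    alpha = np.min([m.values.min(axis=0) for m in matrices], axis=0)
    return TransformParams(alpha, scope_key, matrices[0].panel.channel_names)


def offsets_for_samples(samples: Sequence[SampleDataset],
                        scope_key: tuple[str, str] | None = None) -> TransformParams:
    """Offsets pooled over every treatment of every sample in one group."""
    mats = [rm for s in samples for rm in s.responses.values()]
    if scope_key is None and samples:
        scope_key = (samples[0].cell_type, samples[0].cohort.value)
    return compute_offsets(mats, scope_key or ("", ""))


def log_shift_transform(matrix: ResponseMatrix | np.ndarray,
                        params: TransformParams) -> np.ndarray:
    """x = ln(d - alpha + 1), element-wise; all outputs >= 0 within the group."""
    values = matrix.values if isinstance(matrix, ResponseMatrix) else np.asarray(matrix, float)
    if values.shape[1] != params.alpha.shape[0]:
        raise PanelMismatchError("matrix width does not match offset vector")
    shifted = values - params.alpha
    if np.any(shifted < 0):
        r, c = np.argwhere(shifted < 0)[0]
        raise OffsetViolationError(
            f"measurement below offset at cell {r}, channel "
            f"'{params.channel_names[c]}' ({values[r, c]} < {params.alpha[c]})"
        )
    return np.log1p(shifted)


def transform_sample(sample: SampleDataset,
                     params: TransformParams) -> dict[int, np.ndarray]:
    """Transform every treatment matrix of one sample; keys are hypothesis indices."""
    return {i: log_shift_transform(rm, params) for i, rm in sample.responses.items()}
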
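"""Gaussian-mixture signal-to-noise ratio.

The signaling system is viewed as a transmitter of M codewords (one per
stimulation condition). Under hypothesis H_i the transmitted signal is
m1_i with probability rho_i and m2_i otherwise, corrupted by zero-mean
Gaussian noise with covariance Sigma1_i or Sigma2_i respectively. Signal
power is the mixture-weighted sum of squared mean norms; noise power is
the mixture-weighted sum of covariance traces:

    SNR = sum_i [rho_i |m1_i|^2 + (1-rho_i) |m2_i|^2]
          / sum_i [rho_i Tr(Sigma1_i) + (1-rho_i) Tr(Sigma2_i)]

Note the signal power uses uncentered second moments of the mixture means
(in the same log-transformed space in which detection operates), not the
variance around a grand mean. SNR is dimensionless; it is conventionally
reported in decibels, SNR_dB = 10 log10(SNR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateNoiseError, DomainError
from .gmm import GMParams
from .detection import HypothesisModelSet


@dataclass(frozen=True)
class SnrResult:
    snr_linear: float
    snr_db: float
    signal_power: float
    noise_power: float


def snr_gm(models: HypothesisModelSet | Sequence[GMParams],
           include_baseline: bool = True) -> SnrResult:
    """Mixture SNR over all hypotheses of one fitted sample.

    The baseline (hypothesis 0) is one of the M signals of the detection
    problem and is included by default; ``include_baseline=False`` drops
    it for sensitivity analysis.
    """
    params = models.models if isinstance(models, HypothesisModelSet) else list(models)
    if not include_baseline:
        params = params[1:]
    if not params:
        raise ValueError("need at least one hypothesis model")
    signal = 0.0
    noise = 0.0
    for p in params:
        signal += p.rho * float(p.comp1.mean @ p.comp1.mean)
        signal += (1.0 - p.rho) * float(p.comp2.mean @ p.comp2.mean)
        noise += p.rho * float(np.trace(p.comp1.cov))
        noise += (1.0 - p.rho) * float(np.trace(p.comp2.cov))
    if noise <= 0.0:
        raise DegenerateNoiseError("total noise power is zero; SNR undefined")
    lin = signal / noise
    db = snr_to_db(lin) if lin > 0 else float("-inf")
    return SnrResult(snr_linear=lin, snr_db=db, signal_power=signal,
                     noise_power=noise)


def snr_to_db(snr_linear: float, allow_zero: bool = False) -> float:
    """Decibel conversion 10 log10(SNR); SNR must be positive.

    ``allow_zero=True`` opts in to mapping 0 to -inf instead of raising.
    """
    if snr_linear < 0 or (snr_linear == 0 and not allow_zero):
        raise DomainError(f"snr_linear must be positive, got {snr_linear}")
    if snr_linear == 0:
        return float("-inf")
    return float(10.0 * np.log10(snr_linear))


def snr_from_db(snr_db: float) -> float:
    """Inverse of :func:`snr_to_db`."""
    return float(10.0 ** (snr_db / 10.0))
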
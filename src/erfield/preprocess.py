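"""Recording quality control and light-response cell classification.

Operates on already-extracted summaries: a mean spike waveform with a noise
SD for the signal-to-noise check, and per-repeat firing rates during light
on/off periods (plus 1-s transition transients) for ON / OFF / ON-OFF
classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import f_oneway

SNR_DISCARD_THRESHOLD = 4.0


@dataclass(frozen=True)
class WaveformSummary:
    mean_waveform: np.ndarray        # uV
    noise_sd: float                  # uV


@dataclass(frozen=True)
class LightResponse:
    """Per-repeat spike rates (spikes/s) for light-step stimulation."""

    on_rates: np.ndarray
    off_rates: np.ndarray
    on_transient: np.ndarray         # rate in the 1 s after light-on
    off_transient: np.ndarray        # rate in the 1 s after light-off


class CellClass(str, Enum):
    ON = "ON"
    OFF = "OFF"
    ON_OFF = "ON_OFF"
    UNCLASSIFIED = "UNCLASSIFIED"


def snr(w: WaveformSummary) -> float:
    """Peak-to-peak spike amplitude over twice the noise SD."""
    wave = np.asarray(w.mean_waveform, dtype=float)
    if wave.size == 0:
        raise ValueError("empty waveform")
    if w.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    return float((wave.max() - wave.min()) / (2.0 * w.noise_sd))


def passes_qc(w: WaveformSummary, threshold: float = SNR_DISCARD_THRESHOLD) -> bool:
    """Recordings below the SNR threshold are discarded."""
    return snr(w) >= threshold


def _significant_increase(sample: np.ndarray, baseline: np.ndarray,
                          alpha: float) -> bool:
    sample = np.asarray(sample, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.allclose(sample, sample.mean()) and np.allclose(baseline, baseline.mean()):
        return False
    stat, p = f_oneway(sample, baseline)
    return bool(p < alpha and sample.mean() > baseline.mean())


def classify_light_response(lr: LightResponse, alpha: float = 0.05) -> CellClass:
    """ON / OFF / ON-OFF classification from light-step responses.

    One-way ANOVA at level ``alpha`` compares on- vs off-period rates, and
    each 1-s transition transient against the pooled steady-state rates.
    Both transients elevated -> ON_OFF; otherwise a significant transient
    takes precedence over the mean-rate comparison (ON for the light-on
    transient, OFF for the light-off one); classification is invariant to
    uniform rate scaling.  Fewer than 2 repeats per condition ->
    UNCLASSIFIED.
    """
    arrays = [np.asarray(a, dtype=float) for a in
              (lr.on_rates, lr.off_rates, lr.on_transient, lr.off_transient)]
    if any(a.size < 2 for a in arrays):
        return CellClass.UNCLASSIFIED
    on, off, on_tr, off_tr = arrays
    steady = np.concatenate([on, off])
    on_transient_sig = _significant_increase(on_tr, steady, alpha)
    off_transient_sig = _significant_increase(off_tr, steady, alpha)
    if on_transient_sig and off_transient_sig:
        return CellClass.ON_OFF
    if on_transient_sig:
        return CellClass.ON
    if off_transient_sig:
        return CellClass.OFF
    if _significant_increase(on, off, alpha):
        return CellClass.ON
    if _significant_increase(off, on, alpha):
        return CellClass.OFF
    return CellClass.UNCLASSIFIED
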
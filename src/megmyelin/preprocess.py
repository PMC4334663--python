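"""Sensor-space preprocessing of epoched MEG data.

Implements the evoked-response chain: peak-to-peak artifact rejection
(5 pT default), trial averaging, zero-phase 20 Hz low-pass filtering,
baseline correction to the 100 ms preceding the noise-to-pitch
transition, and peak-latency detection on global field power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .reference import ARTIFACT_THRESHOLD_T, BASELINE_S, LOWPASS_HZ


class PreprocessError(ValueError):
    pass


@dataclass
class EpochSet:
    """Epoched sensor data: trials x channels x samples, tesla.

    ``t0_s`` is the epoch start relative to stimulus onset and
    ``transition_s`` the within-epoch time of the noise-to-pitch
    transition (also relative to stimulus onset).
    """

    data: np.ndarray
    sfreq_hz: float
    t0_s: float
    transition_s: float
    rejected: np.ndarray | None = None  # bool per original trial

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise PreprocessError("epoch data must be trials x channels x samples")
        if self.sfreq_hz <= 0:
            raise PreprocessError("sampling frequency must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.data.shape[2]) / self.sfreq_hz

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class EvokedField:
    """Trial-averaged field: channels x samples, with provenance."""

    data: np.ndarray
    sfreq_hz: float
    t0_s: float
    transition_s: float
    n_trials_used: int
    processing: tuple = field(default_factory=tuple)

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.data.shape[1]) / self.sfreq_hz


def reject_artifacts(epochs: EpochSet, threshold_T: float = ARTIFACT_THRESHOLD_T) -> EpochSet:
    """Drop trials whose worst-channel peak-to-peak amplitude exceeds the threshold."""
    if threshold_T <= 0:
        raise PreprocessError("rejection threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    bad = ptp.max(axis=1) > threshold_T
    if bad.all():
        raise PreprocessError(
            f"all {epochs.n_trials} trials exceed the {threshold_T:g} T "
            "peak-to-peak threshold; nothing left to average"
        )
    return replace(epochs, data=epochs.data[~bad], rejected=bad)


def average_epochs(epochs: EpochSet) -> EvokedField:
    """Arithmetic mean over retained trials."""
    if epochs.n_trials == 0:
        raise PreprocessError("no trials to average")
    return EvokedField(
        data=epochs.data.mean(axis=0),
        sfreq_hz=epochs.sfreq_hz,
        t0_s=epochs.t0_s,
        transition_s=epochs.transition_s,
        n_trials_used=epochs.n_trials,
        processing=("average",),
    )


def lowpass(evoked: EvokedField, cutoff_hz: float = LOWPASS_HZ, order: int = 4) -> EvokedField:
    """Zero-phase (forward-backward) Butterworth low-pass."""
    nyq = evoked.sfreq_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise PreprocessError(f"cutoff must be in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=evoked.sfreq_hz, output="sos")
    out = signal.sosfiltfilt(sos, evoked.data, axis=1)
    return replace(
        evoked,
        data=out,
        processing=evoked.processing + (f"lowpass:{cutoff_hz}Hz:order{order}:zero-phase",),
    )


def baseline_correct(evoked: EvokedField, window_s: float = BASELINE_S) -> EvokedField:
    """Subtract, per channel, the mean over the window preceding the transition."""
    t = evoked.times
    sel = (t >= evoked.transition_s - window_s) & (t < evoked.transition_s)
    if not sel.any():
        raise PreprocessError("baseline window lies outside the epoch")
    out = evoked.data - evoked.data[:, sel].mean(axis=1, keepdims=True)
    return replace(
        evoked,
        data=out,
        processing=evoked.processing + (f"baseline:{window_s * 1e3:g}ms-pre-transition",),
    )


def decimate(epochs: EpochSet, factor: int) -> EpochSet:
    """Anti-aliased decimation (zero-phase FIR) by an integer factor."""
    if factor < 1:
        raise PreprocessError("decimation factor must be >= 1")
    if factor == 1:
        return epochs
    out = signal.decimate(epochs.data, factor, axis=2, ftype="fir", zero_phase=True)
    return replace(epochs, data=out, sfreq_hz=epochs.sfreq_hz / factor)


def global_field_power(evoked: EvokedField) -> np.ndarray:
    """Root-mean-square over channels at each sample."""
    return np.sqrt(np.mean(evoked.data**2, axis=0))


def find_peak_latency(evoked: EvokedField, search_window_s: tuple[float, float]) -> tuple[float, int]:
    """Time and sample index of maximal global field power in a window.

    The window is given relative to stimulus onset and should lie after
    the transition.  Flat signals tie-break to the earliest sample.
    """
    t = evoked.times
    lo, hi = search_window_s
    sel = np.where((t >= lo) & (t <= hi))[0]
    if sel.size == 0:
        raise PreprocessError("empty peak search window")
    gfp = global_field_power(evoked)[sel]
    if np.ptp(gfp) == 0:
        warnings.warn("flat global field power in search window; returning earliest sample")
    idx = sel[int(np.argmax(gfp))]  # argmax returns first maximum -> earliest tie
    return float(t[idx]), int(idx)
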
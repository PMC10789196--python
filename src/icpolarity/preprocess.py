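"""Preprocessing: windowed-FIR high-pass filtering and full-rank average reference.

The high-pass filter is a zero-phase Hamming-window FIR whose cutoff frequency
is the -6 dB point (default 1.5 Hz, transition bandwidth 1 Hz), applied as a
forward convolution with group-delay compensation.

The full-rank average reference recovers the initial reference electrode: a
channel of continuous zeros is appended for it, and every sample is then
re-referenced to the mean over all channels including the appended one.  The
recovered reference channel equals minus the mean of the original channels at
every sample, and the per-sample mean of the output is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .head_model import make_montage
from .synthetic_data import SensorRecording

__all__ = ["FilterSpec", "design_highpass", "highpass", "fullrank_average_reference"]


@dataclass(frozen=True)
class FilterSpec:
    """Hamming-window FIR high-pass: ``cutoff_hz`` is the -6 dB frequency."""

    cutoff_hz: float = 1.5
    transition_bw_hz: float = 1.0
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not self.cutoff_hz - self.transition_bw_hz / 2.0 > 0:
            raise ValueError("cutoff - transition_bw/2 must be positive")

    def order(self, sampling_rate: float) -> int:
        """Filter order: ceil(3.3 / normalized transition bandwidth), made even."""
        n = int(np.ceil(3.3 / (self.transition_bw_hz / sampling_rate)))
        return n + (n % 2)


def design_highpass(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """FIR taps (odd length = order + 1), -6 dB at ``spec.cutoff_hz``."""
    if not sampling_rate > 2.0 * (spec.cutoff_hz + spec.transition_bw_hz):
        raise ValueError("sampling rate too low for the requested cutoff")
    numtaps = spec.order(sampling_rate) + 1
    # Spectral inversion of a unit-DC-gain lowpass: exact null at DC and
    # gain exactly 0.5 (-6 dB) at the cutoff.
    lowpass = signal.firwin(numtaps, spec.cutoff_hz, window=spec.window,
                            pass_zero=True, fs=sampling_rate)
    taps = -lowpass
    taps[numtaps // 2] += 1.0
    return taps


def highpass(rec: SensorRecording, spec: FilterSpec | None = None) -> SensorRecording:
    """Zero-phase high-pass: forward FIR convolution, group delay compensated."""
    spec = spec or FilterSpec()
    taps = design_highpass(spec, rec.sampling_rate)
    order = len(taps) - 1
    if rec.n_samples < 3 * order:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than 3x filter order ({order})"
        )
    # Edge-replication padding keeps boundary transients out of the output
    # (a constant signal maps to exactly zero everywhere).
    padded = np.pad(rec.data, ((0, 0), (order, order)), mode="edge")
    full = signal.fftconvolve(padded, taps[None, :], mode="full")
    delay = order // 2
    filtered = full[:, order + delay:order + delay + rec.n_samples]
    return SensorRecording(data=filtered, electrodes=list(rec.electrodes),
                           sampling_rate=rec.sampling_rate,
                           ground_truth=rec.ground_truth)


def fullrank_average_reference(rec: SensorRecording,
                               initial_ref_label: str = "FCz") -> SensorRecording:
    """Recover the initial reference and re-reference to the all-channel mean.

    Appends a zero channel for ``initial_ref_label`` (placed at its idealized
    10-10 site) and subtracts the mean over all n+1 channels from every sample.
    The output has n+1 channels, per-sample mean exactly zero, and the same
    rank as the input.
    """
    if initial_ref_label in rec.labels:
        raise ValueError(
            f"initial reference {initial_ref_label!r} collides with a data channel"
        )
    radius = float(np.linalg.norm(rec.electrodes[0].position)) if rec.electrodes else 85.0
    ref_electrode = make_montage([initial_ref_label], radius)[0]
    stacked = np.vstack([rec.data, np.zeros((1, rec.n_samples))])
    referenced = stacked - stacked.mean(axis=0, keepdims=True)
    return SensorRecording(data=referenced,
                           electrodes=list(rec.electrodes) + [ref_electrode],
                           sampling_rate=rec.sampling_rate,
                           ground_truth=rec.ground_truth)
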
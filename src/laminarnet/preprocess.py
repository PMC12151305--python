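"""Time-series conditioning: run concatenation, detrending, band-pass filtering.

Runs are concatenated first, then each channel is linearly detrended and
band-pass filtered with a second-order Butterworth (0.01-0.1 Hz by default)
applied forward and backward for zero net phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .containers import LaminarTimeSeries


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; ``order`` is the design order before the
    forward-backward pass doubles the effective roll-off."""

    highpass_hz: float = 0.01
    lowpass_hz: float = 0.1
    order: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass_hz < lowpass_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, sampling_hz: float) -> np.ndarray:
        nyquist = sampling_hz / 2.0
        if self.lowpass_hz >= nyquist:
            raise ValueError(
                f"lowpass ({self.lowpass_hz} Hz) must be below Nyquist "
                f"({nyquist:.4g} Hz)"
            )
        return signal.butter(
            self.order,
            [self.highpass_hz, self.lowpass_hz],
            btype="bandpass",
            fs=sampling_hz,
            output="sos",
        )


def concatenate_runs(runs: Sequence[LaminarTimeSeries]) -> LaminarTimeSeries:
    """Row-wise concatenation of runs sharing channels and TR."""
    if not runs:
        raise ValueError("need at least one run")
    first = runs[0]
    for run in runs[1:]:
        if run.channel_labels != first.channel_labels:
            raise ValueError("runs have mismatched channel labels")
        if run.tr_seconds != first.tr_seconds:
            raise ValueError("runs have mismatched TR")
    return LaminarTimeSeries(
        participant_id=first.participant_id,
        data=np.concatenate([run.data for run in runs], axis=0),
        channel_labels=first.channel_labels,
        tr_seconds=first.tr_seconds,
    )


def detrend_and_bandpass(
    ts: LaminarTimeSeries, spec: FilterSpec = FilterSpec()
) -> LaminarTimeSeries:
    """Linear detrend per channel, then zero-phase Butterworth band-pass.

    The forward-backward pass uses reflective padding of ``3 * order``
    samples at both ends to bound edge transients on short runs.
    """
    if ts.n_timepoints <= 6 * spec.order:
        raise ValueError(
            f"need more than {6 * spec.order} time points for order "
            f"{spec.order} zero-phase filtering, got {ts.n_timepoints}"
        )
    sos = spec.sos(ts.sampling_hz)
    detrended = signal.detrend(ts.data, axis=0, type="linear")
    filtered = signal.sosfiltfilt(
        sos, detrended, axis=0, padtype="even", padlen=3 * spec.order
    )
    return LaminarTimeSeries(
        participant_id=ts.participant_id,
        data=np.ascontiguousarray(filtered),
        channel_labels=ts.channel_labels,
        tr_seconds=ts.tr_seconds,
    )
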
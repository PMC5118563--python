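"""Band-pass filtering, robust noise estimation, threshold spike detection,
and array-wide electrical-activity maps.

Traces are band-pass filtered (500-3000 Hz, zero-phase Butterworth), the
noise standard deviation of each electrode is estimated robustly from the
median absolute deviation, and spikes are detected as local minima of
excursions below -5.5 x noise SD with a per-electrode dead time.  The
activity map summarizes a scan without sorting: per electrode, the largest
magnitude among the negative spike amplitudes observed; electrodes never
recorded are *missing*, which is distinct from a recorded-but-silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "DetectionParams",
    "SpikeEvent",
    "ActivityMap",
    "bandpass",
    "noise_sd",
    "detect_spikes",
    "detect_block",
    "activity_map",
]

#: MAD -> SD consistency factor for a Gaussian (1 / Phi^-1(3/4)).
MAD_SCALE = 0.6745


@dataclass(frozen=True)
class DetectionParams:
    band_low: float = 500.0
    band_high: float = 3000.0
    threshold_mult: float = 5.5
    dead_time_ms: float = 1.0
    activity_display_min: float = 50.0
    filter_order: int = 2

    def validate(self, sample_rate: float) -> None:
        if not 0 < self.band_low < self.band_high < sample_rate / 2:
            raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
        if self.threshold_mult <= 0:
            raise ValueError("threshold_mult must be positive")


@dataclass(frozen=True)
class SpikeEvent:
    """Threshold-crossing event, timed at the negative-excursion peak."""

    electrode_id: int
    sample: int
    amplitude: float  # μV, negative


def bandpass(trace: np.ndarray, sample_rate: float, params: DetectionParams | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass; length preserved.

    Zero-phase (forward-backward) filtering keeps trough timing unbiased,
    which matters because later stages align waveforms at the trough sample.
    """
    params = params or DetectionParams()
    params.validate(sample_rate)
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    if not np.isfinite(x).all():
        raise ValueError("trace contains NaN or Inf")
    sos = signal.butter(
        params.filter_order, [params.band_low, params.band_high], btype="bandpass",
        fs=sample_rate, output="sos",
    )
    return signal.sosfiltfilt(sos, x, axis=-1)


def noise_sd(filtered: np.ndarray) -> float:
    """Robust noise SD: ``median(|x|) / 0.6745``.

    The median absolute deviation is nearly unaffected by the rare large
    spike excursions, unlike the plain standard deviation.
    """
    x = np.asarray(filtered)
    if x.size == 0:
        raise ValueError("empty trace")
    return float(np.median(np.abs(x)) / MAD_SCALE)


def detect_spikes(
    filtered: np.ndarray,
    sd: float,
    sample_rate: float,
    params: DetectionParams | None = None,
    electrode_id: int = 0,
) -> list[SpikeEvent]:
    """Local minima of excursions below ``-threshold_mult * sd``, separated
    by at least ``dead_time_ms`` on this electrode."""
    params = params or DetectionParams()
    if sd < 0:
        raise ValueError("noise SD must be >= 0")
    x = np.asarray(filtered, dtype=float)
    thr = params.threshold_mult * sd
    distance = max(1, int(round(params.dead_time_ms * 1e-3 * sample_rate)))
    peaks, _ = signal.find_peaks(-x, height=max(thr, np.finfo(float).tiny), distance=distance)
    return [SpikeEvent(electrode_id, int(p), float(x[p])) for p in peaks]


def detect_block(
    traces: np.ndarray,
    electrode_ids: Sequence[int],
    sample_rate: float,
    params: DetectionParams | None = None,
    prefiltered: bool = False,
) -> tuple[dict[int, list[SpikeEvent]], dict[int, float], np.ndarray]:
    """Filter (unless ``prefiltered``) and detect on every electrode of a
    block; returns (events by electrode, noise SD by electrode, filtered
    traces as float32)."""
    params = params or DetectionParams()
    n_e = len(electrode_ids)
    filtered = np.empty((n_e, traces.shape[1]), dtype=np.float32)
    events: dict[int, list[SpikeEvent]] = {}
    sds: dict[int, float] = {}
    for i, e in enumerate(electrode_ids):
        f = traces[i] if prefiltered else bandpass(traces[i], sample_rate, params)
        filtered[i] = f
        sd = noise_sd(f)
        sds[int(e)] = sd
        events[int(e)] = detect_spikes(f, sd, sample_rate, params, electrode_id=int(e))
    return events, sds, filtered


@dataclass
class ActivityMap:
    """Per-electrode largest |negative spike amplitude| (μV).

    ``values`` holds every *recorded* electrode (0 if it saw no events);
    electrodes absent from ``values`` were never recorded.
    """

    values: dict[int, float] = field(default_factory=dict)

    def active_count(self, min_amplitude: float = 50.0) -> int:
        """Electrodes whose largest amplitude exceeds the display floor
        (50 μV by default) — the scalar used for day-to-day comparisons."""
        return sum(1 for v in self.values.values() if v > min_amplitude)

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values, name="max_neg_amplitude_uV").sort_index()


def activity_map(
    events_by_electrode: Mapping[int, Iterable[SpikeEvent]],
    recorded_electrodes: Iterable[int],
) -> ActivityMap:
    """Fold detected events into the per-electrode amplitude maximum."""
    values = {int(e): 0.0 for e in recorded_electrodes}
    for e, evs in events_by_electrode.items():
        amps = [abs(ev.amplitude) for ev in evs if ev.amplitude < 0]
        if amps and int(e) in values:
            values[int(e)] = max(values[int(e)], max(amps))
    return ActivityMap(values)
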
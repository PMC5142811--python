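"""Ratiometric trace extraction, normalization, aggregation and screening.

The G/R ratio (calcium indicator over co-expressed reference) is measured
in a spherical mask around each tracked nucleus center, normalized to its
time-series minimum (the transient baseline), resampled by linear
interpolation for cross-worm averaging, and screened for correlation with
the stimulus waveform and for adaptation over repeated stimulus cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ImageStack, StimulusProtocol
from .nuclei import TRACKED, NeuronTrack


@dataclass
class RatioTrace:
    """One neuron's G/R ratio time series.

    Missing frames (lost tracking, reference below background) are NaN.
    After min-normalization the minimum of the defined values is 1.
    """

    neuron_id: int | str
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False
    n_contributing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class ScreenResult:
    """Outcome of the stimulus-correlation screen for one neuron."""

    neuron_id: int | str
    pearson_r: float
    classification: str  # positive | negative | uncorrelated
    cycle_amplitudes: np.ndarray
    adaptation_index: float


def _sphere_offsets(radius_vox: float, voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Integer voxel offsets inside a sphere of physical radius
    ``radius_vox * dx`` (dx = x voxel pitch)."""
    vz, vy, vx = voxel_size
    r_um = radius_vox * vx
    nz = int(np.floor(r_um / vz))
    ny = int(np.floor(r_um / vy))
    nx = int(np.floor(r_um / vx))
    offs = []
    for dz in range(-nz, nz + 1):
        for dy in range(-ny, ny + 1):
            for dx in range(-nx, nx + 1):
                if (dz * vz) ** 2 + (dy * vy) ** 2 + (dx * vx) ** 2 <= r_um**2:
                    offs.append((dz, dy, dx))
    return np.asarray(offs, dtype=int)


def extract_ratio(
    stack: ImageStack,
    track: NeuronTrack,
    mask_radius: float | None = None,
    bg_floor: float = 1e-6,
) -> RatioTrace:
    """Mean G over mean R inside a spherical mask around the tracked center.

    Frames where the track is not in 'tracked' status, or where the mean
    reference intensity is at or below ``bg_floor``, yield NaN.
    """
    g_idx = stack.channel_index("G") if "G" in stack.channel_names else 0
    r_idx = stack.channel_index("R") if "R" in stack.channel_names else 1
    radius = mask_radius if mask_radius is not None else track.mask_radius
    offsets = _sphere_offsets(radius, stack.voxel_size)
    shape = np.asarray(stack.data.shape[1:4])
    values = np.full(stack.n_frames, np.nan)
    for t in range(min(stack.n_frames, track.n_frames)):
        if track.status and track.status[t] != TRACKED:
            continue
        vox = np.round(track.centers[t]).astype(int) + offsets
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[ok]
        if len(vox) == 0:
            continue
        g = stack.data[t, vox[:, 0], vox[:, 1], vox[:, 2], g_idx].mean()
        r = stack.data[t, vox[:, 0], vox[:, 1], vox[:, 2], r_idx].mean()
        if r <= bg_floor:
            continue
        values[t] = g / r
    return RatioTrace(neuron_id=track.neuron_id, times=stack.times, values=values)


def normalize_min(trace: RatioTrace) -> RatioTrace:
    """Divide by the time-series minimum (the transient baseline); idempotent."""
    defined = trace.defined()
    if not defined.any():
        raise ValueError("cannot normalize an all-missing trace")
    mn = np.nanmin(trace.values)
    if mn <= 0:
        raise ValueError("min-normalization requires strictly positive values")
    return RatioTrace(
        neuron_id=trace.neuron_id,
        times=trace.times,
        values=trace.values / mn,
        normalized=True,
        n_contributing=trace.n_contributing,
    )


def resample(trace: RatioTrace, common_times: np.ndarray) -> np.ndarray:
    """Linear interpolation of the defined values onto ``common_times``."""
    common_times = np.asarray(common_times, dtype=float)
    d = trace.defined()
    if d.sum() < 2:
        return np.full(len(common_times), np.nan)
    out = np.interp(common_times, trace.times[d], trace.values[d])
    out[(common_times < trace.times[d][0]) | (common_times > trace.times[d][-1])] = np.nan
    return out


def aggregate(
    traces: list[RatioTrace], common_times: np.ndarray
) -> tuple[RatioTrace, RatioTrace]:
    """Pointwise mean and standard error across traces.

    Each trace is linearly resampled onto ``common_times``; SE is
    sd/sqrt(n) over the traces contributing at each point (0 by convention
    where n = 1, with ``n_contributing`` recording the coverage).
    """
    if len(traces) == 0:
        raise ValueError("aggregate requires at least one trace")
    common_times = np.asarray(common_times, dtype=float)
    mat = np.stack([resample(tr, common_times) for tr in traces])
    n = np.isfinite(mat).sum(axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # n<=1 slices
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    se[n == 0] = np.nan
    mean_tr = RatioTrace("mean", common_times, mean, n_contributing=n)
    se_tr = RatioTrace("se", common_times, se, n_contributing=n)
    return mean_tr, se_tr


def _pearson_nan(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(stats.pearsonr(x, y).statistic)


def sort_by_reference(
    traces: list[RatioTrace], reference: RatioTrace
) -> list[tuple[RatioTrace, float]]:
    """Order traces by descending Pearson correlation with a reference trace
    (the correlation-sorted heat-map ordering).

    Traces must share the reference's time base.  Zero-variance traces have
    undefined correlation (NaN) and sort last; ties break by neuron_id.
    """
    scored = []
    for tr in traces:
        r = _pearson_nan(tr.values, reference.values)
        scored.append((tr, r))
    scored.sort(
        key=lambda p: (
            np.isnan(p[1]),  # undefined last
            -(p[1] if np.isfinite(p[1]) else 0.0),
            str(p[0].neuron_id),
        )
    )
    return scored


def stimulus_waveform(protocol: StimulusProtocol, times: np.ndarray) -> np.ndarray:
    """Boxcar waveform: 1 during heating pulses, 0 elsewhere."""
    times = np.asarray(times, dtype=float)
    w = np.zeros_like(times)
    for t0, t1 in protocol.heat_windows():
        w[(times >= t0) & (times < t1)] = 1.0
    return w


def screen_stimulus(
    trace: RatioTrace,
    protocol: StimulusProtocol,
    r_threshold: float = 0.5,
    baseline_window: float = 10.0,
    min_defined_fraction: float = 0.5,
) -> ScreenResult:
    """Classify a trace by its correlation with the stimulus waveform.

    Classification is positive / negative when the Pearson correlation with
    the boxcar stimulus reaches ``+/- r_threshold``, otherwise uncorrelated.
    Per-cycle amplitude = max within the heating window minus the median of
    the ``baseline_window`` seconds preceding it; the adaptation index is
    (A1 - A_last)/A1 when A1 > 0.
    """
    d = trace.defined()
    wave = stimulus_waveform(protocol, trace.times)
    if d.mean() < min_defined_fraction:
        r = np.nan
    else:
        r = _pearson_nan(trace.values, wave)
    if np.isnan(r):
        cls = "uncorrelated"
    elif r >= r_threshold:
        cls = "positive"
    elif r <= -r_threshold:
        cls = "negative"
    else:
        cls = "uncorrelated"

    amps = []
    for t0, t1 in protocol.heat_windows():
        in_cycle = (trace.times >= t0) & (trace.times < t1) & d
        pre = (trace.times >= t0 - baseline_window) & (trace.times < t0) & d
        if not in_cycle.any() or not pre.any():
            amps.append(np.nan)
            continue
        amps.append(
            float(np.max(trace.values[in_cycle]) - np.median(trace.values[pre]))
        )
    amps = np.asarray(amps)
    if len(amps) and np.isfinite(amps[0]) and amps[0] > 0 and np.isfinite(amps[-1]):
        adaptation = float((amps[0] - amps[-1]) / amps[0])
    else:
        adaptation = np.nan
    return ScreenResult(
        neuron_id=trace.neuron_id,
        pearson_r=float(r) if np.isfinite(r) else np.nan,
        classification=cls,
        cycle_amplitudes=amps,
        adaptation_index=adaptation,
    )
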
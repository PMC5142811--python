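"""Ground-truthed synthetic recordings and behavior sequences.

The imaging generator emulates drifting fluorescent nuclei with
stimulus-locked calcium dynamics: positively correlated responders whose
amplitude adapts geometrically over repeated heat pulses, negatively
correlated non-adapting responders, neurons with slow stimulus-independent
fluctuations, and silent neurons.  The behavior generator samples 4-state
continuous-time Markov chains with phase-dependent transition rates,
standing in for plate assays of freely crawling worms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .core import BEHAVIORS, Ethogram, ImageStack, StimulusProtocol

RESPONSE_CLASSES = ("positive_adapting", "negative", "uncorrelated", "silent")


@dataclass
class NeuronSpec:
    """Ground-truth description of one synthetic nucleus.

    ``gain`` is the fractional ratio change at full response;
    ``adaptation_factor`` multiplies the response amplitude each stimulus
    cycle (1.0 = no adaptation).  Baselines are peak blob intensities in
    camera units.
    """

    center0: tuple[float, float, float]
    radius: float = 2.5
    response_class: str = "silent"
    gain: float = 1.0
    adaptation_factor: float = 1.0
    baseline_G: float = 1000.0
    baseline_R: float = 1000.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0 < self.adaptation_factor <= 1):
            raise ValueError("adaptation_factor must be in (0, 1]")
        if self.baseline_G <= 0 or self.baseline_R <= 0:
            raise ValueError("baselines must be positive")
        if self.response_class not in RESPONSE_CLASSES:
            raise ValueError(f"response_class must be one of {RESPONSE_CLASSES}")


@dataclass
class CTMCModel:
    """Phase-dependent continuous-time Markov chain over the 4 behaviors.

    ``rate_matrices`` maps a phase kind ("pre", "heat", "interval") to a
    4x4 matrix of off-diagonal transition rates in 1/s (row = from-state,
    order as in :data:`~wormscreen.core.BEHAVIORS`); diagonals are ignored
    and treated as the negative row sum.
    """

    rate_matrices: dict[str, np.ndarray] = field(default_factory=dict)
    states: tuple[str, ...] = BEHAVIORS

    def __post_init__(self) -> None:
        for kind, m in self.rate_matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (len(self.states),) * 2:
                raise ValueError(f"rate matrix for {kind!r} must be square over states")
            off = m[~np.eye(len(self.states), dtype=bool)]
            if np.any(off < 0) or not np.all(np.isfinite(off)):
                raise ValueError("off-diagonal rates must be finite and >= 0")
            self.rate_matrices[kind] = m

    def rates_for(self, kind: str) -> np.ndarray:
        return self.rate_matrices[kind]


def default_ctmc(heat_fr_boost: float = 10.0) -> CTMCModel:
    """A plausible crawling-worm chain: mostly forward at baseline, with the
    forward-to-reversal rate boosted during heating (the nociceptive
    avoidance response)."""
    # order: forward, reversal, turn, pause
    pre = np.array(
        [
            [0.0, 0.02, 0.005, 0.01],
            [0.25, 0.0, 0.15, 0.0],
            [0.5, 0.0, 0.0, 0.0],
            [0.2, 0.02, 0.0, 0.0],
        ]
    )
    heat = pre.copy()
    heat[0, 1] *= heat_fr_boost  # accelerated F->R under noxious heat
    heat[1, 2] *= 2.0
    interval = pre.copy()
    return CTMCModel(rate_matrices={"pre": pre, "heat": heat, "interval": interval})


def stimulus_kernel(
    times: np.ndarray,
    protocol: StimulusProtocol,
    tau_on: float = 2.0,
    tau_off: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle response kernel evaluated at ``times``.

    Returns ``(kernel, cycle_index)`` where ``kernel[j, i]`` is the cycle-j
    component at time i: a saturating exponential rise during the heat pulse
    and an exponential decay afterwards; ``cycle_index[i]`` is the most
    recent cycle started by time i (-1 before the first pulse).
    """
    times = np.asarray(times, dtype=float)
    windows = protocol.heat_windows()
    kernel = np.zeros((len(windows), len(times)))
    cycle_index = np.full(len(times), -1, dtype=int)
    for j, (t0, t1) in enumerate(windows):
        cycle_index[times >= t0] = j
        during = (times >= t0) & (times < t1)
        after = times >= t1
        kernel[j, during] = 1.0 - np.exp(-(times[during] - t0) / tau_on)
        peak = 1.0 - np.exp(-(t1 - t0) / tau_on)
        kernel[j, after] = peak * np.exp(-(times[after] - t1) / tau_off)
    return kernel, cycle_index


def true_trace(
    spec: NeuronSpec,
    times: np.ndarray,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    tau_on: float = 2.0,
    tau_off: float = 5.0,
    fluctuation_sigma_s: float = 5.0,
) -> np.ndarray:
    """Noise-free G/R ratio trace for one neuron (baseline 1)."""
    times = np.asarray(times, dtype=float)
    if spec.response_class == "silent":
        return np.ones_like(times)
    if spec.response_class == "uncorrelated":
        # smooth stimulus-independent fluctuations (low-pass-filtered noise)
        dt = times[1] - times[0] if len(times) > 1 else 1.0
        raw = rng.standard_normal(len(times))
        smooth = gaussian_filter1d(raw, sigma=max(fluctuation_sigma_s / dt, 1.0))
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        tr = 1.0 + 0.5 * spec.gain * smooth
        return np.clip(tr, 0.05, None)
    kernel, _ = stimulus_kernel(times, protocol, tau_on, tau_off)
    amps = spec.adaptation_factor ** np.arange(kernel.shape[0])
    resp = amps @ kernel
    sign = 1.0 if spec.response_class == "positive_adapting" else -1.0
    tr = 1.0 + sign * spec.gain * resp
    return np.clip(tr, 0.05, None)


def _render_blobs(
    shape: tuple[int, int, int],
    centers: np.ndarray,
    amplitudes: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    """Sum of isotropic Gaussian blobs (sigma = radius/2, truncated at 3*sigma)."""
    vol = np.zeros(shape)
    for (cz, cy, cx), amp, radius in zip(centers, amplitudes, radii):
        sigma = radius / 2.0
        ext = int(np.ceil(3 * sigma))
        z0, z1 = max(int(np.floor(cz)) - ext, 0), min(int(np.ceil(cz)) + ext + 1, shape[0])
        y0, y1 = max(int(np.floor(cy)) - ext, 0), min(int(np.ceil(cy)) + ext + 1, shape[1])
        x0, x1 = max(int(np.floor(cx)) - ext, 0), min(int(np.ceil(cx)) + ext + 1, shape[2])
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
        )
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        blob = amp * np.exp(-d2 / (2 * sigma**2))
        blob[d2 > (3 * sigma) ** 2] = 0.0
        vol[z0:z1, y0:y1, x0:x1] += blob
    return vol


def random_walk_drift(
    n_frames: int,
    rng: np.random.Generator,
    step_sigma: tuple[float, float, float] = (0.1, 0.5, 0.5),
    max_step: float = 2.0,
    smooth_frames: float = 3.0,
    reversion: float = 0.05,
    max_excursion: float = 6.0,
) -> np.ndarray:
    """Smooth, bounded rigid drift trajectory, (n_frames, 3), zero at frame 0.

    A mean-reverting (Ornstein-Uhlenbeck-like) random walk: per-frame steps
    are Gaussian and temporally smoothed, each step is clipped to
    ``max_step`` voxels, and ``reversion`` pulls the excursion back toward
    zero so the drift stays bounded (the paralyzed, stage-tracked
    preparation wobbles around a fixed position rather than wandering
    freely); ``max_excursion`` is a hard per-axis cap.
    """
    steps = rng.normal(0.0, step_sigma, size=(n_frames, 3))
    steps = gaussian_filter1d(steps, sigma=smooth_frames, axis=0)
    norms = np.linalg.norm(steps, axis=1, keepdims=True)
    over = norms[:, 0] > max_step
    steps[over] *= max_step / norms[over]
    drift = np.zeros((n_frames, 3))
    for t in range(1, n_frames):
        drift[t] = (1.0 - reversion) * drift[t - 1] + steps[t]
        np.clip(drift[t], -max_excursion, max_excursion, out=drift[t])
    return drift


def gaussian_psf_kernel(sigma: tuple[float, float, float]) -> np.ndarray:
    """Unit-sum 3D Gaussian kernel with odd extents (3-sigma support)."""
    axes = []
    for s in sigma:
        ext = max(int(np.ceil(3 * s)), 1)
        x = np.arange(-ext, ext + 1)
        axes.append(np.exp(-(x**2) / (2 * max(s, 1e-9) ** 2)))
    k = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return k / k.sum()


def default_specs(
    shape: tuple[int, int, int] = (8, 64, 64),
    n_per_class: int = 5,
    gain: float = 1.0,
    adaptation_factor: float = 0.5,
    radius: float = 2.5,
    margin: float = 10.0,
) -> list[NeuronSpec]:
    """The default 20-neuron screen: 5 positive_adapting, 5 negative,
    5 uncorrelated, 5 silent, laid out on a grid with ``margin`` voxels of
    clearance from the y/x borders."""
    classes = [c for c in RESPONSE_CLASSES for _ in range(n_per_class)]
    n = len(classes)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    ys = np.linspace(margin, shape[1] - 1 - margin, nrows)
    xs = np.linspace(margin, shape[2] - 1 - margin, ncols)
    specs = []
    for i, cls in enumerate(classes):
        r, c = divmod(i, ncols)
        z = shape[0] / 2.0 - 1 + (i % 2)  # alternate between two z planes
        specs.append(
            NeuronSpec(
                center0=(z, float(ys[r]), float(xs[c])),
                radius=radius,
                response_class=cls,
                gain=gain if cls != "negative" else 0.5 * gain,
                adaptation_factor=adaptation_factor if cls == "positive_adapting" else 1.0,
            )
        )
    return specs


def simulate_stack(
    specs: list[NeuronSpec],
    protocol: StimulusProtocol | None = None,
    shape: tuple[int, int, int] = (8, 64, 64),
    n_frames: int | None = None,
    frame_interval: float = 0.5,
    drift: np.ndarray | None = None,
    drift_max_step: float = 2.0,
    drift_step_sigma: tuple[float, float, float] = (0.1, 0.5, 0.5),
    psf_sigma: tuple[float, float, float] | None = (1.0, 0.8, 0.8),
    shot_noise: bool = True,
    shot_floor: float = 10.0,
    read_noise: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[ImageStack, dict]:
    """Simulate a two-channel recording of drifting responsive nuclei.

    The G channel carries each neuron's baseline intensity modulated by its
    true ratio trace; the R channel is the constant reference at identical
    positions.  Both are blurred by the PSF, then mean-preserving Gaussian
    shot noise (variance = mean above ``shot_floor``) and additive read
    noise are applied.

    Returns ``(stack, truth)`` where ``truth`` has per-frame true centers
    (``(n_frames, n_neurons, 3)``), true ratio traces, the drift series and
    each neuron's class label.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    protocol = protocol or StimulusProtocol()
    if n_frames is None:
        n_frames = int(round(protocol.total_duration / frame_interval))
    times = np.arange(n_frames) * frame_interval

    if drift is None:
        if drift_max_step > 0:
            drift = random_walk_drift(
                n_frames, rng, step_sigma=drift_step_sigma, max_step=drift_max_step
            )
        else:
            drift = np.zeros((n_frames, 3))
    drift = np.asarray(drift, dtype=float)

    centers0 = np.array([s.center0 for s in specs], dtype=float)
    radii = np.array([s.radius for s in specs])
    traces = np.stack([true_trace(s, times, protocol, rng) for s in specs])

    # feasibility: neurons must stay inside the volume at all drift positions
    all_centers = centers0[None, :, :] + drift[:, None, :]
    if np.any(all_centers < 0) or np.any(all_centers >= np.array(shape)):
        raise ValueError("a neuron exits the volume under the requested drift")
    if read_noise < 0 or shot_floor <= 0:
        raise ValueError("noise parameters must be positive")

    psf = gaussian_psf_kernel(psf_sigma) if psf_sigma is not None else None
    data = np.empty((n_frames,) + shape + (2,), dtype=np.float32)
    base_G = np.array([s.baseline_G for s in specs])
    base_R = np.array([s.baseline_R for s in specs])
    for t in range(n_frames):
        centers_t = all_centers[t]
        g = _render_blobs(shape, centers_t, base_G * traces[:, t], radii)
        r = _render_blobs(shape, centers_t, base_R, radii)
        if psf is not None:
            g = fftconvolve(g, psf, mode="same")
            r = fftconvolve(r, psf, mode="same")
        for c, vol in enumerate((g, r)):
            if shot_noise:
                sd = np.sqrt(np.maximum(vol, shot_floor))
                vol = vol + rng.standard_normal(vol.shape) * sd
            if read_noise > 0:
                vol = vol + rng.normal(0.0, read_noise, vol.shape)
            data[t, :, :, :, c] = np.maximum(vol, 0.0)

    stack = ImageStack(
        data=data, frame_interval=frame_interval, channel_names=("G", "R")
    )
    truth = {
        "centers": all_centers,
        "traces": traces,
        "times": times,
        "drift": drift,
        "classes": [s.response_class for s in specs],
        "specs": specs,
        "protocol": protocol,
    }
    return stack, truth


def simulate_ethograms(
    model: CTMCModel,
    protocol: StimulusProtocol | None = None,
    n_worms: int = 20,
    fps: float = 20.0,
    seed: int | np.random.Generator = 0,
    initial_state: str = "forward",
) -> tuple[list[Ethogram], CTMCModel]:
    """Sample frame-labeled ethograms from a phase-dependent CTMC.

    Event times are drawn Gillespie-style with the rate matrix of the phase
    containing the current time (re-drawn at phase boundaries, valid by
    memorylessness); each frame is labeled with the state occupied at the
    frame midpoint.  Returns the ethograms and the true model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    protocol = protocol or StimulusProtocol()
    if fps <= 0:
        raise ValueError("fps must be positive")
    total = protocol.total_duration
    n_frames = int(round(total * fps))

    # phase boundaries as (start, end, kind)
    phases: list[tuple[float, float, str]] = []
    t = 0.0
    if protocol.pre_duration > 0:
        phases.append((0.0, protocol.pre_duration, "pre"))
        t = protocol.pre_duration
    for _ in range(protocol.repeats):
        phases.append((t, t + protocol.stim_duration, "heat"))
        t += protocol.stim_duration
        phases.append((t, t + protocol.isi, "interval"))
        t += protocol.isi
    if not phases:
        phases = [(0.0, total, "pre")]

    states = list(model.states)
    ethograms = []
    for w in range(n_worms):
        state = states.index(initial_state)
        # piecewise-constant-rate CTMC: record (time, state) jump sequence
        jump_times = [0.0]
        jump_states = [state]
        for start, end, kind in phases:
            rates = model.rates_for(kind)
            now = max(start, 0.0)
            while now < end:
                out_rates = rates[state].copy()
                out_rates[state] = 0.0
                total_rate = out_rates.sum()
                if total_rate <= 0:
                    break
                wait = rng.exponential(1.0 / total_rate)
                if now + wait >= end:
                    break
                now += wait
                state = rng.choice(len(states), p=out_rates / total_rate)
                jump_times.append(now)
                jump_states.append(state)
        jump_times = np.asarray(jump_times)
        midpoints = (np.arange(n_frames) + 0.5) / fps
        idx = np.searchsorted(jump_times, midpoints, side="right") - 1
        labels = [states[jump_states[i]] for i in idx]
        ethograms.append(Ethogram(worm_id=f"worm{w:03d}", labels=labels, fps=fps))
    return ethograms, model
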
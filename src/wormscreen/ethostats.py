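"""Behavioral ethogram statistics.

Implements the plate-assay analysis chain: phase windows from the stimulus
protocol, per-phase behavior fractions, transition events with their
pre-transition bout durations, harmonic-mean transition rates with
leave-one-out jackknife SDs, bias-corrected (BC) percentile bootstrap
confidence intervals (83.4% by default, chosen so that non-overlapping
intervals correspond to p < 0.05 for two means), Mann-Whitney comparisons,
post-stimulus reversal durations, and behavior-network graph export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BEHAVIORS, UNKNOWN, Ethogram, StimulusProtocol

#: Default confidence level for all error bars: pairwise non-overlap of two
#: equal-SE 83.4% intervals corresponds to a two-sided p of about 0.05.
DEFAULT_LEVEL = 0.834
DEFAULT_B = 1000


@dataclass
class PhaseWindows:
    """Ordered, non-overlapping (label, start_s, end_s) stimulation phases:
    P (pre-heat), H1..Hk (heating), L1..Lk (low-temperature intervals)."""

    windows: list[tuple[str, float, float]]

    def __iter__(self):
        return iter(self.windows)

    def __len__(self):
        return len(self.windows)

    @property
    def labels(self) -> list[str]:
        return [w[0] for w in self.windows]

    def label_at(self, time_s: float) -> str | None:
        for label, start, end in self.windows:
            if start <= time_s < end:
                return label
        return None


@dataclass
class TransitionEvent:
    """One behavioral transition and the bout that preceded it."""

    worm_id: str
    time_s: float
    from_behavior: str
    to_behavior: str
    pre_duration: float  # seconds, length of the preceding bout
    phase: str | None = None


def phase_windows(protocol: StimulusProtocol) -> PhaseWindows:
    """Deterministic phase decomposition of a protocol.

    The heating ramp is included in the H windows (heating phases are
    treated as full-temperature blocks).  An empty pre-phase is omitted.
    """
    windows: list[tuple[str, float, float]] = []
    t = 0.0
    if protocol.pre_duration > 0:
        windows.append(("P", 0.0, protocol.pre_duration))
        t = protocol.pre_duration
    for i in range(1, protocol.repeats + 1):
        windows.append((f"H{i}", t, t + protocol.stim_duration))
        t += protocol.stim_duration
        windows.append((f"L{i}", t, t + protocol.isi))
        t += protocol.isi
    return PhaseWindows(windows=windows)


# ---------------------------------------------------------------------------
# fractions


def worm_fractions(
    ethogram: Ethogram, windows: PhaseWindows
) -> pd.DataFrame:
    """Per-window behavior fractions for a single worm.

    A frame belongs to the window containing its midpoint; 'unknown' frames
    are excluded from the denominator, so fractions over the four behaviors
    sum to 1 wherever any frame is defined.
    """
    mids = (np.arange(ethogram.n_frames) + 0.5) / ethogram.fps
    labels = np.asarray(ethogram.labels)
    rows = []
    for name, start, end in windows:
        in_win = (mids >= start) & (mids < end)
        lab = labels[in_win]
        defined = lab[lab != UNKNOWN]
        for b in BEHAVIORS:
            frac = np.nan if len(defined) == 0 else float((defined == b).mean())
            rows.append((ethogram.worm_id, name, b, frac, len(defined)))
    return pd.DataFrame(
        rows, columns=["worm_id", "phase", "behavior", "fraction", "n_frames"]
    )


def behavior_fractions(
    ethograms: list[Ethogram],
    windows: PhaseWindows,
    level: float = DEFAULT_LEVEL,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Mean behavior fraction per (behavior, phase) with bootstrap CI over worms."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_worm = pd.concat([worm_fractions(e, windows) for e in ethograms])
    rows = []
    for (phase, behavior), grp in per_worm.groupby(["phase", "behavior"], sort=False):
        vals = grp["fraction"].dropna().to_numpy()
        if len(vals) == 0:
            rows.append((phase, behavior, np.nan, np.nan, np.nan, 0))
            continue
        mean = float(vals.mean())
        if len(vals) >= 2:
            lo, hi = bootstrap_ci(vals, np.mean, level=level, B=B, seed=rng)
        else:
            lo = hi = mean
        rows.append((phase, behavior, mean, lo, hi, len(vals)))
    return pd.DataFrame(
        rows, columns=["phase", "behavior", "fraction", "ci_lo", "ci_hi", "n_worms"]
    )


# ---------------------------------------------------------------------------
# transitions


def _bouts(labels: np.ndarray, min_bout: int) -> list[tuple[str, int, int]]:
    """Run-length encode labels and debounce: runs of known behavior shorter
    than ``min_bout`` frames are absorbed into the preceding bout.  Returns
    (label, start_frame, length_frames) tuples; 'unknown' runs survive as
    barriers and are never absorbed."""
    runs: list[list] = []
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1][2] += 1
        else:
            runs.append([lab, i, 1])
    out: list[list] = []
    for lab, start, length in runs:
        if (
            lab != UNKNOWN
            and length < min_bout
            and out
            and out[-1][0] != UNKNOWN
        ):
            out[-1][2] += length  # absorbed into the preceding bout
        elif out and out[-1][0] == lab:
            out[-1][2] += length  # re-merge after an absorption
        else:
            out.append([lab, start, length])
    return [tuple(r) for r in out]


def extract_transitions(
    ethogram: Ethogram,
    min_bout: int = 2,
    windows: PhaseWindows | None = None,
) -> list[TransitionEvent]:
    """Transition events with their pre-transition bout durations.

    Transition time points are extracted first, then the length of the
    behavior immediately before each transition is measured (in seconds,
    the full bout length without truncation at phase boundaries).  Events
    are assigned to the phase containing the transition instant; bouts
    adjacent to 'unknown' frames emit no event at that boundary.
    """
    if min_bout < 1:
        raise ValueError("min_bout must be >= 1")
    bouts = _bouts(np.asarray(ethogram.labels), min_bout)
    events = []
    for (lab_a, start_a, len_a), (lab_b, start_b, _) in zip(bouts, bouts[1:]):
        if lab_a == UNKNOWN or lab_b == UNKNOWN:
            continue
        t = start_b / ethogram.fps
        events.append(
            TransitionEvent(
                worm_id=ethogram.worm_id,
                time_s=t,
                from_behavior=lab_a,
                to_behavior=lab_b,
                pre_duration=len_a / ethogram.fps,
                phase=windows.label_at(t) if windows is not None else None,
            )
        )
    return events


def harmonic_mean_rate(pre_durations: np.ndarray) -> float:
    """Harmonic mean of the per-event rates 1/d_i, i.e. n / sum(d_i)."""
    d = np.asarray(pre_durations, dtype=float)
    if len(d) == 0:
        return np.nan
    return float(len(d) / d.sum())


def jackknife_sd(values: np.ndarray, statistic=harmonic_mean_rate) -> float:
    """Leave-one-out jackknife standard deviation of a statistic.

    ``sqrt((n-1)/n * sum((theta_i - theta_bar)^2))`` over the n
    leave-one-out estimates; undefined (NaN) for n = 1.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return np.nan
    loo = np.array(
        [statistic(np.delete(values, i)) for i in range(n)], dtype=float
    )
    return float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))


def transition_rate(pre_durations: np.ndarray) -> tuple[float, float]:
    """Harmonic-mean transition rate (1/s) and its jackknife SD.

    Returns (NaN, NaN) for an empty event set: absence of opportunities is
    not evidence of a zero rate.
    """
    d = np.asarray(pre_durations, dtype=float)
    if len(d) == 0:
        return np.nan, np.nan
    return harmonic_mean_rate(d), jackknife_sd(d)


def transition_table(
    ethograms: list[Ethogram],
    windows: PhaseWindows,
    min_bout: int = 2,
    level: float = DEFAULT_LEVEL,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per (from, to, phase) transition statistics.

    Events pool across worms; the bootstrap resampling unit for rate CIs is
    the transition event.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = [ev for e in ethograms for ev in extract_transitions(e, min_bout, windows)]
    rows = []
    by_key: dict[tuple[str, str, str], list[float]] = {}
    for ev in events:
        if ev.phase is None:
            continue
        by_key.setdefault((ev.from_behavior, ev.to_behavior, ev.phase), []).append(
            ev.pre_duration
        )
    for phase in windows.labels:
        for src in BEHAVIORS:
            for dst in BEHAVIORS:
                if src == dst:
                    continue
                durs = np.asarray(by_key.get((src, dst, phase), []), dtype=float)
                rate, jsd = transition_rate(durs)
                if len(durs) >= 2:
                    lo, hi = bootstrap_ci(
                        durs, harmonic_mean_rate, level=level, B=B, seed=rng
                    )
                else:
                    lo = hi = rate
                rows.append((phase, src, dst, len(durs), rate, jsd, lo, hi))
    return pd.DataFrame(
        rows,
        columns=[
            "phase", "from", "to", "n", "rate", "jackknife_sd", "ci_lo", "ci_hi",
        ],
    )


# ---------------------------------------------------------------------------
# inference


def bootstrap_ci(
    samples: np.ndarray,
    statistic=np.mean,
    level: float = DEFAULT_LEVEL,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Bias-corrected (BC) percentile bootstrap confidence interval.

    ``B`` resamples with replacement of the sample units; the median-bias
    correction ``z0 = Phi^-1(#{theta* < theta_hat}/B)`` shifts the
    percentile positions to ``Phi(2 z0 +/- z_(1+level)/2)``.  BC (not BCa):
    no acceleration term.  Deterministic under a fixed seed.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        raise ValueError("bootstrap requires at least 2 samples")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta_hat = float(statistic(samples))
    n = len(samples)
    idx = rng.integers(0, n, size=(B, n))
    boot = np.array([statistic(samples[row]) for row in idx], dtype=float)
    return _bc_interval(boot, theta_hat, level)


def _bc_interval(
    boot: np.ndarray, theta_hat: float, level: float
) -> tuple[float, float]:
    """BC percentile interval from a bootstrap distribution.

    With ``theta_hat`` at the bootstrap median, z0 = 0 and this reduces to
    the plain percentile interval.  A degenerate distribution yields [c, c].
    """
    boot = np.asarray(boot, dtype=float)
    B = len(boot)
    if np.allclose(boot, boot[0]):
        return float(boot[0]), float(boot[0])
    prop = np.mean(boot < theta_hat)
    # clip to keep z0 finite for extreme bias
    prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
    z0 = stats.norm.ppf(prop)
    za = stats.norm.ppf((1 + level) / 2)
    lo_p = stats.norm.cdf(2 * z0 - za)
    hi_p = stats.norm.cdf(2 * z0 + za)
    lo, hi = np.quantile(boot, [lo_p, hi_p])
    return float(lo), float(hi)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small tie-free samples (min(n, m) <= 8),
    tie-corrected normal approximation otherwise.  Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    small = min(len(x), len(y)) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def normal_ci(mean: float, se: float, level: float = DEFAULT_LEVEL) -> tuple[float, float]:
    """Normal-theory confidence interval mean +/- z_(1+level)/2 * SE."""
    z = stats.norm.ppf((1 + level) / 2)
    return mean - z * se, mean + z * se


def two_sample_ztest(
    mean1: float, se1: float, mean2: float, se2: float
) -> tuple[float, float]:
    """Two-sided z-test for two independent means with known SEs."""
    z = (mean1 - mean2) / np.hypot(se1, se2)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def p_stars(p: float) -> str:
    """The figure star coding: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def reversal_duration_after(
    ethogram: Ethogram, stim_time: float, response_window: float = 3.0
) -> float:
    """Duration (s) of the first reversal bout starting within
    ``response_window`` after a stimulus.

    A reversal already in progress at the stimulus does not count (its bout
    started earlier); the counted bout is measured to its natural end even
    if that extends beyond the window.  Returns 0 if no reversal starts in
    the window.
    """
    if not (0 <= stim_time <= ethogram.duration):
        raise ValueError("stim_time outside the ethogram's span")
    for lab, start, length in _bouts(np.asarray(ethogram.labels), min_bout=1):
        t0 = start / ethogram.fps
        if lab == "reversal" and stim_time <= t0 <= stim_time + response_window:
            return length / ethogram.fps
    return 0.0


def compare_groups(
    groups: dict[str, np.ndarray],
    control: str,
    statistic=np.mean,
    level: float = DEFAULT_LEVEL,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Compare every group against a designated control.

    Per group: Mann-Whitney p vs control, star coding, BC bootstrap CI of
    the group statistic, and whether its CI overlaps the control's (the
    graphical p<0.05 criterion at level 0.834).
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not among groups")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cis = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) >= 2:
            cis[name] = bootstrap_ci(vals, statistic, level=level, B=B, seed=rng)
        else:
            est = float(statistic(vals)) if len(vals) else np.nan
            cis[name] = (est, est)
    rows = []
    ctrl_vals = np.asarray(groups[control], dtype=float)
    ctrl_ci = cis[control]
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if name == control:
            u, p = np.nan, 1.0
        else:
            u, p = mann_whitney(vals, ctrl_vals)
        lo, hi = cis[name]
        non_overlap = bool(hi < ctrl_ci[0] or lo > ctrl_ci[1]) if name != control else False
        rows.append(
            (
                name,
                len(vals),
                float(statistic(vals)) if len(vals) else np.nan,
                lo,
                hi,
                u,
                p,
                p_stars(p) if name != control else "",
                non_overlap,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "n", "estimate", "ci_lo", "ci_hi", "U", "p", "stars",
            "ci_nonoverlap_vs_control",
        ],
    )
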
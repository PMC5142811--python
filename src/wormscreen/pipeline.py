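"""End-to-end pipelines chaining all stages with one resolved configuration.

Every run writes its resolved configuration next to its outputs so any
stage can be rerun in isolation; all randomness flows through the single
configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .core import ImageStack, StimulusProtocol
from .ethostats import (
    DEFAULT_B,
    DEFAULT_LEVEL,
    behavior_fractions,
    compare_groups,
    phase_windows,
    transition_table,
)
from .nuclei import GVFParams, detect_nuclei, track_all, tracks_to_frame
from .preprocess import PSFModel, deconvolve_stack, register_stack
from .traces import extract_ratio, normalize_min, screen_stimulus

log = logging.getLogger("wormscreen")


@dataclass
class RunConfig:
    """Resolved parameters for a full pipeline run.

    Unknown keys are rejected on load; the resolved config (defaults filled
    in) is written beside the outputs of every run.
    """

    # inputs / outputs
    stack_path: str | None = None
    ethogram_path: str | None = None
    protocol_path: str | None = None
    out_dir: str = "out"
    # registration
    reference_frame: int = 0
    upsample: int = 20
    register_channel: str = "R"
    # deconvolution
    deconvolve: bool = False
    rl_iterations: int = 25
    psf_sigma: tuple[float, float, float] = (1.0, 0.8, 0.8)
    # detection / tracking
    gvf_mu: float = 0.2
    gvf_n_iter: int = 80
    gvf_dt: float = 0.5
    min_basin: int = 30
    merge_radius: float = 2.0
    crop_half_size: tuple[int, int, int] = (3, 7, 7)
    max_step: float = 4.0
    detect_channel: str = "R"
    # extraction / screening
    mask_radius: float = 2.0
    r_threshold: float = 0.5
    # statistics
    bootstrap_B: int = DEFAULT_B
    ci_level: float = DEFAULT_LEVEL
    control_group: str | None = None
    min_bout: int = 2
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def run_imaging_pipeline(
    config: RunConfig, stack: ImageStack | None = None
) -> dict[str, Path]:
    """register -> (deconvolve) -> detect -> track -> extract -> screen.

    Each stage's output is persisted as flat CSV in ``config.out_dir``.
    Returns a mapping from stage name to output path.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.write(out_dir / "config.json")
    outputs: dict[str, Path] = {"config": out_dir / "config.json"}

    if stack is None:
        if not config.stack_path:
            raise ValueError("config.stack_path is required")
        stack = wio.read_stack(config.stack_path)
    protocol = (
        wio.read_protocol(config.protocol_path)
        if config.protocol_path
        else StimulusProtocol()
    )

    log.info("registering %d frames (upsample=%d)", stack.n_frames, config.upsample)
    stack, shifts = register_stack(
        stack,
        reference_frame=config.reference_frame,
        channel=config.register_channel,
        upsample=config.upsample,
    )
    pd.DataFrame(shifts.shifts, columns=["dz", "dy", "dx"]).to_csv(
        out_dir / "shifts.csv", index_label="frame"
    )
    outputs["shifts"] = out_dir / "shifts.csv"

    if config.deconvolve:
        log.info("deconvolving (%d RL iterations)", config.rl_iterations)
        stack = deconvolve_stack(
            stack, PSFModel(sigma=tuple(config.psf_sigma)), config.rl_iterations
        )

    params = GVFParams(mu=config.gvf_mu, n_iter=config.gvf_n_iter, dt=config.gvf_dt)
    centers = detect_nuclei(
        stack.volume(config.reference_frame, config.detect_channel),
        params=params,
        min_basin=config.min_basin,
        merge_radius=config.merge_radius,
    )
    log.info("detected %d nuclei", len(centers))
    pd.DataFrame(centers, columns=["z", "y", "x"]).to_csv(
        out_dir / "centers.csv", index_label="neuron_id"
    )
    outputs["centers"] = out_dir / "centers.csv"

    tracks = track_all(
        stack,
        centers,
        channel=config.detect_channel,
        crop_half_size=tuple(config.crop_half_size),
        params=params,
        max_step=config.max_step,
        merge_radius=config.merge_radius,
        mask_radius=config.mask_radius,
    )
    tracks_to_frame(tracks).to_csv(out_dir / "tracks.csv", index=False)
    outputs["tracks"] = out_dir / "tracks.csv"

    traces = [normalize_min(extract_ratio(stack, tr)) for tr in tracks]
    wio.write_traces(traces, out_dir / "traces.csv")
    outputs["traces"] = out_dir / "traces.csv"

    rows = []
    for tr in traces:
        res = screen_stimulus(tr, protocol, r_threshold=config.r_threshold)
        rows.append(
            {
                "neuron_id": res.neuron_id,
                "r": res.pearson_r,
                "class": res.classification,
                **{f"A{i+1}": a for i, a in enumerate(res.cycle_amplitudes)},
                "adaptation_index": res.adaptation_index,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "screen.csv", index=False)
    outputs["screen"] = out_dir / "screen.csv"
    return outputs


def run_behavior_pipeline(config: RunConfig) -> dict[str, Path]:
    """Ethogram CSV + protocol JSON -> the full set of behavioral statistics.

    Worm ids of the form ``<strain>:<id>`` are grouped by strain for the
    comparison report when ``config.control_group`` is set.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.write(out_dir / "config.json")
    outputs: dict[str, Path] = {"config": out_dir / "config.json"}

    if not config.ethogram_path:
        raise ValueError("config.ethogram_path is required")
    ethograms = wio.read_ethograms(config.ethogram_path)
    if not ethograms:
        raise ValueError(f"no ethograms found in {config.ethogram_path}")
    protocol = (
        wio.read_protocol(config.protocol_path)
        if config.protocol_path
        else StimulusProtocol()
    )
    windows = phase_windows(protocol)
    rng = np.random.default_rng(config.seed)

    fractions = behavior_fractions(
        ethograms, windows, level=config.ci_level, B=config.bootstrap_B, seed=rng
    )
    fractions.to_csv(out_dir / "fractions.csv", index=False)
    outputs["fractions"] = out_dir / "fractions.csv"

    rates = transition_table(
        ethograms,
        windows,
        min_bout=config.min_bout,
        level=config.ci_level,
        B=config.bootstrap_B,
        seed=rng,
    )
    rates.to_csv(out_dir / "rates.csv", index=False)
    outputs["rates"] = out_dir / "rates.csv"

    # behavior-network graph per phase
    for phase in windows.labels:
        fr = fractions[fractions["phase"] == phase]
        node_fracs = dict(zip(fr["behavior"], fr["fraction"]))
        ra = rates[(rates["phase"] == phase) & rates["rate"].notna()]
        edge_rates = {
            (r["from"], r["to"]): r["rate"] for _, r in ra.iterrows()
        }
        path = out_dir / f"graph_{phase}.graphml"
        wio.write_behavior_graph(node_fracs, edge_rates, path)
        outputs[f"graph_{phase}"] = path

    if config.control_group:
        groups: dict[str, list] = {}
        for e in ethograms:
            strain = e.worm_id.split(":", 1)[0]
            # per-worm forward fraction during H1 as the compared statistic
            wf = worm_stat_h1(e, windows)
            if np.isfinite(wf):
                groups.setdefault(strain, []).append(wf)
        comparisons = compare_groups(
            {k: np.asarray(v) for k, v in groups.items()},
            control=config.control_group,
            level=config.ci_level,
            B=config.bootstrap_B,
            seed=rng,
        )
        comparisons.to_csv(out_dir / "comparisons.csv", index=False)
        outputs["comparisons"] = out_dir / "comparisons.csv"
    return outputs


def worm_stat_h1(ethogram, windows) -> float:
    """Per-worm turn fraction during the first heating phase (the statistic
    compared across strains)."""
    from .ethostats import worm_fractions

    wf = worm_fractions(ethogram, windows)
    row = wf[(wf["phase"] == "H1") & (wf["behavior"] == "turn")]
    if len(row) == 0:
        return np.nan
    return float(row["fraction"].iloc[0])
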
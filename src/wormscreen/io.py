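"""Reading and writing of on-disk artifacts.

Formats: multi-page TIFF (+ JSON sidecar) for image stacks, CSV for
ethograms and traces, JSON for stimulus protocols, GraphML for behavior
networks.  Stacks are always returned in canonical ``(t, z, y, x, c)`` axis
order regardless of the order stored on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .core import BEHAVIORS, Ethogram, ImageStack, StimulusProtocol, canonical_label

CANONICAL_AXES = "TZYXC"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as a multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata={"axes": CANONICAL_AXES})
    meta = {
        "axes": CANONICAL_AXES,
        "voxel_size_um": list(stack.voxel_size),
        "frame_interval_s": stack.frame_interval,
        "channel_names": list(stack.channel_names),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack from TIFF (axis-tagged) or raw binary + sidecar.

    The on-disk axis order may be any permutation of TZYXC; the returned
    stack is permuted to canonical order with values preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = meta.get("axes") or series.axes
    else:  # raw binary: sidecar must declare dtype, shape and axes
        if not sidecar.exists():
            raise ValueError(f"raw binary {path} requires a JSON sidecar")
        if "shape" not in meta or "axes" not in meta:
            raise ValueError("sidecar must declare 'shape' and 'axes' for raw binaries")
        data = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "uint16")))
        data = data.reshape(meta["shape"])
        axes = meta["axes"]

    axes = str(axes).upper()
    if sorted(axes) != sorted(CANONICAL_AXES):
        raise ValueError(
            f"undeclared or unsupported axis order {axes!r}; need a permutation of {CANONICAL_AXES}"
        )
    data = np.transpose(data, [axes.index(a) for a in CANONICAL_AXES])

    if meta.get("channel_names"):
        channel_names = tuple(meta["channel_names"])
    elif data.shape[4] == 2:
        channel_names = ("G", "R")
    else:
        channel_names = tuple(f"C{i}" for i in range(data.shape[4]))
    return ImageStack(
        data=data,
        voxel_size=tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0))),
        frame_interval=float(meta.get("frame_interval_s", 0.5)),
        channel_names=channel_names,
    )


def read_ethograms(path: str | Path) -> list[Ethogram]:
    """Read frame-labeled ethograms from CSV (columns worm_id, frame, label).

    One ethogram is returned per worm, frames sorted; frames absent from the
    file (between 0 and the worm's last frame) are labeled ``unknown``.
    Duplicate (worm, frame) rows and labels outside the vocabulary raise.
    """
    df = pd.read_csv(path, dtype={"worm_id": str})
    required = {"worm_id", "frame", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"ethogram CSV needs columns {sorted(required)}")
    out: list[Ethogram] = []
    if len(df) == 0:
        return out
    fps = float(df["fps"].iloc[0]) if "fps" in df.columns else 20.0
    for worm_id, grp in df.groupby("worm_id", sort=True):
        if grp["frame"].duplicated().any():
            dup = grp.loc[grp["frame"].duplicated(), "frame"].iloc[0]
            raise ValueError(f"duplicate row for worm {worm_id!r}, frame {dup}")
        n = int(grp["frame"].max()) + 1
        labels = np.full(n, "unknown", dtype=object)
        labels[grp["frame"].to_numpy(int)] = [canonical_label(l) for l in grp["label"]]
        out.append(Ethogram(worm_id=str(worm_id), labels=labels, fps=fps))
    return out


def write_ethograms(ethograms: list[Ethogram], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for e in ethograms:
        for frame, label in enumerate(e.labels):
            rows.append((e.worm_id, frame, label, e.fps))
    pd.DataFrame(rows, columns=["worm_id", "frame", "label", "fps"]).to_csv(
        path, index=False
    )
    return path


def read_protocol(path: str | Path) -> StimulusProtocol:
    return StimulusProtocol.from_dict(json.loads(Path(path).read_text()))


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(protocol.to_dict(), indent=1))
    return path


def write_traces(traces, path: str | Path) -> Path:
    """Write ratio traces as long-format CSV (neuron_id, time_s, ratio)."""
    path = Path(path)
    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.neuron_id, t, v))
    pd.DataFrame(rows, columns=["neuron_id", "time_s", "ratio"]).to_csv(
        path, index=False
    )
    return path


def read_traces(path: str | Path):
    from .traces import RatioTrace

    df = pd.read_csv(path)
    out = []
    for nid, grp in df.groupby("neuron_id", sort=True):
        out.append(
            RatioTrace(
                neuron_id=nid,
                times=grp["time_s"].to_numpy(float),
                values=grp["ratio"].to_numpy(float),
            )
        )
    return out


def behavior_graph(
    fractions: dict[str, float],
    rates: dict[tuple[str, str], float],
    width_scale: float = 10.0,
) -> nx.DiGraph:
    """Build the behavior-network graph.

    Nodes are the four behaviors with attribute ``fraction``; directed edges
    carry ``rate`` (1/s) and ``width`` proportional to the rate.  Zero-rate
    transitions get no edge.
    """
    g = nx.DiGraph()
    for b in BEHAVIORS:
        g.add_node(b, fraction=float(fractions.get(b, 0.0)))
    for (src, dst), rate in rates.items():
        if rate < 0:
            raise ValueError(f"negative transition rate for {src}->{dst}")
        if rate > 0:
            g.add_edge(src, dst, rate=float(rate), width=float(rate * width_scale))
    return g


def write_behavior_graph(
    fractions: dict[str, float],
    rates: dict[tuple[str, str], float],
    path: str | Path,
    width_scale: float = 10.0,
) -> Path:
    path = Path(path)
    nx.write_graphml(behavior_graph(fractions, rates, width_scale), path)
    return path


def validate(path: str | Path) -> dict:
    """Check format conformance of a file; returns a small report dict."""
    path = Path(path)
    report = {"path": str(path), "ok": False, "kind": None, "detail": ""}
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            s = read_stack(path)
            report.update(kind="stack", ok=True, detail=f"shape {s.data.shape}")
        elif path.suffix.lower() == ".csv":
            head = pd.read_csv(path, nrows=1)
            if "label" in head.columns:
                e = read_ethograms(path)
                report.update(kind="ethogram", ok=True, detail=f"{len(e)} worms")
            else:
                t = read_traces(path)
                report.update(kind="traces", ok=True, detail=f"{len(t)} traces")
        elif path.suffix.lower() == ".json":
            read_protocol(path)
            report.update(kind="protocol", ok=True)
        elif path.suffix.lower() == ".graphml":
            g = nx.read_graphml(path)
            report.update(kind="graph", ok=True, detail=f"{g.number_of_nodes()} nodes")
        else:
            report["detail"] = "unrecognized extension"
    except Exception as exc:  # pragma: no cover - reporting path
        report["detail"] = f"{type(exc).__name__}: {exc}"
    return report
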
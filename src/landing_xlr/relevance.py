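"""Relevance post-processing: averaging, smoothing, scaling, aggregation.

The processing order mirrors the explanation pipeline: per-trial raw maps
are rectified and averaged, smoothed per channel with a 25/50/25 kernel
applied three times, min-max scaled to [0, 1], and finally aggregated into
contribution shares per channel / joint / plane / 1%-phase bin, plus the
extraction of highly relevant variables (RS above a threshold).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .channels import ChannelId, Joint, Plane, channel_from_label
from .lrp import RelevanceMap


class MapStateError(ValueError):
    """An operation received a map in the wrong processing state."""


@dataclass(frozen=True)
class SmoothingSpec:
    """Three-tap smoothing: previous 25%, current 50%, next 25%.

    ``boundary`` rules for the two edge nodes:

    - ``renormalize`` (default): truncated kernel rescaled to sum 1
      (preserves constants; does not exactly preserve the series sum).
    - ``replicate``: edge value repeated outward (preserves constants AND
      the series sum exactly, since every input's outgoing weight is 1).
    - ``reflect``: mirror about the edge node.
    """

    weights: tuple[float, float, float] = (0.25, 0.5, 0.25)
    repetitions: int = 3
    boundary: str = "renormalize"

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("smoothing weights must sum to 1")
        if self.repetitions < 0:
            raise ValueError("repetitions must be >= 0")
        if self.boundary not in ("renormalize", "replicate", "reflect"):
            raise ValueError(f"unknown boundary rule: {self.boundary!r}")


def _smooth_once(row: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    w_prev, w_cur, w_next = spec.weights
    if spec.boundary == "replicate":
        padded = np.concatenate([[row[0]], row, [row[-1]]])
    elif spec.boundary == "reflect":
        padded = np.concatenate([[row[1]], row, [row[-2]]])
    else:  # renormalize: treat out-of-range as absent, rescale edge weights
        out = w_prev * np.concatenate([[0.0], row[:-1]]) + w_cur * row
        out += w_next * np.concatenate([row[1:], [0.0]])
        out[0] /= w_cur + w_next
        out[-1] /= w_prev + w_cur
        return out
    return w_prev * padded[:-2] + w_cur * padded[1:-1] + w_next * padded[2:]


def average_maps(
    maps: Sequence[RelevanceMap],
    selection: str = "correct",
    rectify: bool = True,
) -> RelevanceMap:
    """Node-wise mean over selected per-trial maps.

    ``selection``: ``correct`` (default; correctly classified trials only),
    ``all``, or one of the class labels (correct trials of that class).
    Negative relevance is clipped to zero before averaging unless
    ``rectify=False``; downstream shares and [0,1] scaling presuppose
    nonnegative contributions.
    """
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].values.shape
    channels = maps[0].channels
    chosen = []
    for m in maps:
        if m.values.shape != shape or m.channels != channels:
            raise ValueError("maps must share the same channel x node grid")
        if selection == "all":
            keep = True
        elif selection == "correct":
            keep = bool(m.meta.get("correct", True))
        else:
            keep = bool(m.meta.get("correct", True)) and m.meta.get("true_class") == selection
        if keep:
            chosen.append(m)
    if not chosen:
        raise ValueError(f"selection {selection!r} matched no maps")
    stack = np.stack([m.values for m in chosen])
    if rectify:
        stack = np.clip(stack, 0.0, None)
    return RelevanceMap(
        values=stack.mean(axis=0),
        channels=channels,
        state="raw",
        meta={"n_averaged": len(chosen), "selection": selection, "rectified": rectify},
    )


def smooth_rs(map_: RelevanceMap, spec: SmoothingSpec | None = None) -> RelevanceMap:
    """Apply the 25/50/25 kernel ``repetitions`` times per channel row."""
    if map_.state == "scaled":
        raise MapStateError("cannot smooth an already-scaled map")
    spec = spec or SmoothingSpec()
    values = map_.values.copy()
    for _ in range(spec.repetitions):
        values = np.apply_along_axis(_smooth_once, 1, values, spec)
    meta = dict(map_.meta)
    meta["smoothing"] = {
        "weights": list(spec.weights),
        "repetitions": spec.repetitions,
        "boundary": spec.boundary,
    }
    return RelevanceMap(values=values, channels=map_.channels, state="smoothed", meta=meta)


def scale_rs(map_: RelevanceMap, per_channel: bool = False) -> RelevanceMap:
    """Min-max rescale the smoothed map to [0, 1].

    Global scope by default so cross-channel shares stay comparable;
    ``per_channel=True`` rescales each channel row independently. A
    degenerate (constant) map scales to all zeros with a warning.
    """
    if map_.state != "smoothed":
        raise MapStateError(f"scale_rs expects a smoothed map, got state {map_.state!r}")
    v = map_.values
    if per_channel:
        lo = v.min(axis=1, keepdims=True)
        hi = v.max(axis=1, keepdims=True)
    else:
        lo = v.min()
        hi = v.max()
    span = hi - lo
    degenerate = ~(np.asarray(span) > 0)
    if np.any(degenerate):
        warnings.warn("degenerate (constant) relevance map scaled to all zeros")
    scaled = np.where(
        np.broadcast_to(np.asarray(span) > 0, v.shape),
        (v - lo) / np.where(np.asarray(span) == 0, 1.0, span),
        0.0,
    )
    meta = dict(map_.meta)
    meta["scaling"] = "per_channel" if per_channel else "global"
    return RelevanceMap(values=scaled, channels=map_.channels, state="scaled", meta=meta)


@dataclass
class ContributionTable:
    """Percentage shares of total relevance along several partitions."""

    channel_share: dict[str, float]  # channel label -> %
    joint_share: dict[str, float]
    plane_share: dict[str, float]
    phase_share: np.ndarray  # % per 1%-phase bin (node)
    early_window: tuple[int, int]  # inclusive node range
    early_share: float = field(init=False)

    def __post_init__(self) -> None:
        lo, hi = self.early_window
        self.early_share = float(self.phase_share[lo : hi + 1].sum())

    def to_dict(self) -> dict:
        return {
            "channel_share": self.channel_share,
            "joint_share": self.joint_share,
            "plane_share": self.plane_share,
            "phase_share": self.phase_share.tolist(),
            "early_window": list(self.early_window),
            "early_share": self.early_share,
        }


def aggregate_contributions(
    map_: RelevanceMap, early_window: tuple[int, int] = (1, 22)
) -> ContributionTable:
    """Sum scaled relevance into channel/joint/plane/phase-bin shares.

    ``early_window`` is inclusive of both endpoint bins; the default (1, 22)
    covers 22 of the 101 one-percent bins.
    """
    if map_.state != "scaled":
        raise MapStateError("aggregation expects a scaled map")
    total = map_.values.sum()
    if total <= 0:
        raise ValueError("zero total relevance; nothing to aggregate")
    per_channel = map_.values.sum(axis=1) / total * 100.0
    channel_share = {c.label: float(s) for c, s in zip(map_.channels, per_channel)}
    joint_share = {
        j.value: float(sum(s for c, s in zip(map_.channels, per_channel) if c.joint is j))
        for j in Joint
    }
    plane_share = {
        p.value: float(sum(s for c, s in zip(map_.channels, per_channel) if c.plane is p))
        for p in Plane
    }
    phase_share = map_.values.sum(axis=0) / total * 100.0
    lo, hi = early_window
    if not (0 <= lo <= hi < map_.n_nodes):
        raise ValueError(f"early window {early_window} outside the node grid")
    return ContributionTable(
        channel_share=channel_share,
        joint_share=joint_share,
        plane_share=plane_share,
        phase_share=phase_share,
        early_window=(lo, hi),
    )


@dataclass
class HighRsSet:
    """Maximal runs of consecutive nodes with RS strictly above a threshold."""

    threshold: float
    runs: list[tuple[ChannelId, int, int]]  # (channel, start node, end node) inclusive
    n_nodes_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_nodes_total = sum(end - start + 1 for _, start, end in self.runs)

    def nodes_for(self, channel: ChannelId) -> set[int]:
        out: set[int] = set()
        for ch, start, end in self.runs:
            if ch == channel:
                out.update(range(start, end + 1))
        return out

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_nodes_total": self.n_nodes_total,
            "runs": [
                {"channel": ch.label, "start": start, "end": end}
                for ch, start, end in self.runs
            ],
        }


def write_map(map_: RelevanceMap, path: str | Path) -> None:
    """Write a relevance map as a channels x nodes CSV plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        map_.values,
        index=[c.label for c in map_.channels],
        columns=[str(t) for t in range(map_.n_nodes)],
    )
    df.to_csv(path, index_label="channel", float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"state": map_.state, "meta": map_.meta}, indent=2))


def read_map(path: str | Path) -> RelevanceMap:
    path = Path(path)
    df = pd.read_csv(path, index_col="channel", float_precision="round_trip")
    channels = tuple(channel_from_label(label) for label in df.index)
    state, meta = "raw", {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        state = payload.get("state", "raw")
        meta = payload.get("meta", {})
    return RelevanceMap(values=df.to_numpy(), channels=channels, state=state, meta=meta)


def extract_high_rs(map_: RelevanceMap, threshold: float = 0.7) -> HighRsSet:
    """Extract maximal per-channel runs with RS strictly greater than threshold."""
    if map_.state != "scaled":
        raise MapStateError("high-RS extraction expects a scaled map")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    runs: list[tuple[ChannelId, int, int]] = []
    for ch, row in zip(map_.channels, map_.values):
        above = row > threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            runs.append((ch, int(start), int(stop - 1)))
    return HighRsSet(threshold=threshold, runs=runs)
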
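"""Layer-wise relevance propagation (z-rule) for the dense network.

The output score of the decomposed class is redistributed layer by layer
down to the input grid through proportional messages

    R_{i<-j} = z_ij / z_j* . R_j,        z_ij = x_i w_ij,  z_j* = sum_i z_ij

which conserves relevance at every layer. The denominator is stabilized by
``z* -> z* + eps * sign(z*)``; biases are excluded from the denominator by
default (matching the message rule as written), in which case conservation
is exact up to the stabilizer. With ``bias_in_denominator=True`` the bias
joins ``z*`` but receives no outgoing relevance, and the resulting leakage
is reported on the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .channels import ChannelId
from .mlp import ForwardTrace, NetworkModel, forward
from .tasks import FoldPlan, TaskMatrix


class LrpNumericalError(ArithmeticError):
    """A propagation denominator vanished without a stabilizer."""


@dataclass
class RelevanceMap:
    """Relevance over a channel x node grid, with processing-state flags."""

    values: np.ndarray  # (n_channels, n_nodes)
    channels: tuple[ChannelId, ...]
    state: str = "raw"  # raw | smoothed | scaled
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("relevance values must be a 2-D channel x node grid")
        if len(self.channels) != self.values.shape[0]:
            raise ValueError("channel list must match grid rows")
        if self.state not in ("raw", "smoothed", "scaled"):
            raise ValueError(f"unknown state: {self.state!r}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def total(self) -> float:
        return float(self.values.sum())


def propagate_scores(
    model: NetworkModel,
    trace: ForwardTrace,
    target_class: int | np.ndarray | None = None,
    epsilon: float = 1e-9,
    bias_in_denominator: bool = False,
) -> tuple[np.ndarray, dict]:
    """Backward-propagate output relevance to the model inputs.

    Returns ``(R, diagnostics)`` where ``R`` has shape (n_trials, input_dim)
    and diagnostics records the decomposed scores and conservation leakage
    ``sum(R_input) - f(x)`` per trial.

    ``target_class``: index (scalar or per-trial array) of the class score
    to decompose; default is the predicted class of each trial.
    """
    scores = trace.scores
    n = scores.shape[0]
    if target_class is None:
        tc = trace.predicted
    elif np.ndim(target_class) > 0:
        tc = np.asarray(target_class, dtype=int)
        if tc.shape != (n,):
            raise ValueError("per-trial target_class must have one entry per trial")
    else:
        if not 0 <= int(target_class) < model.n_classes:
            raise ValueError(f"target_class out of range: {target_class}")
        tc = np.full(n, int(target_class), dtype=int)
    if (tc < 0).any() or (tc >= model.n_classes).any():
        raise ValueError("target_class out of range")

    f_x = scores[np.arange(n), tc]
    R = np.zeros_like(scores)
    R[np.arange(n), tc] = f_x

    for li in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[li]
        x = trace.inputs[li]  # (n, fan_in)
        # z_j* per upper neuron: sum of local pre-activations (+ bias opt-in)
        zstar = x @ layer.W
        if bias_in_denominator:
            zstar = zstar + layer.b
        if epsilon > 0.0:
            denom = zstar + epsilon * np.where(zstar >= 0.0, 1.0, -1.0)
        else:
            bad = np.isclose(zstar, 0.0, atol=1e-300) & (R != 0.0)
            if bad.any():
                trial, neuron = np.argwhere(bad)[0]
                raise LrpNumericalError(
                    f"zero denominator at layer {li}, neuron {neuron} "
                    f"(trial {trial}); use a nonzero stabilizer"
                )
            denom = zstar
        s = np.where(R != 0.0, R / np.where(denom == 0.0, 1.0, denom), 0.0)
        R = x * (s @ layer.W.T)
        if not np.isfinite(R).all():
            trial, neuron = np.argwhere(~np.isfinite(R))[0]
            raise LrpNumericalError(
                f"non-finite relevance at layer {li}, neuron {neuron} (trial {trial})"
            )

    leakage = R.sum(axis=1) - f_x
    diagnostics = {
        "decomposed_score": f_x,
        "target_class": tc,
        "leakage": leakage,
        "epsilon": epsilon,
        "bias_in_denominator": bias_in_denominator,
    }
    return R, diagnostics


def propagate(
    model: NetworkModel,
    trace: ForwardTrace,
    feature_index: Sequence[tuple[ChannelId, int]],
    target_class: int | np.ndarray | None = None,
    epsilon: float = 1e-9,
    bias_in_denominator: bool = False,
) -> list[RelevanceMap]:
    """Propagate and fold relevance back onto the channel x node grid.

    ``feature_index`` is the task's column -> (channel, node) map; it must
    be channel-major (the task builder's layout).
    """
    R, diag = propagate_scores(model, trace, target_class, epsilon, bias_in_denominator)
    channels = tuple(dict.fromkeys(c for c, _ in feature_index))
    n_nodes = len(feature_index) // len(channels)
    if R.shape[1] != len(feature_index):
        raise ValueError("feature_index length must equal model input dimension")
    maps = []
    for i in range(R.shape[0]):
        maps.append(
            RelevanceMap(
                values=R[i].reshape(len(channels), n_nodes),
                channels=channels,
                state="raw",
                meta={
                    "target_class": int(diag["target_class"][i]),
                    "decomposed_score": float(diag["decomposed_score"][i]),
                    "leakage": float(diag["leakage"][i]),
                    "epsilon": epsilon,
                },
            )
        )
    return maps


def relevance_for_testset(
    models: Mapping[int, NetworkModel],
    task: TaskMatrix,
    fold_plan: FoldPlan,
    target_class: int | str | None = None,
    epsilon: float = 1e-9,
    bias_in_denominator: bool = False,
) -> list[RelevanceMap]:
    """One raw map per test trial, each under its own rotation's model.

    Every trial appears in exactly one rotation's test fold, so the result
    has one map per dataset trial; maps record the trial index, subject,
    true/predicted class, and whether the trial was correctly classified.
    ``target_class`` may be ``None``/``"predicted"`` (decompose the
    predicted class score), ``"true"`` (the true class score), or a fixed
    class index.
    """
    maps: list[RelevanceMap | None] = [None] * len(task.y)
    class_to_idx = {c: i for i, c in enumerate(models[next(iter(models))].classes)}
    for r in range(fold_plan.k):
        if r not in models:
            raise KeyError(f"missing trained model for rotation {r}")
        model = models[r]
        _, _, test_m = fold_plan.trial_masks(task.groups, r)
        idx = np.flatnonzero(test_m)
        if len(idx) == 0:
            continue
        trace = forward(model, task.X[idx])
        if target_class in (None, "predicted"):
            tc = None
        elif target_class == "true":
            tc = np.asarray([class_to_idx[l] for l in task.y[idx]])
        else:
            tc = int(target_class)
        trial_maps = propagate(
            model, trace, task.feature_index, tc, epsilon, bias_in_denominator
        )
        predicted = trace.predicted
        for pos, trial in enumerate(idx):
            m = trial_maps[pos]
            true_label = task.y[trial]
            m.meta.update(
                trial=int(trial),
                subject=int(task.groups[trial]),
                rotation=r,
                true_class=str(true_label),
                predicted_class=model.classes[predicted[pos]],
                correct=bool(class_to_idx.get(true_label, -1) == predicted[pos]),
            )
            maps[trial] = m
    return [m for m in maps if m is not None]
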
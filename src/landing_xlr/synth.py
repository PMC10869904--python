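"""Synthetic two-class landing-waveform generator.

Emulates the statistical structure of a paired fatigue-intervention landing
study: smooth per-channel base curves, subject-level random offsets shared
across the two conditions (paired design), smooth correlated trial noise,
and configurable phase-localized class-difference templates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .channels import CHANNELS, CHANNEL_INDEX, N_CHANNELS, ChannelId, channel_from_label

CLASS_BEFORE = "before_fatigue"
CLASS_AFTER = "after_fatigue"
#: Fixed class order used for tie-breaking and output layout.
CLASS_ORDER = (CLASS_BEFORE, CLASS_AFTER)

_BASE_SEED = 0x1A5D  # fixed: base curves are a property of the channel, not the run


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class EffectTemplate:
    """Class-difference template localized in a phase window.

    The window is a half-open interval ``[start, end)`` in percent of the
    landing phase; the template is added to the ``after_fatigue`` class
    expectation on the named channel.
    """

    channel: ChannelId
    window: tuple[float, float]
    amplitude: float
    shape: str = "boxcar"  # or "raised_cosine"

    def __post_init__(self) -> None:
        start, end = self.window
        if not (0.0 <= start < end <= 100.0):
            raise ConfigurationError(
                f"effect window must satisfy 0 <= start < end <= 100, got {self.window}"
            )
        if not np.isfinite(self.amplitude):
            raise ConfigurationError("effect amplitude must be finite")
        if self.shape not in ("boxcar", "raised_cosine"):
            raise ConfigurationError(f"unknown effect shape: {self.shape!r}")

    def profile(self, n_nodes: int) -> np.ndarray:
        """Node-wise additive profile of this template on an n-node grid."""
        phase = 100.0 * np.arange(n_nodes) / (n_nodes - 1)
        start, end = self.window
        mask = (phase >= start) & (phase < end)
        out = np.zeros(n_nodes)
        if self.shape == "boxcar":
            out[mask] = self.amplitude
        else:  # raised cosine (Hann bump peaking mid-window)
            u = (phase[mask] - start) / (end - start)
            out[mask] = self.amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        return out


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int
    n_trials: int
    n_nodes: int = 101
    basis_order: int = 4
    subject_sd: float = 0.0
    trial_sd: float = 0.0
    noise_smooth_sigma: float = 2.0
    effects: tuple[EffectTemplate, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_trials <= 0:
            raise ConfigurationError("n_subjects and n_trials must be positive")
        if self.n_nodes < 3:
            raise ConfigurationError("n_nodes must be >= 3")
        if self.basis_order <= 0:
            raise ConfigurationError("basis_order must be positive")
        if self.subject_sd < 0 or self.trial_sd < 0:
            raise ConfigurationError("standard deviations must be nonnegative")
        object.__setattr__(self, "effects", tuple(self.effects))

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_trials": self.n_trials,
            "n_nodes": self.n_nodes,
            "basis_order": self.basis_order,
            "subject_sd": self.subject_sd,
            "trial_sd": self.trial_sd,
            "noise_smooth_sigma": self.noise_smooth_sigma,
            "effects": [
                {
                    "channel": e.channel.label,
                    "window": list(e.window),
                    "amplitude": e.amplitude,
                    "shape": e.shape,
                }
                for e in self.effects
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        effects = tuple(
            EffectTemplate(
                channel=channel_from_label(e["channel"]),
                window=tuple(e["window"]),
                amplitude=float(e["amplitude"]),
                shape=e.get("shape", "boxcar"),
            )
            for e in d.get("effects", [])
        )
        return cls(
            n_subjects=int(d["n_subjects"]),
            n_trials=int(d["n_trials"]),
            n_nodes=int(d.get("n_nodes", 101)),
            basis_order=int(d.get("basis_order", 4)),
            subject_sd=float(d.get("subject_sd", 0.0)),
            trial_sd=float(d.get("trial_sd", 0.0)),
            noise_smooth_sigma=float(d.get("noise_smooth_sigma", 2.0)),
            effects=effects,
            seed=int(d.get("seed", 0)),
        )


@dataclass
class LandingDataset:
    """Trials x channels x nodes waveform tensor with subject and class labels.

    Row layout: all ``before_fatigue`` trials (subject-major, trial-minor),
    then all ``after_fatigue`` trials in the same subject/trial order.
    """

    data: np.ndarray  # (n_trials_total, N_CHANNELS, n_nodes)
    subject: np.ndarray  # (n_trials_total,) int subject ids
    klass: np.ndarray  # (n_trials_total,) strings in CLASS_ORDER
    meta: dict = field(default_factory=dict)

    @property
    def n_trials_total(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[2]

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject)

    def class_mask(self, klass: str) -> np.ndarray:
        return self.klass == klass

    def class_mean(self, klass: str) -> np.ndarray:
        """Mean waveform tensor (channels x nodes) over one class."""
        return self.data[self.class_mask(klass)].mean(axis=0)

    def subject_means(self, klass: str) -> np.ndarray:
        """Per-subject trial-mean tensors, shape (n_subjects, channels, nodes).

        Subjects are ordered by ascending subject id; this is the pairing
        substrate for paired statistics.
        """
        mask = self.class_mask(klass)
        out = []
        for s in self.subjects:
            sel = mask & (self.subject == s)
            if not sel.any():
                raise ValueError(f"subject {s} has no trials in class {klass}")
            out.append(self.data[sel].mean(axis=0))
        return np.asarray(out)

    def validate(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1] != N_CHANNELS:
            raise ValueError("data must be (trials, 18, nodes)")
        if not np.isfinite(self.data).all():
            raise ValueError("dataset contains non-finite values")
        if len(self.subject) != len(self.klass) or len(self.subject) != len(self.data):
            raise ValueError("label vectors must match trial count")
        for s in self.subjects:
            counts = [((self.subject == s) & (self.klass == c)).sum() for c in CLASS_ORDER]
            if len(set(counts)) != 1:
                raise ValueError(f"subject {s} has unbalanced per-class trial counts")


def base_curves(n_nodes: int, basis_order: int) -> np.ndarray:
    """Smooth per-channel base waveforms, shape (channels, nodes).

    Built from a low-order sinusoid basis with per-channel coefficients drawn
    from a fixed stream keyed on the channel index, so the curves are a
    stable property of the channel identity (independent of the run seed).
    """
    t = np.arange(n_nodes) / (n_nodes - 1)
    curves = np.empty((N_CHANNELS, n_nodes))
    for ci in range(N_CHANNELS):
        rng = np.random.default_rng([_BASE_SEED, ci, basis_order])
        curve = np.zeros(n_nodes)
        for h in range(1, basis_order + 1):
            amp = rng.normal(0.0, 1.0) / h
            phase = rng.uniform(0.0, 2.0 * np.pi)
            curve += amp * np.sin(np.pi * h * t + phase)
        curves[ci] = curve
    return curves


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sd: float, sigma: float
) -> np.ndarray:
    """Smooth correlated noise with exact per-node marginal SD ``sd``.

    White noise on a padded grid is convolved with a Gaussian kernel
    normalized to unit l2 norm ('valid' mode), which preserves the marginal
    variance at every node including the edges.
    """
    if sd == 0.0:
        return np.zeros(shape)
    n_nodes = shape[-1]
    if sigma <= 0:
        return rng.normal(0.0, sd, size=shape)
    half = max(1, int(np.ceil(4 * sigma)))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    kernel /= np.linalg.norm(kernel)
    padded = rng.normal(0.0, sd, size=shape[:-1] + (n_nodes + 2 * half,))
    flat = padded.reshape(-1, n_nodes + 2 * half)
    out = np.empty((flat.shape[0], n_nodes))
    for i, row in enumerate(flat):
        out[i] = np.convolve(row, kernel, mode="valid")
    return out.reshape(shape[:-1] + (n_nodes,))


def generate_dataset(config: GeneratorConfig) -> LandingDataset:
    """Generate a paired two-class dataset per ``config``.

    The two classes share subjects and subject-level random offsets; the
    ``after_fatigue`` class expectation additionally carries the summed
    effect templates. Identical seed => byte-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    n_sub, n_tri, n_nodes = config.n_subjects, config.n_trials, config.n_nodes
    base = base_curves(n_nodes, config.basis_order)

    effect_grid = np.zeros((N_CHANNELS, n_nodes))
    for eff in config.effects:
        effect_grid[CHANNEL_INDEX[eff.channel]] += eff.profile(n_nodes)

    # subject offset: constant over nodes, independent per subject x channel
    subject_offset = rng.normal(0.0, config.subject_sd, size=(n_sub, N_CHANNELS))

    n_per_class = n_sub * n_tri
    data = np.empty((2 * n_per_class, N_CHANNELS, n_nodes))
    subject = np.empty(2 * n_per_class, dtype=np.int64)
    klass = np.empty(2 * n_per_class, dtype=object)

    row = 0
    for class_idx, class_name in enumerate(CLASS_ORDER):
        for s in range(n_sub):
            mean = base + subject_offset[s][:, None]
            if class_idx == 1:
                mean = mean + effect_grid
            for _ in range(n_tri):
                noise = _smooth_noise(
                    rng, (N_CHANNELS, n_nodes), config.trial_sd, config.noise_smooth_sigma
                )
                data[row] = mean + noise
                subject[row] = s
                klass[row] = class_name
                row += 1

    ds = LandingDataset(
        data=data,
        subject=subject,
        klass=np.asarray(klass, dtype=object),
        meta={"generator": config.to_dict()},
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# CSV round-trip


class DatasetParseError(ValueError):
    """Malformed dataset table."""


def _expected_columns(n_nodes: int) -> list[str]:
    cols = ["subject", "class"]
    for ch in CHANNELS:
        cols.extend(f"{ch.label}_{node}" for node in range(n_nodes))
    return cols


def write_dataset(dataset: LandingDataset, path: str | Path) -> None:
    """Write the dataset as a wide CSV (plus a JSON config sidecar if known)."""
    path = Path(path)
    n_nodes = dataset.n_nodes
    flat = dataset.data.reshape(dataset.n_trials_total, N_CHANNELS * n_nodes)
    df = pd.DataFrame(flat, columns=_expected_columns(n_nodes)[2:])
    df.insert(0, "class", dataset.klass)
    df.insert(0, "subject", dataset.subject)
    df.to_csv(path, index=False, float_format="%.17g")  # round-trip precision
    if dataset.meta:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(dataset.meta, indent=2))


def read_dataset(path: str | Path) -> LandingDataset:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    for required in ("subject", "class"):
        if required not in cols:
            raise DatasetParseError(f"missing required column: {required!r}")
    n_value_cols = len(cols) - 2
    if n_value_cols % N_CHANNELS != 0:
        raise DatasetParseError(
            f"value column count {n_value_cols} is not a multiple of {N_CHANNELS} channels"
        )
    n_nodes = n_value_cols // N_CHANNELS
    expected = _expected_columns(n_nodes)
    if cols != expected:
        for got, want in zip(cols, expected):
            if got != want:
                raise DatasetParseError(
                    f"unexpected column {got!r} (expected {want!r}); "
                    "columns must follow the documented channel-major order"
                )
        raise DatasetParseError("column count mismatch")  # pragma: no cover
    values = df[expected[2:]].to_numpy(dtype=float)
    data = values.reshape(len(df), N_CHANNELS, n_nodes)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
        except json.JSONDecodeError:
            warnings.warn(f"ignoring unreadable sidecar {sidecar}")
    ds = LandingDataset(
        data=data,
        subject=df["subject"].to_numpy(dtype=np.int64),
        klass=df["class"].to_numpy(dtype=object),
        meta=meta,
    )
    ds.validate()
    return ds
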
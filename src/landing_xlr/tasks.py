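"""Channel-subset task matrices, subject-grouped folds, and the Zero-R baseline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNELS, ChannelId, Joint, Plane, Quantity
from .synth import CLASS_ORDER, LandingDataset

#: The nine channel-subset tasks, in canonical order (matching M1..M9).
TASK_IDS: tuple[str, ...] = (
    "all",
    "kinematics",
    "kinetics",
    "ankle",
    "knee",
    "hip",
    "sagittal",
    "frontal",
    "transversal",
)


def task_channels(task: str) -> tuple[ChannelId, ...]:
    """Channel subset for one task, in canonical channel order."""
    if task == "all":
        pred = lambda c: True
    elif task == "kinematics":
        pred = lambda c: c.quantity is Quantity.ANGLE
    elif task == "kinetics":
        pred = lambda c: c.quantity is Quantity.MOMENT
    elif task in Joint._value2member_map_:
        joint = Joint(task)
        pred = lambda c: c.joint is joint
    elif task in Plane._value2member_map_:
        plane = Plane(task)
        pred = lambda c: c.plane is plane
    else:
        raise ValueError(f"unknown task: {task!r} (expected one of {TASK_IDS})")
    return tuple(c for c in CHANNELS if pred(c))


@dataclass
class TaskMatrix:
    """Flattened feature matrix for one classification task.

    Features are channel-major then node: column ``c * n_nodes + t`` holds
    channel ``channels[c]`` at node ``t``. ``feature_index`` materializes
    that map so relevance can be folded back onto the channel x node grid.
    """

    task: str
    X: np.ndarray  # (n_trials, n_features)
    y: np.ndarray  # (n_trials,) class labels
    groups: np.ndarray  # (n_trials,) subject ids
    channels: tuple[ChannelId, ...]
    n_nodes: int
    feature_index: list[tuple[ChannelId, int]] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_task(dataset: LandingDataset, task: str) -> TaskMatrix:
    channels = task_channels(task)
    idx = [CHANNELS.index(c) for c in channels]
    n_nodes = dataset.n_nodes
    X = dataset.data[:, idx, :].reshape(dataset.n_trials_total, len(channels) * n_nodes)
    if not np.isfinite(X).all():
        raise ValueError("task matrix contains non-finite values")
    feature_index = [(c, t) for c in channels for t in range(n_nodes)]
    return TaskMatrix(
        task=task,
        X=X,
        y=dataset.klass.copy(),
        groups=dataset.subject.copy(),
        channels=channels,
        n_nodes=n_nodes,
        feature_index=feature_index,
    )


@dataclass
class FoldPlan:
    """Subject-level assignment to k folds with a rotating train/val/test scheme.

    Per rotation ``r``: fold ``r`` is the test part, fold ``(r+1) % k`` the
    validation part, and the remaining ``k - 2`` folds are the training part.
    All trials of a subject share its fold.
    """

    k: int
    assignment: dict[int, int]  # subject id -> fold index

    def fold_subjects(self, fold: int) -> list[int]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def rotation_roles(self, rotation: int) -> tuple[list[int], list[int], list[int]]:
        """(train_subjects, validation_subjects, test_subjects) for one rotation."""
        if not 0 <= rotation < self.k:
            raise ValueError(f"rotation must be in [0, {self.k}), got {rotation}")
        test = self.fold_subjects(rotation)
        val = self.fold_subjects((rotation + 1) % self.k)
        train = sorted(
            s
            for s, f in self.assignment.items()
            if f not in (rotation, (rotation + 1) % self.k)
        )
        return train, val, test

    def trial_masks(
        self, groups: np.ndarray, rotation: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        train, val, test = self.rotation_roles(rotation)
        return (
            np.isin(groups, train),
            np.isin(groups, val),
            np.isin(groups, test),
        )


def grouped_kfold(subjects: np.ndarray | LandingDataset, k: int, seed: int) -> FoldPlan:
    """Assign subjects to k folds of near-equal size, deterministically per seed."""
    if isinstance(subjects, LandingDataset):
        subjects = subjects.subjects
    subjects = np.unique(np.asarray(subjects))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds number of subjects ({len(subjects)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignment: dict[int, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for pos in chunk:
            assignment[int(subjects[pos])] = fold
    return FoldPlan(k=k, assignment=assignment)


def zeror_baseline(y_train: np.ndarray, y_test: np.ndarray) -> float:
    """Majority-class baseline accuracy.

    The predicted label is the most frequent class in ``y_train``; ties are
    broken by the fixed class order (``before_fatigue`` first), falling back
    to sorted label order for unknown labels.
    """
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if len(y_train) == 0 or len(y_test) == 0:
        raise ValueError("label vectors must be non-empty")
    labels, counts = np.unique(y_train, return_counts=True)

    def rank(label: object) -> tuple[int, str]:
        try:
            return (CLASS_ORDER.index(label), "")
        except ValueError:
            return (len(CLASS_ORDER), str(label))

    # highest count wins; ties resolved by the fixed class order
    max_count = counts.max()
    tied = [l for l, c in zip(labels, counts) if c == max_count]
    majority = min(tied, key=rank)
    return float(np.mean(y_test == majority))
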
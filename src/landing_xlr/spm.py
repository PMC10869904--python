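"""1-D statistical parametric mapping for paired waveform comparisons.

Node-wise paired-samples t trajectories over the 101-node landing phase,
with a family-wise critical threshold from 1-D random field theory (Euler
characteristic of a t field at the residual smoothness), a sign-flip
permutation threshold as a distribution-free cross-check, and the
Rosenthal t -> r effect-size transform with configurable banding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .relevance import HighRsSet

_FOUR_LN2 = 4.0 * np.log(2.0)
_FWHM_CAP = 1e6  # constant-in-node residuals -> effectively one resel


@dataclass
class SpmResult:
    """Paired-t trajectory with its critical threshold and clusters."""

    t: np.ndarray  # (n_nodes,)
    df: int
    fwhm: float
    t_crit: float
    clusters: list[tuple[int, int]]  # inclusive node runs with |t| > t_crit
    alpha: float
    zero_variance_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def supra_nodes(self) -> set[int]:
        out: set[int] = set()
        for start, end in self.clusters:
            out.update(range(start, end + 1))
        return out

    def to_dict(self) -> dict:
        return {
            "t": self.t.tolist(),
            "df": self.df,
            "fwhm": self.fwhm,
            "t_crit": self.t_crit,
            "alpha": self.alpha,
            "clusters": [list(c) for c in self.clusters],
            "zero_variance_nodes": self.zero_variance_nodes.tolist(),
        }


def paired_t_trajectory(class_a: np.ndarray, class_b: np.ndarray) -> tuple[np.ndarray, int]:
    """Node-wise paired t statistic for matched rows (a minus b).

    Inputs are (n_subjects, n_nodes) matrices with matched subject rows.
    Returns ``(t, df)`` with ``df = n - 1``. Zero-variance nodes yield
    signed infinities (or NaN when the difference is identically zero);
    callers flag and exclude them.
    """
    a = np.atleast_2d(np.asarray(class_a, dtype=float))
    b = np.atleast_2d(np.asarray(class_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("matched matrices must have identical shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t needs at least 2 matched rows")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t, n - 1


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Residual smoothness (FWHM, in nodes) of a 1-D field.

    Standard RFT estimator: the per-node variance of the normalized residual
    gradient gives resels-per-node; FWHM is the reciprocal of its mean.
    Degenerate (constant-in-node) residuals return a large capped value.
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    if r.shape[1] < 2:
        raise ValueError("need at least 2 nodes to estimate smoothness")
    ssq = (r**2).sum(axis=0)
    grad = np.gradient(r, axis=1)
    v = (grad**2).sum(axis=0)
    good = ssq > 0
    if not good.any():
        return _FWHM_CAP
    v = v[good] / ssq[good]
    resels_per_node = np.sqrt(v / _FOUR_LN2)
    mean_rpn = resels_per_node.mean()
    if mean_rpn <= 1.0 / _FWHM_CAP:
        return _FWHM_CAP
    return float(min(1.0 / mean_rpn, _FWHM_CAP))


def _ec_survival(u: float, df: int, resels: float) -> float:
    """Expected Euler characteristic of the |field| > u excursion, one tail."""
    rho0 = stats.t.sf(u, df)
    rho1 = resels * np.sqrt(_FOUR_LN2) / (2.0 * np.pi) * (1.0 + u * u / df) ** (
        -(df - 1) / 2.0
    )
    return rho0 + rho1


def rft_threshold(df: int, fwhm: float, n_nodes: int, alpha: float = 0.05) -> float:
    """Two-tailed RFT critical t for a 1-D field of ``n_nodes`` nodes.

    Solves ``EC(u) = alpha / 2`` with ``resels = (n_nodes - 1) / fwhm``;
    the result is clamped between the pointwise two-tailed quantile (the
    one-resel limit) and the Bonferroni-over-nodes bound.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    resels = (n_nodes - 1) / fwhm
    pointwise = float(stats.t.isf(alpha / 2.0, df))
    bonferroni = float(stats.t.isf(alpha / (2.0 * n_nodes), df))
    target = alpha / 2.0
    if _ec_survival(pointwise, df, resels) <= target:
        return pointwise
    hi = bonferroni
    if _ec_survival(hi, df, resels) > target:
        return bonferroni
    u = optimize.brentq(lambda x: _ec_survival(x, df, resels) - target, pointwise, hi)
    return float(min(max(u, pointwise), bonferroni))


def permutation_threshold(
    paired_diffs: np.ndarray, alpha: float = 0.05, n_perm: int = 1000, seed: int = 0
) -> float:
    """Sign-flip max-|t| permutation critical value (two-tailed).

    Random sign flips of whole subject difference curves; returns the
    (1 - alpha) quantile of the maximum absolute t over nodes.
    """
    d = np.atleast_2d(np.asarray(paired_diffs, dtype=float))
    n = d.shape[0]
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if 2.0**n < 1.0 / alpha:
        import warnings

        warnings.warn(
            f"only 2^{n} distinct sign patterns; permutation threshold at "
            f"alpha={alpha} is coarse"
        )
    rng = np.random.default_rng(seed)
    sqrt_n = np.sqrt(n)
    max_t = np.empty(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        dp = d * signs[:, None]
        mean = dp.mean(axis=0)
        sd = dp.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(mean / (sd / sqrt_n))
        max_t[p] = np.nanmax(np.where(np.isfinite(t), t, np.nan))
    return float(np.quantile(max_t, 1.0 - alpha))


def _clusters_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [(int(s), int(e - 1)) for s, e in zip(edges[::2], edges[1::2])]


def spm_paired_t(
    class_a: np.ndarray,
    class_b: np.ndarray,
    alpha: float = 0.05,
    method: str = "rft",
    n_perm: int = 1000,
    seed: int = 0,
) -> SpmResult:
    """Full paired SPM analysis: t trajectory, threshold, clusters.

    Smoothness is estimated from the mean-centered difference curves
    (the model residuals of the paired design). Zero-variance nodes are
    flagged and excluded from smoothness and threshold estimation.
    """
    t, df = paired_t_trajectory(class_a, class_b)
    d = np.asarray(class_a, dtype=float) - np.asarray(class_b, dtype=float)
    residuals = d - d.mean(axis=0)
    zero_var = np.flatnonzero(~np.isfinite(t) | (residuals.std(axis=0) == 0))
    finite = np.isfinite(t)
    fwhm = estimate_fwhm(residuals[:, finite] if finite.sum() >= 2 else residuals)
    if method == "rft":
        t_crit = rft_threshold(df, fwhm, residuals.shape[1], alpha)
    elif method == "permutation":
        t_crit = permutation_threshold(d, alpha, n_perm, seed)
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    mask = np.zeros(t.shape, dtype=bool)
    mask[finite] = np.abs(t[finite]) > t_crit
    return SpmResult(
        t=t,
        df=df,
        fwhm=fwhm,
        t_crit=t_crit,
        clusters=_clusters_from_mask(mask),
        alpha=alpha,
        zero_variance_nodes=zero_var,
    )


# ---------------------------------------------------------------------------
# Effect size


@dataclass
class EffectSizeTrajectory:
    r: np.ndarray  # (n_nodes,) in [0, 1)
    cutoffs: tuple[float, float]
    bands: np.ndarray = field(init=False)  # 0: small, 1: medium, 2: large

    def __post_init__(self) -> None:
        lo, hi = self.cutoffs
        self.bands = np.digitize(self.r, [lo, hi])

    def to_dict(self) -> dict:
        return {
            "r": self.r.tolist(),
            "cutoffs": list(self.cutoffs),
            "bands": self.bands.tolist(),
        }


def effect_size_r(
    t: np.ndarray | float, df: int, cutoffs: tuple[float, float] = (0.5, 0.8)
) -> EffectSizeTrajectory:
    """Rosenthal transform ``r = sqrt(t^2 / (t^2 + df))``, node-wise."""
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    with np.errstate(invalid="ignore"):
        r = np.sqrt(t * t / (t * t + df))
    r = np.where(np.isfinite(t), r, 1.0)  # infinite t -> limit r = 1
    return EffectSizeTrajectory(r=r, cutoffs=cutoffs)


# ---------------------------------------------------------------------------
# RS vs SPM concordance


@dataclass
class ConcordanceReport:
    """Per-channel overlap between high-RS runs and SPM clusters."""

    per_channel: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {"per_channel": self.per_channel}


def _overlap_stats(rs_nodes: set[int], spm_nodes: set[int]) -> dict[str, float]:
    inter = len(rs_nodes & spm_nodes)
    union = len(rs_nodes | spm_nodes)
    return {
        "n_rs": float(len(rs_nodes)),
        "n_spm": float(len(spm_nodes)),
        "n_intersection": float(inter),
        "jaccard": inter / union if union else 0.0,
        "coverage_of_rs": inter / len(rs_nodes) if rs_nodes else 0.0,
        "coverage_of_spm": inter / len(spm_nodes) if spm_nodes else 0.0,
    }


def concordance(
    high_rs: HighRsSet, spm_by_channel: Mapping[object, SpmResult]
) -> ConcordanceReport:
    """Quantify how well high-RS runs coincide with supra-threshold clusters.

    ``spm_by_channel`` maps channels (or labels) to per-channel SpmResults
    on the same node grid. Node counting is inclusive at both run ends.
    """
    per_channel: dict[str, dict[str, float]] = {}
    grid_len: int | None = None
    for ch, spm in spm_by_channel.items():
        if grid_len is None:
            grid_len = len(spm.t)
        elif len(spm.t) != grid_len:
            raise ValueError("all SPM results must share the same node grid")
        label = getattr(ch, "label", str(ch))
        channel = ch if hasattr(ch, "label") else None
        rs_nodes = high_rs.nodes_for(channel) if channel is not None else set()
        if channel is None:
            for run_ch, start, end in high_rs.runs:
                if run_ch.label == label:
                    rs_nodes.update(range(start, end + 1))
        if rs_nodes and max(rs_nodes) >= grid_len:
            raise ValueError("high-RS nodes exceed the SPM node grid")
        per_channel[label] = _overlap_stats(rs_nodes, spm.supra_nodes())
    return ConcordanceReport(per_channel=per_channel)
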
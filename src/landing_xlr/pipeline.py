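"""End-to-end orchestration: synth -> tasks -> train -> explain -> spm -> report."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .channels import CHANNELS, CHANNEL_INDEX
from .lrp import relevance_for_testset
from .mlp import Hyperparams, evaluate_cv
from .relevance import (
    SmoothingSpec,
    aggregate_contributions,
    average_maps,
    extract_high_rs,
    scale_rs,
    smooth_rs,
)
from .spm import concordance, effect_size_r, spm_paired_t
from .synth import CLASS_AFTER, CLASS_BEFORE, GeneratorConfig, LandingDataset, generate_dataset
from .tasks import TASK_IDS, build_task, grouped_kfold

# stage offsets for fanning the top-level seed out to per-stage streams
_STAGE_OFFSETS = {"synth": 0, "folds": 1, "train": 2, "explain": 3, "spm": 4}

#: Injected-effect benchmark: one boxcar on the knee sagittal angle, phase
#: window [15, 25), amplitude far above the noise floor (Bayes error << 1%).
BENCHMARK_CHANNEL = CHANNELS[CHANNEL_INDEX[[c for c in CHANNELS if c.label == "knee_sagittal_angle"][0]]]
BENCHMARK_WINDOW = (15.0, 25.0)


def benchmark_generator(
    n_subjects: int = 16,
    n_trials: int = 3,
    amplitude: float = 2.0,
    seed: int = 0,
    with_effect: bool = True,
) -> GeneratorConfig:
    """Scaled-down synthetic benchmark used by the end-to-end checks."""
    from .synth import EffectTemplate

    effects = (
        (EffectTemplate(channel=BENCHMARK_CHANNEL, window=BENCHMARK_WINDOW, amplitude=amplitude),)
        if with_effect
        else ()
    )
    return GeneratorConfig(
        n_subjects=n_subjects,
        n_trials=n_trials,
        subject_sd=0.05,
        trial_sd=0.1,
        noise_smooth_sigma=1.0,
        effects=effects,
        seed=seed,
    )


def benchmark_hyperparams() -> Hyperparams:
    """Training settings that recover the benchmark effect reliably."""
    return Hyperparams(
        preprocess="center",
        learning_rate=0.3,
        l2=0.01,
        init_scale=0.1,
        max_epochs=1500,
        patience=50,
    )


@dataclass
class RunConfig:
    generator: GeneratorConfig
    tasks: tuple[str, ...] = TASK_IDS
    k: int = 8
    seed: int = 0
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    lrp_epsilon: float = 1e-9
    lrp_bias_in_denominator: bool = False
    lrp_target: str = "predicted"  # or "true"
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    rs_threshold: float = 0.7
    early_window: tuple[int, int] = (1, 22)
    alpha: float = 0.05
    spm_method: str = "rft"
    map_selection: str = "correct"

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, _STAGE_OFFSETS[stage]]).generate_state(1)[0]
        )

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "tasks": list(self.tasks),
            "k": self.k,
            "seed": self.seed,
            "hyperparams": self.hyperparams.to_dict(),
            "lrp_epsilon": self.lrp_epsilon,
            "lrp_bias_in_denominator": self.lrp_bias_in_denominator,
            "lrp_target": self.lrp_target,
            "smoothing": {
                "weights": list(self.smoothing.weights),
                "repetitions": self.smoothing.repetitions,
                "boundary": self.smoothing.boundary,
            },
            "rs_threshold": self.rs_threshold,
            "early_window": list(self.early_window),
            "alpha": self.alpha,
            "spm_method": self.spm_method,
            "map_selection": self.map_selection,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(raw: dict) -> tuple[RunConfig | None, list[str]]:
    """Build a RunConfig from a plain dict, collecting all violations."""
    errors: list[str] = []
    gen = None
    try:
        gen = GeneratorConfig.from_dict(raw.get("generator", {}))
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"generator: {exc}")
    tasks = tuple(raw.get("tasks", TASK_IDS))
    for t in tasks:
        if t not in TASK_IDS:
            errors.append(f"tasks: unknown task {t!r}")
    k = raw.get("k", 8)
    if not isinstance(k, int) or k < 2:
        errors.append("k: must be an integer >= 2")
    threshold = raw.get("rs_threshold", 0.7)
    if not 0.0 <= threshold <= 1.0:
        errors.append("rs_threshold: must lie in [0, 1]")
    alpha = raw.get("alpha", 0.05)
    if not 0.0 < alpha < 1.0:
        errors.append("alpha: must lie in (0, 1)")
    try:
        hp = Hyperparams(**raw.get("hyperparams", {}))
    except TypeError as exc:
        errors.append(f"hyperparams: {exc}")
        hp = Hyperparams()
    smoothing_raw = raw.get("smoothing", {})
    try:
        smoothing = SmoothingSpec(
            weights=tuple(smoothing_raw.get("weights", (0.25, 0.5, 0.25))),
            repetitions=int(smoothing_raw.get("repetitions", 3)),
            boundary=smoothing_raw.get("boundary", "renormalize"),
        )
    except ValueError as exc:
        errors.append(f"smoothing: {exc}")
        smoothing = SmoothingSpec()
    early = tuple(raw.get("early_window", (1, 22)))
    if len(early) != 2 or early[0] > early[1] or early[0] < 0:
        errors.append("early_window: must be (lo, hi) with 0 <= lo <= hi")
    if errors or gen is None:
        return None, errors
    return (
        RunConfig(
            generator=gen,
            tasks=tasks,
            k=int(k),
            seed=int(raw.get("seed", 0)),
            hyperparams=hp,
            lrp_epsilon=float(raw.get("lrp_epsilon", 1e-9)),
            lrp_bias_in_denominator=bool(raw.get("lrp_bias_in_denominator", False)),
            lrp_target=raw.get("lrp_target", "predicted"),
            smoothing=smoothing,
            rs_threshold=float(threshold),
            early_window=(int(early[0]), int(early[1])),
            alpha=float(alpha),
            spm_method=raw.get("spm_method", "rft"),
            map_selection=raw.get("map_selection", "correct"),
        ),
        [],
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def explain_task(
    dataset: LandingDataset, task_id: str, config: RunConfig
) -> dict[str, Any]:
    """Classify one task, propagate relevance, and post-process the maps."""
    task = build_task(dataset, task_id)
    fold_plan = grouped_kfold(dataset, config.k, config.stage_seed("folds"))
    report, models = evaluate_cv(
        task, fold_plan, config.hyperparams, config.stage_seed("train"), return_models=True
    )
    maps = relevance_for_testset(
        models,
        task,
        fold_plan,
        target_class=config.lrp_target,
        epsilon=config.lrp_epsilon,
        bias_in_denominator=config.lrp_bias_in_denominator,
    )
    mean_map = average_maps(maps, selection=config.map_selection)
    smoothed = smooth_rs(mean_map, config.smoothing)
    scaled = scale_rs(smoothed)
    contributions = aggregate_contributions(scaled, config.early_window)
    high_rs = extract_high_rs(scaled, config.rs_threshold)
    return {
        "task": task,
        "fold_plan": fold_plan,
        "cv_report": report,
        "maps": maps,
        "scaled_map": scaled,
        "contributions": contributions,
        "high_rs": high_rs,
    }


def spm_per_channel(dataset: LandingDataset, config: RunConfig) -> dict:
    """Paired SPM + effect sizes for every channel's waveform."""
    before = dataset.subject_means(CLASS_BEFORE)
    after = dataset.subject_means(CLASS_AFTER)
    results = {}
    for ch in CHANNELS:
        ci = CHANNEL_INDEX[ch]
        spm = spm_paired_t(
            after[:, ci, :],
            before[:, ci, :],
            alpha=config.alpha,
            method=config.spm_method,
            seed=config.stage_seed("spm"),
        )
        finite_t = np.where(np.isfinite(spm.t), spm.t, 0.0)
        results[ch] = {"spm": spm, "effect_size": effect_size_r(finite_t, spm.df)}
    return results


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and assemble the run report.

    When ``out_dir`` is given, artifacts (dataset CSV, per-task JSON blocks,
    report) are written there as they are produced, so a failing stage
    leaves its predecessors' outputs on disk.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
        "tasks": {},
    }

    def _log(stage: str, t0: float) -> None:
        report["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

    t0 = time.perf_counter()
    try:
        dataset = generate_dataset(config.generator)
    except Exception as exc:
        raise StageError("synth", exc) from exc
    _log("synth", t0)
    if out is not None:
        from .synth import write_dataset

        write_dataset(dataset, out / "dataset.csv")

    for task_id in config.tasks:
        t0 = time.perf_counter()
        try:
            block = explain_task(dataset, task_id, config)
        except Exception as exc:
            if out is not None:
                (out / "report.partial.json").write_text(json.dumps(report, indent=2))
            raise StageError(f"task:{task_id}", exc) from exc
        _log(f"task:{task_id}", t0)
        task_report = {
            "cv": block["cv_report"].to_dict(),
            "contributions": block["contributions"].to_dict(),
            "high_rs": block["high_rs"].to_dict(),
        }
        if task_id == "all":
            task_report["_block"] = block  # kept in-memory for concordance
        report["tasks"][task_id] = task_report

    t0 = time.perf_counter()
    try:
        spm_results = spm_per_channel(dataset, config)
    except Exception as exc:
        raise StageError("spm", exc) from exc
    _log("spm", t0)
    report["spm"] = {
        ch.label: {
            "t_crit": res["spm"].t_crit,
            "fwhm": res["spm"].fwhm,
            "clusters": [list(c) for c in res["spm"].clusters],
            "max_abs_t": float(np.nanmax(np.abs(res["spm"].t))),
            "max_r": float(res["effect_size"].r.max()),
        }
        for ch, res in spm_results.items()
    }

    if "all" in report["tasks"]:
        block = report["tasks"]["all"].pop("_block")
        conc = concordance(
            block["high_rs"], {ch: res["spm"] for ch, res in spm_results.items()}
        )
        report["concordance"] = conc.to_dict()

    if out is not None:
        serializable = {k: v for k, v in report.items()}
        (out / "report.json").write_text(json.dumps(serializable, indent=2))
    return report
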
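import numpy as np
import pytest

import landing_xlr as lx
from landing_xlr.pipeline import benchmark_generator, benchmark_hyperparams

KNEE_SAG_ANGLE = lx.ChannelId(lx.Joint.KNEE, lx.Plane.SAGITTAL, lx.Quantity.ANGLE)


@pytest.fixture(scope="session")
def small_dataset():
    """8 subjects x 2 trials with the benchmark knee effect."""
    return lx.generate_dataset(benchmark_generator(n_subjects=8, n_trials=2, seed=11))


@pytest.fixture(scope="session")
def small_run(small_dataset):
    """Trained CV models + per-trial relevance maps on the knee task."""
    task = lx.build_task(small_dataset, "knee")
    plan = lx.grouped_kfold(small_dataset, 4, 3)
    report, models = lx.evaluate_cv(
        task, plan, benchmark_hyperparams(), seed=3, return_models=True
    )
    maps = lx.relevance_for_testset(models, task, plan)
    return {
        "dataset": small_dataset,
        "task": task,
        "plan": plan,
        "report": report,
        "models": models,
        "maps": maps,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_relevance_map(rng, n_channels=18, n_nodes=101, state="scaled"):
    values = rng.uniform(0.0, 1.0, size=(n_channels, n_nodes))
    return lx.RelevanceMap(values=values, channels=lx.CHANNELS[:n_channels], state=state)
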
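"""Shared fixtures: a small generated corpus and one trained pipeline.

Thread counts are pinned to 1 before numpy is imported so that training
trajectories (and therefore every downstream assertion) are
bit-reproducible regardless of how many cores the host machine has.
"""

import os

for _var in (
    "OPENBLAS_NUM_THREADS",
    "OMP_NUM_THREADS",
    "MKL_NUM_THREADS",
    "NUMEXPR_NUM_THREADS",
):
    os.environ.setdefault(_var, "1")

import pytest  # noqa: E402

from cardioicd.experiments import ExperimentConfig, run_experiment  # noqa: E402
from cardioicd.model import ModelConfig  # noqa: E402
from cardioicd.synthetic import GeneratorConfig, default_profiles, generate  # noqa: E402


def small_generator_config(**overrides) -> GeneratorConfig:
    """Four-code corpus with geen-only negation; the suite's workhorse."""
    base = dict(
        n_letters=800,
        profiles=default_profiles()[:4],
        target_cardinality=2.0,
        negation_terms=("geen",),
        negation_rate=0.5,
        seed=43,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_synthetic():
    """Generated corpus + PHI gold spans for the shared fixture config."""
    return generate(small_generator_config())


@pytest.fixture(scope="session")
def trained_pipeline():
    """One full experiment-II run on the shared fixture (trained once)."""
    config = ExperimentConfig(
        experiment="II_full_text",
        generator=small_generator_config(),
        model=ModelConfig.test_profile(),
        compute_coefficients=False,
        seed=43,
    )
    return run_experiment(config)
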
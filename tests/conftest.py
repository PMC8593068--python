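import numpy as np
import pandas as pd
import pytest

from clinnet import GeneratorConfig, simulate_study
from clinnet.config import reference_generator
from clinnet.simulate import ArmConfig, RevisionRule


@pytest.fixture(scope="session")
def reference_cfg() -> GeneratorConfig:
    return reference_generator(master_seed=12345)


@pytest.fixture(scope="session")
def reference_study(reference_cfg) -> pd.DataFrame:
    return simulate_study(reference_cfg)


def make_cfg(**overrides) -> GeneratorConfig:
    """A small, fast two-trial configuration; override freely."""
    arms = {
        "black_female": ArmConfig(
            estimate_mean=25.0,
            estimate_sd=20.0,
            initial_choice_probs=(0.299, 0.37, 0.141, 0.19),
        ),
        "white_male": ArmConfig(
            estimate_mean=25.0,
            estimate_sd=20.0,
            initial_choice_probs=(0.234, 0.33, 0.214, 0.222),
        ),
    }
    base = dict(
        arms=arms,
        n_trials=2,
        n_network_per_arm=10,
        n_control_per_arm=5,
        network_degree=4,
        revision=RevisionRule(alpha=0.05, beta=0.9, noise_sd=2.0),
        master_seed=7,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture()
def small_cfg() -> GeneratorConfig:
    return make_cfg()


@pytest.fixture(scope="session")
def small_study() -> pd.DataFrame:
    return simulate_study(make_cfg())


def records_from_choices(choices_by_arm, round_no=1, condition="control", trial_id=1):
    """Hand-build a minimal records table from per-arm recommendation lists."""
    rows = []
    for arm, choices in choices_by_arm.items():
        for i, rec in enumerate(choices):
            rows.append(
                {
                    "trial_id": trial_id,
                    "condition": condition,
                    "arm": arm,
                    "clinician_id": f"{arm}-{i}",
                    "round": round_no,
                    "estimate": 50.0,
                    "recommendation": rec,
                    "network_position": pd.NA,
                    "completed": 1,
                }
            )
    df = pd.DataFrame(rows)
    df["network_position"] = df["network_position"].astype("Int64")
    return df


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
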
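import numpy as np
import pytest

from lxt.synthetic_data import (
    GenoSimConfig,
    TraitSpec,
    TrialSimConfig,
    simulate_genotypes,
    simulate_trial,
)


def yield_only_spec(**overrides) -> dict[str, TraitSpec]:
    """A single-trait variance configuration for fast, targeted trials."""
    base = dict(
        mu={"infested": 5300.0, "non_infested": 5300.0},
        sigma2_gca_line=310_000.0,
        sigma2_gca_tester=90_000.0,
        sigma2_sca=130_000.0,
        sigma2_env=2_000_000.0,
        sigma2_rep=300_000.0,
        sigma2_block=170_000.0,
        sigma2_line_env=140_000.0,
        sigma2_tester_env=45_000.0,
        sigma2_sca_env=125_000.0,
        sigma2_error=1_000_000.0,
        bounds=(0.0, None),
    )
    base.update(overrides)
    return {"yield": TraitSpec(**base)}


def small_trial_config(seed: int = 7, **kwargs) -> TrialSimConfig:
    defaults = dict(
        n_lines=5,
        environments={"infested": 2, "non_infested": 2},
        traits=yield_only_spec(),
        seed=seed,
    )
    defaults.update(kwargs)
    return TrialSimConfig(**defaults)


@pytest.fixture(scope="session")
def small_trial():
    cfg = small_trial_config()
    frame, truth = simulate_trial(cfg)
    return cfg, frame, truth


@pytest.fixture(scope="session")
def default_trial():
    cfg = TrialSimConfig(seed=11)
    frame, truth = simulate_trial(cfg)
    return cfg, frame, truth


@pytest.fixture(scope="session")
def small_panel():
    cfg = GenoSimConfig(
        n_samples=20,
        n_markers=400,
        qc_fail_missing=30,
        qc_fail_maf=20,
        qc_fail_het=10,
        seed=3,
    )
    g, truth = simulate_genotypes(cfg)
    return cfg, g, truth


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
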
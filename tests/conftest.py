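import numpy as np
import pytest

from lgdnovelty import paradigm as par
from lgdnovelty import synthgen as sg


@pytest.fixture(scope="session")
def paradigm_cfg() -> par.ParadigmConfig:
    return par.ParadigmConfig(seed=0)


@pytest.fixture(scope="session")
def block_events(paradigm_cfg) -> par.EventTable:
    """One timed variant-A block (440 trials)."""
    return par.build_session(paradigm_cfg, variant="A", n_blocks=1, rng_seed=0)


@pytest.fixture(scope="session")
def small_recording(paradigm_cfg, block_events):
    """Four channels: planted AEP-LD, HG-LD, AEP-GD effects plus one null channel."""
    cfg = sg.GeneratorConfig(
        n_channels=4,
        effects=(
            sg.EffectSpec.detectable("ch000", "AEP-LD"),
            sg.EffectSpec.detectable("ch001", "HG-LD"),
            sg.EffectSpec.detectable("ch002", "AEP-GD"),
        ),
        seed=0,
    )
    return cfg, sg.generate_recording(cfg, block_events, "awake", paradigm_cfg)


@pytest.fixture(scope="session")
def null_calibration():
    """Type-I calibration of the site-level cluster test on null epochs."""
    from lgdnovelty.validation import run_null_calibration

    return run_null_calibration(seed=7, n_sites=800, n_permutations=1000)


@pytest.fixture(scope="session")
def recovery_study():
    """Full-pipeline recovery of planted effects at the detectable preset."""
    from lgdnovelty.validation import run_recovery_study

    return run_recovery_study(seed=11, n_effect_channels_per_kind=3, n_null_channels=96,
                              n_permutations=1000)
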
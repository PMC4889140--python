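import numpy as np
import pytest

import cspdetect as cd

TEMPLATE_SEED = 99999


@pytest.fixture(scope="session")
def config():
    return cd.AnalysisConfig()


@pytest.fixture(scope="session")
def template():
    """MEP exemplar cut from its own seeded trial at the true onset/offset."""
    trial, truth = cd.generate_trial(
        cd.GenerationParams(seed=TEMPLATE_SEED), trial_id="template_source"
    )
    return cd.make_template(
        trial.samples,
        truth.mep_onset_idx,
        truth.mep_offset_idx,
        trial.sampling_rate,
        source_trial_id=trial.trial_id,
    )


@pytest.fixture(scope="session")
def clean_trial():
    return cd.generate_trial(cd.GenerationParams(seed=7), trial_id="clean7")


@pytest.fixture(scope="session")
def recovery_runs(config, template):
    """100 seeded clean trials analyzed with the default pipeline.

    Returns a list of (trial, truth, result) triples shared by the
    recovery tests so the pipeline runs once per session.
    """
    runs = []
    for seed in range(100):
        trial, truth = cd.generate_trial(
            cd.GenerationParams(seed=seed), trial_id=f"rec{seed}"
        )
        runs.append((trial, truth, cd.analyze_trial(trial, config, template)))
    return runs
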
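import pytest

from sescore.config import RunConfig
from sescore.model import SideEffectScreen
from sescore.simulate import default_study_config, simulate_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study():
    """A full synthetic study bundle with its truth manifest."""
    bundle, truth = simulate_study(default_study_config(), seed=STUDY_SEED)
    return bundle, truth


@pytest.fixture(scope="session")
def fitted(study):
    """The pipeline fitted on the session study bundle."""
    bundle, truth = study
    results = SideEffectScreen.from_bundle(bundle, RunConfig()).fit(seed=STUDY_SEED)
    return results, truth
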
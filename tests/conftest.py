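import numpy as np
import pytest

from afcontour import AFParams
from afcontour.stimuli import EnsembleSpec, build_ensemble


@pytest.fixture(scope="session")
def small_ensemble():
    """One small embedded ensemble shared across tests (seeded, deterministic)."""
    spec = EnsembleSpec(af=AFParams(0.25, 0.35), L=6, spacing=2.3, n_stimuli=8,
                        ensemble_id="fix0", profile="fast")
    rng = np.random.default_rng(1234)
    return spec, build_ensemble(spec, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
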
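import numpy as np
import pytest

from matecomm.rates import PopulationParams, SearchParams

# the three standard mate-search scenarios (b=1.0, d=0.1)
ASEXUAL = PopulationParams(b=1.0, d=0.1)
EFFECTIVE = PopulationParams(b=1.0, d=0.1, search=SearchParams(0.8, 0.8))
POOR = PopulationParams(b=1.0, d=0.1, search=SearchParams(0.62, 0.62))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(params=["asexual", "effective", "poor"])
def scenario(request):
    return {"asexual": ASEXUAL, "effective": EFFECTIVE, "poor": POOR}[request.param]
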
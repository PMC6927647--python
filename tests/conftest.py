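import numpy as np
import pytest

from elkipm import simulate
from elkipm.data import DesignSpec


@pytest.fixture(scope="session")
def small_scenario():
    """4 districts x 6 years, full coverage except a couple of gaps."""
    districts = [f"HD{i}" for i in (1, 2, 3, 4)]
    years = list(range(2004, 2010))
    coverage = {
        "HD1": years,
        "HD2": [2004, 2005, 2007, 2008, 2009],
        "HD3": years,
        "HD4": [2005, 2006, 2008, 2009],
    }
    design = DesignSpec.from_strings(["spring_precip", "swe"])
    return simulate.ScenarioConfig(
        districts=districts,
        years=years,
        design=design,
        beta=np.array([-0.2, 0.0]),
        coverage=coverage,
        classification_missing=[("HD2", 2007)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_scenario):
    return simulate.make_study(small_scenario)
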
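import numpy as np
import pytest
from hypothesis import settings

from apcmap import synthetic

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_registry():
    """One draw of the shipped default scenario (~300 areas, 1997-2017)."""
    cfg = synthetic.default_config(seed=1)
    incidence, person_years, geoms, truth = synthetic.generate_registry(cfg)
    return {"config": cfg, "incidence": incidence, "person_years": person_years,
            "geoms": geoms, "truth": truth}


@pytest.fixture(scope="session")
def small_registry():
    """A reduced 6x6-area registry for fast pipeline-level tests."""
    cfg = synthetic.default_config(seed=7)
    cfg.nx, cfg.ny = 6, 6
    cfg.scenarios = [sc for sc in cfg.scenarios if sc.sex == "male"]
    incidence, person_years, geoms, truth = synthetic.generate_registry(cfg)
    return {"config": cfg, "incidence": incidence, "person_years": person_years,
            "geoms": geoms, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
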
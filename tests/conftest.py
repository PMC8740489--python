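import warnings

import pytest

from trbkit.pipeline import run_pipeline
from trbkit.reference import ProtocolSpec
from trbkit.repertoire_io import Assigner
from trbkit.simulate import (
    PopulationConfig,
    novel_spec,
    simulate_population,
    toy_germline,
    toy_protocol,
)

warnings.filterwarnings("ignore", message="empty TRBD2 coarse group")


@pytest.fixture(scope="session")
def toy_sets():
    return toy_germline()


@pytest.fixture(scope="session")
def full_protocol():
    return ProtocolSpec("full")


@pytest.fixture(scope="session")
def assigner_full(toy_sets):
    v, d, j = toy_sets
    return Assigner(v, d, j, protocol=toy_protocol("full"))


@pytest.fixture(scope="session")
def clean_population():
    """Error-free, trim-free population: assignment must be exact."""
    cfg = PopulationConfig(
        n_individuals=3,
        depth=400,
        seed=101,
        error_rate=0.0,
        trim_means={"v3": 0.0, "d5": 0.0, "d3": 0.0, "j5": 0.0},
        n_insert_mean=0.0,
    )
    return cfg, simulate_population(cfg)


@pytest.fixture(scope="session")
def small_pipeline_result():
    """One modest population pushed through the full pipeline, shared
    across tests that only read its outputs."""
    cfg = PopulationConfig(
        n_individuals=8,
        depth=1200,
        seed=42,
        novel_alleles=[novel_spec("TRBV10-3", "01", 47, 0.4)],
        j_usage={"TRBJ1-6": 6.0},
    )
    return cfg, run_pipeline(cfg)
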
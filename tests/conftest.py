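import numpy as np
import pandas as pd
import pytest

from gibbspop import fixtures as F
from gibbspop.pipeline import PipelineConfig, run_pipeline
from gibbspop.schema import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def model():
    return F.generate_ground_truth_model(1)


@pytest.fixture(scope="session")
def hierarchy():
    return F.default_zone_hierarchy(32000)


@pytest.fixture(scope="session")
def census_small(model, hierarchy):
    """3k-household microdata sample drawn exactly from the ground-truth tree."""
    return F.simulate_census_sample(model, 3000, hierarchy.iris_ids(), 7, hierarchy)


@pytest.fixture(scope="session")
def run10k(tmp_path_factory):
    """Full pipeline artifacts at the 10k-household study scale (seed 1)."""
    out = tmp_path_factory.mktemp("run10k")
    run_pipeline(PipelineConfig(seed=1, n_households=10000), out)
    return out


@pytest.fixture(scope="session")
def run50k(tmp_path_factory):
    """Full pipeline artifacts at the 50k-household recovery scale (seed 1)."""
    out = tmp_path_factory.mktemp("run50k")
    run_pipeline(PipelineConfig(seed=1, n_households=50000), out)
    return out


def read_tsv(path, **kw):
    kw.setdefault("dtype", {"zone_id": str})
    return pd.read_csv(path, sep="\t", **kw)


@pytest.fixture(scope="session")
def synthetic10k(run10k):
    from gibbspop.generation import Population

    return Population(
        read_tsv(run10k / "synthetic_households.tsv"),
        read_tsv(run10k / "synthetic_individuals.tsv"),
    )
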
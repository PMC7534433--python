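import numpy as np
import pandas as pd
import pytest

from grnoverlap import RegulatoryNetwork, SimulationConfig, simulate_all


def make_network(edges) -> RegulatoryNetwork:
    """Build a network from (regulator, target, weight) triples."""
    return RegulatoryNetwork(
        pd.DataFrame(edges, columns=["regulator", "target", "weight"])
    )


def make_annotation(rows) -> pd.DataFrame:
    """Annotation from (gene_id, is_tf, family, genome, triad_id) tuples."""
    df = pd.DataFrame(
        rows, columns=["gene_id", "is_tf", "family", "genome", "triad_id"]
    )
    return df.set_index("gene_id")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down stated world: quick to simulate, same structure."""
    return SimulationConfig(
        n_background_tfs=40,
        n_genes=3000,
        targets_per_tf=(20, 40),
        triads_per_category={"Stable": 4, "Mid80": 6, "Dynamic": 4},
        n_deg={"12DAA": 120, "22DAA": 60},
        causal_overlap=0.3,
        n_planted_candidates=2,
        candidate_overlap=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("bundle")
    manifest = simulate_all(small_config, out)
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
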
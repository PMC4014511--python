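import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from semde.ontology import GoDag
from semde.qc import ExpressionMatrix
from semde.synthetic import SimulationConfig, generate_expression


@pytest.fixture
def chain_dag() -> GoDag:
    """B is the root; A --is_a--> B."""
    dag = GoDag()
    dag.add_term("B", "root")
    dag.add_term("A", "child")
    dag.add_edge("A", "B", "is_a")
    return dag


@pytest.fixture
def diamond_dag() -> GoDag:
    """A --is_a--> {B, C} --is_a--> D (root)."""
    dag = GoDag()
    for t in "ABCD":
        dag.add_term(t)
    dag.add_edge("A", "B", "is_a")
    dag.add_edge("A", "C", "is_a")
    dag.add_edge("B", "D", "is_a")
    dag.add_edge("C", "D", "is_a")
    return dag


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_animals_per_muscle=10, n_probes=120, n_genes=100,
        prop_de=0.3, noise_sd=0.2, flag_prob=0.02, seed=11,
    )


@pytest.fixture
def small_dataset(small_config):
    return generate_expression(small_config)


def toy_matrix(values: np.ndarray, scale: str = "raw",
               flags: np.ndarray | None = None,
               probes=None, samples=None) -> ExpressionMatrix:
    n, p = values.shape
    probes = probes or [f"P{i}" for i in range(n)]
    samples = samples or [f"S{j}" for j in range(p)]
    vdf = pd.DataFrame(values, index=probes, columns=samples)
    fdf = None
    if flags is not None:
        fdf = pd.DataFrame(flags.astype(bool), index=probes, columns=samples)
    return ExpressionMatrix(vdf, fdf, scale=scale)


def toy_meta(samples, muscles) -> pd.DataFrame:
    return pd.DataFrame({"sample_id": samples, "muscle": muscles})
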
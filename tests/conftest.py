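import numpy as np
import pandas as pd
import pytest

import squamet as sq


@pytest.fixture(scope="session")
def small_dataset():
    """30-species synthetic dataset shared across read-only tests."""
    return sq.generate_dataset(sq.SimulationConfig(n_species=30, seed=42))


@pytest.fixture(scope="session")
def study_like():
    """196-species dataset with the published group composition, plus the
    derived model frame used by the ANOVA and path stages."""
    ds = sq.study_dataset(seed=7)
    fit = sq.fit_mte(ds.table)
    corr = sq.correct(ds.table, fit)
    frame = pd.DataFrame(
        {
            "R": [1 if r.reproductive_mode == "viviparous" else 0 for r in ds.table],
            "G": [1 if r.clade == "snake" else 0 for r in ds.table],
            "ln_mass": corr.ln_mass,
            "inv_kT": corr.inv_kT,
            "ln_smr": corr.ln_smr,
            "t_smr": corr.t_smr,
            "m_smr": corr.m_smr,
        }
    )
    return ds, fit, corr, frame


@pytest.fixture(scope="session")
def vcv30(small_dataset):
    return sq.vcv_from_tree(small_dataset.phylogeny)


def random_dag(rng: np.random.Generator, n_vertices: int, n_edges: int) -> sq.CausalDAG:
    """Random DAG: orient each sampled pair from lower to higher index."""
    verts = [f"v{i}" for i in range(n_vertices)]
    pairs = [(i, j) for i in range(n_vertices) for j in range(i + 1, n_vertices)]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    edges = [(verts[pairs[k][0]], verts[pairs[k][1]]) for k in sorted(idx)]
    return sq.CausalDAG(vertices=verts, edges=edges)
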
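import pandas as pd
import pytest

from pxrdock import (
    DockingScoreMatrix,
    GeneratorConfig,
    PXR_STRUCTURES,
    fixtures,
    generate_dataset,
)


@pytest.fixture(scope="session")
def table1():
    refs, cutoffs = fixtures.load_table1_fixture()
    return refs, cutoffs


@pytest.fixture(scope="session")
def table2():
    compounds, assays, docking = fixtures.load_table2_fixture()
    return compounds, assays, docking


@pytest.fixture(scope="session")
def small_dataset():
    """20 synthetic compounds x 5 structures x 20 poses, seeded."""
    config = GeneratorConfig(n_agonists=10, n_nonagonists=10, rng_seed=42)
    return generate_dataset(config)


@pytest.fixture
def tiny_matrix():
    """2 compounds x 5 structures x 3 poses with hand-set scores."""
    rows = []
    for ci, cid in enumerate(["c1", "c2"]):
        for si, pdb in enumerate(PXR_STRUCTURES):
            for p in range(1, 4):
                rows.append(
                    {
                        "compound_id": cid,
                        "receptor_pdb": pdb,
                        "pose_index": p,
                        "score": 30.0 + 10 * ci + 2 * si + p,
                    }
                )
    return DockingScoreMatrix(pd.DataFrame(rows))
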
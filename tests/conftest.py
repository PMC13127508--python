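import numpy as np
import pandas as pd
import pytest

import pancstate as ps


@pytest.fixture(scope="session")
def exocrine_data():
    """Default exocrine simulation shared across read-only tests."""
    cfg = ps.ExocrineSimConfig(seed=1)
    m, truth, regulon, panels = ps.generate_exocrine_dataset(cfg)
    return {"cfg": cfg, "m": m, "truth": truth, "regulon": regulon, "panels": panels}


@pytest.fixture(scope="session")
def tumor_data():
    from pancstate.simulate import default_tumor_signatures

    sigs = default_tumor_signatures()
    m, truth = ps.generate_tumor_dataset(n_cells=2000, seed=1, signature_sets=sigs)
    return {"m": m, "truth": truth, "signatures": sigs}


@pytest.fixture()
def tiny_matrix():
    """Hand-built 4-cell x 5-gene matrix with clean metadata."""
    counts = np.array(
        [
            [4, 0, 1, 0, 2],
            [0, 3, 0, 1, 0],
            [2, 2, 2, 2, 2],
            [1, 0, 0, 0, 5],
        ]
    )
    meta = pd.DataFrame(
        {
            "donor": ["d1", "d1", "d2", "d2"],
            "context": ["adult"] * 4,
            "sample": ["s1", "s1", "s2", "s2"],
            "pct_mito": [1.0, 2.0, 3.0, 4.0],
            "pct_ribo": [10.0, 11.0, 12.0, 13.0],
            "contamination": [0.1, 0.1, 0.2, 0.2],
        }
    )
    m = ps.make_annotated(counts, [f"c{i}" for i in range(4)], [f"g{i}" for i in range(5)], meta)
    return ps.log_normalize(m)
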
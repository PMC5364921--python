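import numpy as np
import pandas as pd
import pytest

from mockrep import MockModel, OTUTable, simulate_table


@pytest.fixture
def small_table() -> OTUTable:
    """3 samples x 4 OTUs with a 2x(2,1) primer/run design and known counts."""
    counts = pd.DataFrame(
        [[5, 0, 1, 3], [1, 3, 0, 3], [4, 1, 1, 0]],
        index=["P1R1", "P2R1", "P1R2"],
        columns=["otuA", "otuB", "otuC", "otuD"],
    )
    sample_meta = pd.DataFrame(
        {"primer_index": [1, 2, 1], "run": [1, 1, 2]},
        index=["P1R1", "P2R1", "P1R2"],
    )
    otu_meta = pd.DataFrame(
        {
            "is_target": [True, True, False, False],
            "label": ["Genus speciesA", "Genus speciesB", "epibiontC", "unknownD"],
        },
        index=["otuA", "otuB", "otuC", "otuD"],
    )
    return OTUTable(counts, sample_meta, otu_meta)


@pytest.fixture
def design_table() -> OTUTable:
    """Full 7-primer x 2-run design with deterministic non-trivial counts."""
    rng = np.random.default_rng(42)
    samples = [f"P{p}R{r}" for r in (1, 2) for p in range(1, 8)]
    counts = rng.integers(0, 50, size=(14, 10))
    counts[:, 0] += 1  # keep every sample non-empty
    counts = pd.DataFrame(
        counts, index=samples, columns=[f"otu{i}" for i in range(10)]
    )
    meta = pd.DataFrame(
        {
            "primer_index": [int(s[1]) for s in samples],
            "run": [int(s[3]) for s in samples],
        },
        index=samples,
    )
    return OTUTable(counts, meta)


@pytest.fixture(scope="session")
def default_sim():
    """One simulated dataset under the default study conditions."""
    return simulate_table(MockModel(seed=20260924))
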
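import numpy as np
import pandas as pd
import pytest

from txpanel import PipelineConfig
from txpanel.simulate import SimulationConfig, generate_panel


@pytest.fixture
def tiny_panel():
    """Hand-built two-gene panel: 3 probes, 2 cell lines, 1 agent, 1 time.

    GENE1 has probes P1/P2, GENE2 has P3.  Values are chosen so gene-level
    means and fold changes are easy to verify by hand.
    """
    sheet = pd.DataFrame({
        "sample_id": ["v1", "t1", "v2", "t2"],
        "cell_line": ["A", "A", "B", "B"],
        "tissue": "",
        "agent": "drugX",
        "arm": ["vehicle", "high", "vehicle", "high"],
        "time_hr": 24,
    })
    matrix = pd.DataFrame(
        [[4.0, 6.0, 5.0, 5.5],
         [6.0, 8.0, np.nan, 6.5],
         [1.0, 1.0, 2.0, 0.5]],
        index=pd.Index(["P1", "P2", "P3"], name="probe_id"),
        columns=["v1", "t1", "v2", "t2"],
    )
    probe_map = pd.Series(["GENE1", "GENE1", "GENE2"],
                          index=pd.Index(["P1", "P2", "P3"], name="probe_id"))
    return matrix, sheet, probe_map


@pytest.fixture(scope="session")
def small_sim():
    """One seeded scaled-down panel shared across tests: 60 cell lines,
    2 agents, planted concerted and associated genes at high/24h."""
    cfg = SimulationConfig(
        seed=11,
        agents=("dasatinib", "vorinostat"),
        n_null_genes=40, n_concerted_genes=6, n_assoc_genes=8,
        n_gene_sets=4, n_enriched_sets=2, set_size=6,
    )
    expression, sheet, probe_map, response, truth = generate_panel(cfg)
    return {"config": cfg, "expression": expression, "sheet": sheet,
            "probe_map": probe_map, "response": response, "truth": truth}


@pytest.fixture
def pipeline_config():
    return PipelineConfig(n_perm=200, rng_seed=5)
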
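import numpy as np
import pandas as pd
import pytest

from methkit import (
    SimulationConfig,
    compute_beta,
    simulate_intensities,
    simulate_manifest,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_probes=6000, n_genes=600, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One mid-sized simulated study shared across tests."""
    manifest, intensities, truth, sheet, expression, cgi = simulate_study(small_config)
    return {
        "config": small_config,
        "manifest": manifest,
        "intensities": intensities,
        "truth": truth,
        "sheet": sheet,
        "expression": expression,
        "cgi": cgi,
    }


@pytest.fixture(scope="session")
def small_beta(small_study):
    return compute_beta(small_study["intensities"], small_study["sheet"])


@pytest.fixture()
def toy_manifest():
    """Ten probes covering each QC artifact class exactly once."""
    idx = pd.Index([f"cg{i:02d}" for i in range(10)], name="probe_id")
    man = pd.DataFrame(
        {
            "chromosome": ["chr1"] * 10,
            "position": np.arange(10) * 1000 + 500,
            "gene": [f"G{i}" for i in range(10)],
            "gene_context": ["Body"] * 10,
            "cgi_context": ["OpenSea"] * 10,
            "snp_flag": [False, True] + [False] * 8,
            "missing_flag": [True] + [False] * 9,
            "detfail_flag": [False] * 3 + [True] + [False] * 6,
        },
        index=idx,
    )
    man.loc["cg02", "chromosome"] = "chrX"
    return man
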
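import numpy as np
import pandas as pd
import pytest

import methpath as mp
from methpath.methylation import summarize_features_methylation, summaries_to_frame

#: One seed for the shared end-to-end simulation used across the suite.
SIM_SEED = 11


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic experiment shared by the slower end-to-end tests."""
    return mp.run_default_simulation(SIM_SEED)


@pytest.fixture(scope="session")
def pathway_labels(default_sim):
    """Per-TE pathway classification derived from the shared simulation."""
    tes = default_sim["tes"]
    summ = {
        g: summaries_to_frame(
            summarize_features_methylation(tes, default_sim["methylomes"][g])
        )
        for g in ("wt", "cmt2", "drm2")
    }
    df = pd.DataFrame({"length": summ["wt"]["length"]})
    for g in summ:
        df[f"mCHH_{g}"] = summ[g]["mCHH"]
        df[f"meth_{g}"] = summ[g]["meth_reads_CHH"]
        df[f"unmeth_{g}"] = summ[g]["unmeth_reads_CHH"]
    return mp.classify_pathway_table(df)


@pytest.fixture()
def tiny_genome():
    """A 60 bp two-chromosome genome for context arithmetic tests."""
    return mp.GenomeSequence(
        {"chr1": "TACGAACCGTGCATAGCAATNCCGT", "chr2": "ACGTACGTACGTACGTACGT"}
    )
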
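import numpy as np
import pandas as pd
import pytest

from evanomaly.io import AbundanceTable, ProteinId


def make_table(values, donors=("d1", "d2", "d3"),
               conditions=("ctrl", "doped"), accessions=None):
    """Build an AbundanceTable from a dict accession -> {(donor, cond): v}
    or from a (n_proteins, n_donors * n_conditions) array (donor-major)."""
    if isinstance(values, dict):
        accessions = list(values)
        grid = values
    else:
        arr = np.asarray(values, dtype=float)
        if accessions is None:
            accessions = [f"P{i:05d}" for i in range(arr.shape[0])]
        keys = [(d, c) for d in donors for c in conditions]
        grid = {a: dict(zip(keys, row)) for a, row in zip(accessions, arr)}
    cols = pd.MultiIndex.from_product([list(donors), list(conditions)],
                                      names=["donor", "condition"])
    data = pd.DataFrame(
        {key: [grid[a].get(key, np.nan) for a in accessions] for key in cols},
        index=accessions)
    data.columns = cols
    proteins = [ProteinId(a) for a in accessions]
    return AbundanceTable(proteins, list(donors), list(conditions), data)


@pytest.fixture
def tiny_table():
    """3 proteins x 3 donors x 2 conditions with hand-set peak areas."""
    return make_table({
        "P04264": {("d1", "ctrl"): 8.0, ("d2", "ctrl"): 4.0, ("d3", "ctrl"): 2.0,
                   ("d1", "doped"): 16.0, ("d2", "doped"): 8.0, ("d3", "doped"): 4.0},
        "P13645": {("d1", "ctrl"): 1.0, ("d2", "ctrl"): 1.0, ("d3", "ctrl"): 1.0,
                   ("d1", "doped"): 2.0, ("d2", "doped"): 2.0, ("d3", "doped"): 2.0},
        "Q9P2E9": {("d1", "ctrl"): 32.0, ("d2", "ctrl"): 64.0, ("d3", "ctrl"): 128.0,
                   ("d1", "doped"): 32.0, ("d2", "doped"): 64.0, ("d3", "doped"): 128.0},
    })
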
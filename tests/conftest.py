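import numpy as np
import pandas as pd
import pytest

from kerastate import synthetic as syn
from kerastate.decomposition import build_fraction_table


def cohort_fraction_table(cohort) -> pd.DataFrame:
    """Fraction table from generator truth: true states + raw marker UMIs."""
    cells = cohort.cells.copy()
    col = np.asarray(cohort.counts[:, syn.MARKER_GENE_INDEX].todense()).ravel()
    cells["positive"] = col > 0
    cells["state"] = cells["true_state"]
    ker = cells["true_state"].isin(cohort.config.keratinocyte_state_names)
    return build_fraction_table(cells.loc[ker])


def random_fraction_table(rng, n_donors=3, n_states=4, max_cells=200) -> pd.DataFrame:
    rows = []
    for d in range(n_donors):
        for cond in ("normal", "LE"):
            for s in range(n_states):
                n = int(rng.integers(0, max_cells))
                rows.append(
                    {
                        "donor": f"D{d}",
                        "condition": cond,
                        "state": f"K{s}",
                        "n_cells": n,
                        "n_positive": int(rng.integers(0, n + 1)) if n else 0,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small 2-donor cohort reused by read/write and pipeline tests."""
    cfg = syn.CohortConfig(
        n_donors=2,
        cells_per_sample=60,
        n_genes=50,
        state_names=("K0", "K3"),
        composition_alpha={"normal": (6.0, 4.0), "LE": (4.0, 6.0)},
        marker_mu={"normal": (1.0, 0.5), "LE": (0.8, 0.3)},
        n_mito_genes=5,
        n_ribo_genes=6,
        seed=7,
    ).validate()
    return syn.generate_cohort(cfg)
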
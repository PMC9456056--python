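import numpy as np
import pandas as pd
import pytest

from citepipe import adt, synthetic


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared across tests (8 subjects x 300 cells)."""
    design = synthetic.default_design(cells_per_subject=300)
    adt_mat, gene_mat, tag_mat, meta, truth = synthetic.simulate_study(design, seed=11)
    return {
        "design": design,
        "adt": adt_mat,
        "genes": gene_mat,
        "tags": tag_mat,
        "meta": meta,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_norm_and_thresholds(small_study):
    norm = adt.clr_log2(small_study["adt"])
    table = adt.build_threshold_table(norm)
    return norm, table, adt.thresholds_as_dict(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
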
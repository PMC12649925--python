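import numpy as np
import pandas as pd
import pytest

from drynet import synthetic
from drynet.datatypes import MetaboliteMatrix


@pytest.fixture(scope="session")
def planted_hierarchy():
    """Small planted 2-layer hierarchy (study-condition sizes, one seed)."""
    return synthetic.simulate_hierarchy_expression(
        n_pathway_genes=40, n_layer1_tfs=10, n_layer2_tfs=8, n_decoys=32,
        timepoints=6, replicates=3, noise_sd=1.0, seed=1,
    )


@pytest.fixture(scope="session")
def planted_metabolome():
    """1000-metabolite simulated metabolome, 10% differential at log2fc=2."""
    return synthetic.simulate_metabolome(
        n_metabolites=1000, n_groups=2, replicates=3, n_qc=3,
        frac_differential=0.1, log2fc=2.0, missing_rate=0.05, qc_cv=0.2, seed=7,
    )


def make_metabolite_matrix(values, qc_cols=(), class_labels=None, groups=None, timepoints=None):
    """Hand-build a MetaboliteMatrix from a 2-D array for small fixtures."""
    values = np.asarray(values, dtype=float)
    n_met, n_samp = values.shape
    met_ids = [f"m{i}" for i in range(n_met)]
    samp_ids = [f"s{j}" for j in range(n_samp)]
    meta = pd.DataFrame(
        {
            "timepoint": timepoints if timepoints is not None else list(range(n_samp)),
            "replicate": [0] * n_samp,
            "group": groups if groups is not None else ["g"] * n_samp,
            "is_qc": [j in set(qc_cols) for j in range(n_samp)],
        },
        index=samp_ids,
    )
    return MetaboliteMatrix(
        intensities=pd.DataFrame(values, index=met_ids, columns=samp_ids),
        metadata=meta,
        class_labels=class_labels or {},
    )
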
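import numpy as np
import pandas as pd
import pytest

from plaqueomics import (
    CohortConfig,
    IntensityMatrix,
    filter_contaminants,
    filter_min_detection,
    generate_cohort,
    median_normalize,
)


def make_matrix(values, protein_ids=None, ages=(3,), model="5xFAD"):
    """Wrap a 2D array into an IntensityMatrix with a paired design.

    Columns come in (plaque, control) pairs; the number of columns must
    be 2 * n_pairs * len(ages).
    """
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    assert n_samp % (2 * len(ages)) == 0
    n_pairs = n_samp // (2 * len(ages))
    protein_ids = protein_ids or [f"P{i:03d}" for i in range(n_prot)]
    cols, meta = [], []
    for age in ages:
        for p in range(n_pairs):
            pair = f"{model}_{age}m_pr{p:02d}"
            for region, suffix in (("plaque", "plq"), ("nonplaque", "ctl")):
                sid = f"{pair}_{suffix}"
                cols.append(sid)
                meta.append(dict(sample_id=sid, model=model, age_months=age,
                                 region=region, pair_id=pair, replicate=p))
    return IntensityMatrix(
        pd.DataFrame(values, index=protein_ids, columns=cols),
        pd.DataFrame(meta).set_index("sample_id"),
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_proteins=600, n_pairs_per_age=15, seed=11)
    matrix, truth = generate_cohort(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def qc_cohort(small_cohort):
    cfg, matrix, truth = small_cohort
    m = median_normalize(filter_min_detection(filter_contaminants(matrix)))
    return cfg, m, truth
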
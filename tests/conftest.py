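import warnings

import numpy as np
import pandas as pd
import pytest

import protlmm as pl
from protlmm.dataio import FeatureTable


@pytest.fixture(scope="session")
def factorial():
    """Small factorial-study emulation: 8 conditions x 2 subjects x 3 runs."""
    table, truth = pl.generate_factorial(n_proteins=20, seed=11)
    return table, truth, pl.infer_design(table)


@pytest.fixture(scope="session")
def timecourse():
    """Time-course emulation: 14 disease + 29 control subjects, L = 1."""
    table, truth = pl.generate_timecourse(n_proteins=8, seed=13)
    return table, truth, pl.infer_design(table)


@pytest.fixture()
def toy_frame():
    """1 protein, 2 features, 3 runs in 3 conditions (complete)."""
    rows = []
    for c, s, r in [("c1", "s1", "r1"), ("c2", "s2", "r2"), ("c3", "s3", "r3")]:
        for f, v in [("f1", 1024.0), ("f2", 512.0)]:
            rows.append({"ProteinName": "P1", "FeatureName": f, "Condition": c,
                         "BioReplicate": s, "Run": r, "Intensity": v})
    return pd.DataFrame(rows)


def two_condition_table(n_per_group=4, diff=0.5, sigma=0.3, seed=0,
                        n_features=1, L=1):
    """Minimal nested two-condition table built by hand."""
    rng = np.random.default_rng(seed)
    rows = []
    for j, c in enumerate(["A", "B"]):
        for k in range(n_per_group):
            subj = f"{c}_s{k}"
            for l in range(L):
                for i in range(n_features):
                    rows.append({
                        "ProteinName": "P", "FeatureName": f"f{i}",
                        "Condition": c, "BioReplicate": subj,
                        "Run": f"{subj}_t{l}", "Intensity": 1.0,
                        "LogIntensity": rng.normal(10 + i + j * diff, sigma),
                    })
    return FeatureTable(pd.DataFrame(rows), log_base=2)


def fit_quiet(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.fit_protein(*args, **kwargs)
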
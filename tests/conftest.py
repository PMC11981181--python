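import dataclasses

import pytest

from drawscreen import features, svm, synthetic


@pytest.fixture(scope="session", autouse=True)
def _compile_svm_kernels():
    svm.warmup()


def label_sheets(cohort, tables):
    """Insert the cohort's group labels into extracted feature tables."""
    groups = dict(zip(cohort["participant_id"], cohort["group"]))
    out = {}
    for shape, df in tables.items():
        df = df.copy()
        df.insert(1, "group", df["participant_id"].map(groups))
        out[shape] = df
    return out


@pytest.fixture(scope="session")
def default_cohort():
    """Full default synthetic cohort (20 high / 113 low, four shapes)."""
    cohort, recs = synthetic.generate_cohort(synthetic.CohortSpec(seed=1))
    return cohort, label_sheets(cohort, features.extract_feature_table(recs))


@pytest.fixture(scope="session")
def null_features():
    """One-shape feature sheet from a matched no-effect cohort (20/113)."""
    spec = dataclasses.replace(
        synthetic.null_spec(seed=7), shapes=("equilateral_triangle",)
    )
    cohort, recs = synthetic.generate_cohort(spec)
    sheets = label_sheets(cohort, features.extract_feature_table(recs))
    return sheets["equilateral_triangle"]
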
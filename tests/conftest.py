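import numpy as np
import pandas as pd
import pytest

from neurofuse import features, harmonize, model, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """Two-site cohort with default planted effects at miniature scale."""
    truth = synthetic.default_effects(12)
    return synthetic.generate_cohort(
        [(8, 8), (8, 8)], truth=truth, seed=11, n_regions=12, T=40
    )


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return features.cohort_feature_table(small_cohort)


def harmonized_table(cohort, table):
    """Controls-fit, applied-to-everyone harmonization of both modalities."""
    parts = cohort.participants
    ctrl = [i for i in table.subjects if parts.loc[i, "diagnosis"] == synthetic.TD]
    out = []
    for modality in (features.STRUCTURAL, features.FUNCTIONAL):
        sub = table.select(modality)
        m = harmonize.fit_harmonizer(
            sub.restrict(ctrl), parts["site"], parts["age"],
            diagnosis=parts["diagnosis"].reindex(ctrl),
        )
        out.append(harmonize.apply_harmonizer(m, sub, parts["site"], parts["age"]))
    return out[0].concat(out[1])


def planted_feature_names(truth: synthetic.EffectSpec, regions: list[str]) -> list[str]:
    """Schema names of every planted informative feature, both modalities."""
    pair_names = [
        f"fc__{regions[min(i, j)]}__{regions[max(i, j)]}"
        for i, j, _ in truth.informative_pairs
    ]
    return list(truth.informative_structural) + pair_names


def scaled_blocks(table):
    blocks, names = {}, {}
    for m in (features.STRUCTURAL, features.FUNCTIONAL):
        X = table.select(m).df.to_numpy(dtype=float)
        blocks[m] = model.scale_features(X)[0]
        names[m] = table.columns_of(m)
    return blocks, names
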
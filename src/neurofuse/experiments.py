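"""Reusable study-level experiments over the synthetic cohort generator.

These functions bundle the full protocol — simulate, build features,
harmonize on controls, cross-validate the three modality modes, attribute —
at the package's desk scale (10 sites x 60 subjects, 50 regions, T = 150),
so the analysis drivers, the test suite and the acceptance script all run
the identical computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import explain as explain_mod
from . import features as features_mod
from . import harmonize as harmonize_mod
from . import model as model_mod
from . import synthetic

DESK_SITE_PLAN = [(30, 30)] * 10
DESK_REGIONS = 50
DESK_T = 150


def harmonize_both_modalities(cohort: synthetic.Cohort,
                              table: features_mod.FeatureTable) -> features_mod.FeatureTable:
    """Fit the harmonizer on controls per modality and apply to everyone."""
    parts = cohort.participants
    ctrl = [i for i in table.subjects if parts.loc[i, "diagnosis"] == synthetic.TD]
    out = []
    for modality in (features_mod.STRUCTURAL, features_mod.FUNCTIONAL):
        sub = table.select(modality)
        m = harmonize_mod.fit_harmonizer(
            sub.restrict(ctrl), parts["site"], parts["age"],
            diagnosis=parts["diagnosis"].reindex(ctrl),
        )
        out.append(harmonize_mod.apply_harmonizer(m, sub, parts["site"], parts["age"]))
    return out[0].concat(out[1])


def build_harmonized_cohort(truth: synthetic.EffectSpec, seed: int,
                            site_plan=None, n_regions: int = DESK_REGIONS,
                            T: int = DESK_T):
    """Simulate, featurize and harmonize one cohort; returns (cohort, table)."""
    cohort = synthetic.generate_cohort(
        site_plan or DESK_SITE_PLAN, truth=truth, seed=seed,
        n_regions=n_regions, T=T,
    )
    table = features_mod.cohort_feature_table(cohort)
    return cohort, harmonize_both_modalities(cohort, table)


def modality_comparison(truth: synthetic.EffectSpec, seed: int,
                        outer_k: int = 3, epochs: int = 150,
                        search_space=((64, 32),),
                        site_plan=None) -> dict[str, model_mod.CVResults]:
    """Cross-validated AUC of the structural, functional and joint models
    on one synthetic cohort.

    Desk-scale defaults: the full 150-epoch training schedule (shorter
    schedules leave the weak connectivity signal badly underfit) over 3
    outer folds with a fixed head, trading fold count for train-split size
    at n = 600.
    """
    cohort, table = build_harmonized_cohort(truth, seed, site_plan)
    parts = cohort.participants
    cfg = model_mod.TrainConfig(epochs=epochs)
    return {
        mode: model_mod.nested_cv(table, parts["diagnosis"], modality_mode=mode,
                                  outer_k=outer_k, search_space=search_space,
                                  config=cfg, seed=seed)
        for mode in ("structural", "functional", "joint")
    }


def planted_feature_names(truth: synthetic.EffectSpec, regions: list[str]) -> list[str]:
    pair_names = [
        f"fc__{regions[min(i, j)]}__{regions[max(i, j)]}"
        for i, j, _ in truth.informative_pairs
    ]
    return list(truth.informative_structural) + pair_names


def attribution_recovery(truth: synthetic.EffectSpec, seed: int,
                         repetitions: int = 20, epochs: int = 60,
                         percentile: float = 99.0,
                         site_plan=None) -> dict:
    """Fraction of planted informative features selected above the
    importance percentile, plus the full normalized importance vector."""
    cohort, table = build_harmonized_cohort(truth, seed, site_plan)
    parts = cohort.participants
    y = model_mod.binarize_labels(parts["diagnosis"].reindex(table.subjects))
    blocks, names = {}, {}
    for m in (features_mod.STRUCTURAL, features_mod.FUNCTIONAL):
        X = table.select(m).df.to_numpy(dtype=float)
        blocks[m] = model_mod.scale_features(X)[0]
        names[m] = table.columns_of(m)
    s_norm = explain_mod.repeated_split_importance(
        blocks, y, names, repetitions=repetitions, epochs=epochs, seed=seed,
    )
    selected = set(explain_mod.select_top(s_norm, percentile))
    regions = cohort.subjects[0].timeseries.regions
    planted = planted_feature_names(cohort.truth, regions)
    recovered = selected & set(planted)
    return {
        "recovery": len(recovered) / len(planted),
        "n_selected": len(selected),
        "planted": planted,
        "recovered": sorted(recovered),
        "s_norm": s_norm,
        "table": table,
        "participants": parts,
    }


def batch_effect_recovery(seed: int, gamma: float = 2.0, n_sites: int = 6,
                          n_per_group: int = 50, planted_d: float = 0.8) -> dict:
    """Harmonization check: recover a planted site offset, suppress site
    identity, preserve the planted diagnosis effect."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import cross_val_score

    target = "lh_superiortemporal_ThickAvg"
    sites = [f"site{k + 1:02d}" for k in range(n_sites)]
    truth = synthetic.EffectSpec(
        informative_structural={target: planted_d},
        site_location={sites[0]: gamma, **{s: 0.0 for s in sites[1:]}},
    )
    # twin cohort: identical subject-level draws, site effects switched off —
    # the batch-free reference the harmonized effect size is judged against
    twin_truth = synthetic.EffectSpec(
        informative_structural={target: planted_d},
        site_location={s: 0.0 for s in sites},
    )
    plan = [(s, n_per_group, n_per_group) for s in sites]
    cohort = synthetic.generate_cohort(plan, truth=truth, seed=seed,
                                       n_regions=8, T=10)
    twin = synthetic.generate_cohort(plan, truth=twin_truth, seed=seed,
                                     n_regions=8, T=10)
    table = features_mod.structural_table(cohort)
    parts = cohort.participants
    ctrl = [i for i in table.subjects if parts.loc[i, "diagnosis"] == synthetic.TD]
    m = harmonize_mod.fit_harmonizer(
        table.restrict(ctrl), parts["site"], parts["age"],
        diagnosis=parts["diagnosis"].reindex(ctrl),
    )
    # gamma is estimated relative to the grand mean; the planted offset is the
    # contrast of the shifted site against the average of the unshifted ones
    g_feat = m.gamma_star * np.sqrt(m.var_pooled)
    i0 = m.sites.index(sites[0])
    others = [k for k in range(n_sites) if k != i0]
    gamma_hat = float((g_feat[i0] - g_feat[others].mean(axis=0)).mean())

    h = harmonize_mod.apply_harmonizer(m, table, parts["site"], parts["age"])
    site_codes = parts["site"].astype("category").cat.codes
    clf = LogisticRegression(max_iter=2000)
    acc_before = float(cross_val_score(clf, table.df.to_numpy(), site_codes, cv=3).mean())
    acc_after = float(cross_val_score(clf, h.df.to_numpy(), site_codes, cv=3).mean())

    dx = parts["diagnosis"]
    d_raw = explain_mod.cohens_d(table.df.loc[dx == "ASD", target],
                                 table.df.loc[dx == "TD", target]).d
    d_harm = explain_mod.cohens_d(h.df.loc[dx == "ASD", target],
                                  h.df.loc[dx == "TD", target]).d
    tw = twin.structural_table()
    d_twin = explain_mod.cohens_d(tw.loc[dx == "ASD", target],
                                  tw.loc[dx == "TD", target]).d
    return {
        "gamma_planted": gamma,
        "gamma_recovered": gamma_hat,
        "site_acc_before": acc_before,
        "site_acc_after": acc_after,
        "site_chance": 1.0 / n_sites,
        "d_planted": planted_d,
        "d_raw": float(d_raw),
        "d_harmonized": float(d_harm),
        "d_batch_free": float(d_twin),
    }


def fisher_feature_null_sd(T: int = 150, n_pairs: int = 10_000, seed: int = 123) -> float:
    """Sample SD of the scaled Fisher features for white-noise timeseries."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_pairs, T))
    y = rng.standard_normal((n_pairs, T))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    z = np.arctanh(r) * np.sqrt(T - 3)
    return float(z.std(ddof=1))
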
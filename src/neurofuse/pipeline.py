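"""End-to-end orchestration: simulate -> features -> harmonize -> train
(three modality modes) -> explain -> report, with a checksum manifest.

Each stage reads its inputs from and writes its outputs under one run
directory, so stages can be run individually (CLI subcommands) or together
via :func:`run`.  Every stochastic stage derives its seed from the global
seed plus a stable hash of the stage name, recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import explain as explain_mod
from . import features as features_mod
from . import harmonize as harmonize_mod
from . import model as model_mod
from . import synthetic

MODES = ("structural", "functional", "joint")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    modes: tuple[str, ...] = MODES
    harmonize: bool = True
    # synthetic cohort (package-default desk scale; pass the 35-site plan
    # from neurofuse.schema.ABIDE_SITE_PLAN for the full-size layout)
    n_sites: int = 10
    n_asd_per_site: int = 30
    n_td_per_site: int = 30
    n_regions: int = 50
    T: int = 150
    # cross-validation (desk-scale defaults; raise outer_k/inner_k and widen
    # search_space for full-size cohorts)
    outer_k: int = 5
    inner_k: int = 3
    search_space: tuple[tuple[int, ...], ...] = ((32,), (64, 32))
    epochs: int = 60
    batch_size: int = 64
    # explainability (ensemble of models on resampled splits)
    repetitions: int = 20
    explain_epochs: int = 60
    n_samples: int = 100
    background_size: int = 100
    percentile: float = 99.0

    def stage_seed(self, stage: str) -> int:
        return int((self.seed + zlib.crc32(stage.encode())) % 2**31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.modes = tuple(cfg.modes)
        cfg.search_space = tuple(tuple(c) for c in cfg.search_space)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> synthetic.Cohort:
    plan = [(cfg.n_asd_per_site, cfg.n_td_per_site)] * cfg.n_sites
    cohort = synthetic.generate_cohort(
        plan, truth=synthetic.default_effects(cfg.n_regions),
        seed=cfg.stage_seed("simulate"), n_regions=cfg.n_regions, T=cfg.T,
    )
    synthetic.write_cohort(cohort, _out(cfg) / "cohort")
    return cohort


def stage_features(cfg: RunConfig, cohort: synthetic.Cohort | None = None) -> features_mod.FeatureTable:
    cohort = cohort or synthetic.read_cohort(_out(cfg) / "cohort")
    table = features_mod.cohort_feature_table(cohort)
    table.to_tsv(_out(cfg) / "features.tsv")
    return table


def stage_harmonize(cfg: RunConfig, table: features_mod.FeatureTable | None = None) -> features_mod.FeatureTable:
    out = _out(cfg)
    table = table or features_mod.FeatureTable.from_tsv(out / "features.tsv")
    parts = pd.read_csv(out / "cohort" / "participants.tsv", sep="\t", index_col="id")
    controls = parts.index[parts["diagnosis"] == synthetic.TD]
    harmonized = []
    for modality in sorted(table.modality.unique()):  # modalities harmonized independently
        sub = table.select(modality)
        fit_tab = sub.restrict([i for i in sub.subjects if i in set(controls)])
        m = harmonize_mod.fit_harmonizer(fit_tab, parts["site"], parts["age"],
                                         diagnosis=parts["diagnosis"].reindex(fit_tab.subjects))
        m.to_json(out / f"harmonization_{modality}.json")
        harmonized.append(harmonize_mod.apply_harmonizer(m, sub, parts["site"], parts["age"]))
    result = harmonized[0]
    for h in harmonized[1:]:
        result = result.concat(h)
    # keep original column order
    result = features_mod.FeatureTable(
        result.df[table.df.columns], result.modality[table.df.columns], result.provenance)
    result.to_tsv(out / "harmonized.tsv")
    return result


def _analysis_table(cfg: RunConfig) -> features_mod.FeatureTable:
    out = _out(cfg)
    name = "harmonized.tsv" if cfg.harmonize and (out / "harmonized.tsv").exists() else "features.tsv"
    return features_mod.FeatureTable.from_tsv(out / name)


def stage_train(cfg: RunConfig, mode: str,
                table: features_mod.FeatureTable | None = None) -> model_mod.CVResults:
    out = _out(cfg)
    table = table or _analysis_table(cfg)
    parts = pd.read_csv(out / "cohort" / "participants.tsv", sep="\t", index_col="id")
    config = model_mod.TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size)
    # one shared seed across modality modes: identical outer folds, so the
    # paired between-model comparison is well defined
    results = model_mod.nested_cv(
        table, parts["diagnosis"], modality_mode=mode,
        outer_k=cfg.outer_k, inner_k=cfg.inner_k, search_space=cfg.search_space,
        config=config, seed=cfg.stage_seed("train"),
    )
    results.to_json(out / f"cv_{mode}.json")
    results.scores_tsv(out / f"scores_{mode}.tsv")
    return results


def stage_explain(cfg: RunConfig, table: features_mod.FeatureTable | None = None) -> pd.DataFrame:
    out = _out(cfg)
    table = table or _analysis_table(cfg)
    parts = pd.read_csv(out / "cohort" / "participants.tsv", sep="\t", index_col="id")
    y = model_mod.binarize_labels(parts["diagnosis"].reindex(table.subjects))
    seed = cfg.stage_seed("explain")
    blocks, names = {}, {}
    for m in (features_mod.STRUCTURAL, features_mod.FUNCTIONAL):
        X = table.select(m).df.to_numpy(dtype=float)
        blocks[m] = model_mod.scale_features(X)[0]
        names[m] = table.columns_of(m)
    s_norm = explain_mod.repeated_split_importance(
        blocks, y, names, repetitions=cfg.repetitions, epochs=cfg.explain_epochs,
        n_samples=cfg.n_samples, background_size=cfg.background_size, seed=seed,
    )
    imp = explain_mod.importance_table(s_norm, table.modality, cfg.percentile,
                                       repetitions=cfg.repetitions)
    selected = list(imp.index[imp["selected"]])
    effects = explain_mod.effect_directions(table.df, parts["diagnosis"], selected)
    report = imp.join(effects[["d", "sign"]])
    report.rename_axis("feature").to_csv(out / "importance.tsv", sep="\t")
    return report


def stage_report(cfg: RunConfig) -> pd.DataFrame:
    """Metrics table (one row per modality mode) plus the run manifest."""
    out = _out(cfg)
    rows = []
    for mode in cfg.modes:
        d = json.loads((out / f"cv_{mode}.json").read_text())
        rows.append({"model": mode, "auc_mean": d["auc_mean"], "auc_sd": d["auc_sd"],
                     "acc_mean": d["acc_mean"], "acc_sd": d["acc_sd"]})
    metrics = pd.DataFrame(rows).set_index("model")
    metrics.to_csv(out / "metrics.tsv", sep="\t")
    write_manifest(cfg)
    return metrics


def write_manifest(cfg: RunConfig) -> dict:
    out = _out(cfg)
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=list).encode()).hexdigest(),
        "stage_seeds": {s: cfg.stage_seed(s) for s in
                        ["simulate", "train", "explain"]},
        "files": {str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def verify(out_dir: str | Path) -> list[str]:
    """Re-check every manifest checksum; returns the list of mismatches."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    bad = []
    for rel, digest in manifest["files"].items():
        p = out / rel
        if not p.is_file():
            bad.append(f"missing: {rel}")
        elif hashlib.sha256(p.read_bytes()).hexdigest() != digest:
            bad.append(f"checksum mismatch: {rel}")
    return bad


# ---------------------------------------------------------------------------
# one-call run


@dataclass
class RunReport:
    metrics: pd.DataFrame
    importance: pd.DataFrame
    manifest: dict
    cv_results: dict[str, model_mod.CVResults] = field(default_factory=dict)


def run(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline; partial outputs are retained on failure."""
    stage = "simulate"
    try:
        cohort = stage_simulate(cfg)
        stage = "features"
        table = stage_features(cfg, cohort)
        if cfg.harmonize:
            stage = "harmonize"
            table = stage_harmonize(cfg, table)
        cv_results = {}
        for mode in cfg.modes:
            stage = f"train:{mode}"
            cv_results[mode] = stage_train(cfg, mode, table)
        stage = "explain"
        importance = stage_explain(cfg, table)
        stage = "report"
        metrics = stage_report(cfg)
        manifest = json.loads((_out(cfg) / "manifest.json").read_text())
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return RunReport(metrics=metrics, importance=importance,
                     manifest=manifest, cv_results=cv_results)
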
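"""Modality feature tables.

Functional connectivity: the Pearson correlation between each pair of regional
timeseries, Fisher z-transformed (arctanh) and scaled by sqrt(T-3) so each
feature has approximately unit SD under the null, vectorized over the
non-redundant upper triangle — R(R-1)/2 features for R retained regions.
Regions without a usable timeseries in a significant fraction of subjects are
removed atlas-wide rather than discarding subjects.

Structural: a 221-feature morphometric vector parsed from Freesurfer
``aseg.stats`` / ``?h.aparc.stats`` text outputs (or produced directly by the
synthetic generator under the same schema).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .synthetic import Cohort, TimeseriesSet

STRUCTURAL = "structural"
FUNCTIONAL = "functional"

#: |r| is clipped below 1 before arctanh so features stay finite.
R_CLIP = 0.999999

#: Default threshold on the across-subject missingness fraction above which a
#: region is dropped from the atlas.
MISSING_FRAC_THRESHOLD = 0.1


# ---------------------------------------------------------------------------
# containers


@dataclass
class FCMatrix:
    regions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        R = len(self.regions)
        if v.shape != (R, R):
            raise ValueError("values must be R x R")
        self.values = v


@dataclass
class FeatureTable:
    """Named per-subject features with a per-column modality tag."""

    df: pd.DataFrame
    modality: pd.Series  # index = df.columns, values in {structural, functional}
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.modality.index) != list(self.df.columns):
            self.modality = self.modality.reindex(self.df.columns)
        if self.modality.isna().any():
            missing = list(self.modality.index[self.modality.isna()])
            raise ValueError(f"columns without modality tag: {missing[:5]}")
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def subjects(self) -> list[str]:
        return list(self.df.index)

    def columns_of(self, modality: str) -> list[str]:
        return list(self.modality.index[self.modality == modality])

    def restrict(self, subjects) -> "FeatureTable":
        return FeatureTable(self.df.loc[list(subjects)], self.modality, dict(self.provenance))

    def select(self, modality: str) -> "FeatureTable":
        cols = self.columns_of(modality)
        return FeatureTable(self.df[cols], self.modality[cols], dict(self.provenance))

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if list(self.df.index) != list(other.df.index):
            raise ValueError("subject rows differ")
        prov = {**self.provenance, **other.provenance}
        if "harmonized" in self.provenance or "harmonized" in other.provenance:
            prov["harmonized"] = sorted(set(self.provenance.get("harmonized", []))
                                        | set(other.provenance.get("harmonized", [])))
        return FeatureTable(
            pd.concat([self.df, other.df], axis=1),
            pd.concat([self.modality, other.modality]),
            prov,
        )

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.df.rename_axis("id").to_csv(path, sep="\t")
        sidecar = {"modality": self.modality.to_dict(), "provenance": self.provenance}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="id")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(df, pd.Series(sidecar["modality"]).reindex(df.columns), sidecar["provenance"])


@dataclass
class RegionMask:
    retained: list[str]
    removed: dict[str, float]  # region -> missingness fraction

    def __post_init__(self) -> None:
        overlap = set(self.retained) & set(self.removed)
        if overlap:
            raise ValueError(f"regions both retained and removed: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# functional connectivity


def pearson_fc(ts: TimeseriesSet) -> FCMatrix:
    """Sample Pearson correlation between every pair of regional timeseries."""
    if ts.T < 4:
        raise ValueError("need T >= 4")
    sd = ts.data.std(axis=1)
    dead = [r for r, s in zip(ts.regions, sd) if s == 0]
    if dead:
        raise ValueError(f"constant timeseries (correlation undefined) for regions: {dead}")
    R = np.corrcoef(ts.data)
    np.fill_diagonal(R, 1.0)
    return FCMatrix(regions=list(ts.regions), values=R)


def fc_feature_names(regions: list[str]) -> list[str]:
    """Upper-triangle (row-major, i<j) pair names ``fc__A__B``."""
    return [
        f"fc__{regions[i]}__{regions[j]}"
        for i in range(len(regions))
        for j in range(i + 1, len(regions))
    ]


def fc_to_features(fc: FCMatrix, T: int, clip: float = R_CLIP) -> pd.Series:
    """Fisher-z features: arctanh(r) * sqrt(T-3) over the upper triangle.

    |r| is clipped at ``clip`` so r = +/-1 maps to a large finite value.
    """
    if T <= 3:
        raise ValueError("scale factor sqrt(T-3) undefined for T <= 3")
    if not clip < 1:
        raise ValueError("clip must be < 1")
    iu = np.triu_indices(len(fc.regions), k=1)
    r = fc.values[iu]
    z = np.arctanh(np.clip(r, -clip, clip)) * np.sqrt(T - 3)
    return pd.Series(z, index=fc_feature_names(fc.regions))


def filter_regions(
    timeseries: list[TimeseriesSet],
    missing_frac_threshold: float = MISSING_FRAC_THRESHOLD,
    atlas: list[str] | None = None,
) -> RegionMask:
    """Drop regions missing in more than ``missing_frac_threshold`` of subjects.

    The mask is computed cohort-wide and applied uniformly, so subjects with a
    sporadically missing region are kept rather than excluded.
    """
    if not 0 < missing_frac_threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not timeseries:
        raise ValueError("no subjects with timeseries")
    if atlas is None:
        seen: dict[str, None] = {}
        for t in timeseries:
            for r in t.regions:
                seen.setdefault(r)
        atlas = list(seen)
    n = len(timeseries)
    present = {r: 0 for r in atlas}
    for t in timeseries:
        for r in t.regions:
            if r in present:
                present[r] += 1
    frac = {r: 1.0 - present[r] / n for r in atlas}
    removed = {r: f for r, f in frac.items() if f > missing_frac_threshold}
    retained = [r for r in atlas if r not in removed]
    return RegionMask(retained=retained, removed=removed)


def subject_fc_features(ts: TimeseriesSet, mask: RegionMask, clip: float = R_CLIP) -> pd.Series:
    """FC feature vector for one subject under a cohort-wide region mask.

    Pairs involving a retained region this particular subject lacks are set to
    0 (the null value of the scaled Fisher feature).
    """
    have = set(ts.regions)
    keep = [r for r in mask.retained if r in have]  # mask order fixes pair naming
    idx = [ts.regions.index(r) for r in keep]
    sub = TimeseriesSet(regions=keep, data=ts.data[idx])
    feats = fc_to_features(pearson_fc(sub), T=sub.T, clip=clip)
    full = pd.Series(0.0, index=fc_feature_names(mask.retained))
    full[feats.index] = feats.to_numpy()
    return full


# ---------------------------------------------------------------------------
# cohort-level table construction


def functional_table(cohort: Cohort, mask: RegionMask | None = None,
                     missing_frac_threshold: float = MISSING_FRAC_THRESHOLD) -> FeatureTable:
    subs = [s for s in cohort.subjects if s.timeseries is not None]
    if not subs:
        raise ValueError("cohort has no timeseries")
    if mask is None:
        mask = filter_regions([s.timeseries for s in subs], missing_frac_threshold)
    rows = {s.id: subject_fc_features(s.timeseries, mask) for s in subs}
    df = pd.DataFrame.from_dict(rows, orient="index")
    modality = pd.Series(FUNCTIONAL, index=df.columns)
    prov = {"functional_schema": "fisher-z-fc/1", "retained_regions": list(mask.retained),
            "removed_regions": mask.removed}
    return FeatureTable(df, modality, prov)


def structural_table(cohort: Cohort) -> FeatureTable:
    df = cohort.structural_table()
    if df.empty:
        raise ValueError("cohort has no structural vectors")
    modality = pd.Series(STRUCTURAL, index=df.columns)
    return FeatureTable(df, modality, {"structural_schema": "freesurfer-221/1"})


def cohort_feature_table(cohort: Cohort, mask: RegionMask | None = None,
                         missing_frac_threshold: float = MISSING_FRAC_THRESHOLD) -> FeatureTable:
    """Combined structural + functional table, rows aligned on subject id."""
    st = structural_table(cohort)
    fn = functional_table(cohort, mask, missing_frac_threshold)
    common = [s for s in st.subjects if s in set(fn.subjects)]
    return st.restrict(common).concat(fn.restrict(common))


# ---------------------------------------------------------------------------
# Freesurfer stats text format


def _parse_stats(path: str | Path) -> tuple[dict[str, float], pd.DataFrame]:
    """Parse one Freesurfer stats file into ('# Measure' name -> value) and
    the whitespace-delimited table keyed by its ColHeaders."""
    measures: dict[str, float] = {}
    col_headers: list[str] | None = None
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("# Measure"):
            parts = [p.strip() for p in line[len("# Measure"):].split(",")]
            try:
                measures[parts[1]] = float(parts[3])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable Measure line: {line!r}") from exc
        elif line.startswith("# ColHeaders"):
            col_headers = line.split()[2:]
        elif line.startswith("#"):
            continue
        else:
            if col_headers is None:
                raise ValueError(f"{path}:{lineno}: table row before ColHeaders: {line!r}")
            fields = line.split()
            if len(fields) != len(col_headers):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(col_headers)} fields, got {len(fields)}"
                )
            rows.append(fields)
    table = pd.DataFrame(rows, columns=col_headers if col_headers else [])
    return measures, table


def read_freesurfer_stats(aseg_path, lh_aparc_path, rh_aparc_path) -> pd.Series:
    """Assemble the 221-feature structural vector from stats files.

    Globals come from aseg '# Measure' lines (plus the CSF table row and each
    hemisphere's MeanThickness measure); subcortical volumes from the aseg
    table; per-region volume / mean thickness / thickness SD from the
    bilateral aparc tables.  Missing expected entries are reported by name.
    """
    aseg_meas, aseg_tab = _parse_stats(aseg_path)
    out: dict[str, float] = {}
    missing: list[str] = []

    aseg_vol: dict[str, float] = {}
    if not aseg_tab.empty:
        if "StructName" not in aseg_tab or "Volume_mm3" not in aseg_tab:
            raise ValueError(f"{aseg_path}: aseg table lacks StructName/Volume_mm3 columns")
        aseg_vol = dict(zip(aseg_tab["StructName"], aseg_tab["Volume_mm3"].astype(float)))

    for name in schema.GLOBAL_MEASURES:
        if name in ("lh_MeanThickness", "rh_MeanThickness"):
            continue
        if name == "CSF":
            if "CSF" in aseg_vol:
                out["CSF"] = aseg_vol["CSF"]
            else:
                missing.append("CSF")
        elif name in aseg_meas:
            out[name] = aseg_meas[name]
        else:
            missing.append(name)

    for name in schema.SUBCORTICAL_STRUCTURES:
        if name in aseg_vol:
            out[name] = aseg_vol[name]
        else:
            missing.append(name)

    for hemi, path in (("lh", lh_aparc_path), ("rh", rh_aparc_path)):
        meas, tab = _parse_stats(path)
        if "MeanThickness" in meas:
            out[f"{hemi}_MeanThickness"] = meas["MeanThickness"]
        else:
            missing.append(f"{hemi}_MeanThickness")
        by_region = tab.set_index("StructName") if "StructName" in tab else pd.DataFrame()
        for region in schema.DKT_REGIONS:
            for m in schema.CORTICAL_MEASURES:
                key = f"{hemi}_{region}_{m}"
                if region in by_region.index and m in by_region.columns:
                    out[key] = float(by_region.loc[region, m])
                else:
                    missing.append(key)

    if missing:
        raise ValueError(f"missing expected structural entries: {missing}")
    return pd.Series(out).reindex(schema.structural_feature_names())


def write_freesurfer_stats(values: pd.Series, outdir: str | Path) -> tuple[Path, Path, Path]:
    """Write synthetic miniature aseg/aparc stats files carrying ``values``.

    Inverse of :func:`read_freesurfer_stats` for fixture generation; the files
    follow the stats text dialect but carry synthetic numbers, not any
    subject's real morphometry.
    """
    values = values.reindex(schema.structural_feature_names())
    if values.isna().any():
        raise ValueError("values must cover the full 221-feature schema")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    aseg = out / "aseg.stats"
    lines = ["# Title Segmentation Statistics (synthetic fixture)"]
    for name in ("lhCortexVol", "rhCortexVol", "lhCerebralWhiteMatterVol",
                 "rhCerebralWhiteMatterVol", "TotalGrayVol", "BrainSegVolNotVent"):
        lines.append(f"# Measure {name.replace('Vol', '')}, {name}, {name}, {values[name]:.6f}, mm^3")
    lines.append("# ColHeaders Index SegId NVoxels Volume_mm3 StructName")
    seg_rows = list(schema.SUBCORTICAL_STRUCTURES) + ["CSF"]
    for k, name in enumerate(seg_rows, start=1):
        lines.append(f"{k} {k} 1000 {values[name]:.6f} {name}")
    aseg.write_text("\n".join(lines) + "\n")

    paths = [aseg]
    for hemi in ("lh", "rh"):
        p = out / f"{hemi}.aparc.stats"
        lines = [f"# Title Cortical Parcellation Statistics (synthetic fixture, {hemi})",
                 f"# Measure Cortex, MeanThickness, Mean Thickness, {values[f'{hemi}_MeanThickness']:.6f}, mm",
                 "# ColHeaders StructName GrayVol ThickAvg ThickStd"]
        for region in schema.DKT_REGIONS:
            gv = values[f"{hemi}_{region}_GrayVol"]
            ta = values[f"{hemi}_{region}_ThickAvg"]
            ts_ = values[f"{hemi}_{region}_ThickStd"]
            lines.append(f"{region} {gv:.6f} {ta:.6f} {ts_:.6f}")
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    return tuple(paths)
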
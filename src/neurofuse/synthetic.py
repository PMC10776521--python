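"""Synthetic multi-site, two-modality cohort generator.

Emulates the statistical structure of a pooled multi-site autism MRI sample:
many acquisition sites of unequal size, male subjects aged 5-40 years,
additive and multiplicative per-site batch effects, a smooth nonlinear age
trend, and diagnosis effects planted in a sparse, known subset of features.
Functional data are generated as regional timeseries drawn from a
diagnosis- and site-conditional multivariate normal; structural data as a
named morphometric vector.  Because the planted structure is known exactly,
every downstream stage (connectivity features, harmonization, the fusion
classifier, attribution) can be validated against ground truth without any
image download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import schema

ASD = "ASD"
TD = "TD"

#: Age distribution of the emulated cohort (years): truncated normal matching
#: the pooled sample's reported moments (mean ~15, SD ~7, range 5-40).
AGE_MEAN = 15.0
AGE_SD = 7.0
AGE_RANGE = (5.0, 40.0)


# ---------------------------------------------------------------------------
# ground-truth specification


@dataclass
class EffectSpec:
    """Planted ground truth for a synthetic cohort.

    ``informative_structural`` maps structural feature names to signed
    Cohen's-d effects (ASD minus TD, in residual-SD units).
    ``informative_pairs`` lists ``(i, j, delta_rho)`` region-index pairs whose
    pairwise correlation is shifted by ``delta_rho`` in the ASD group —
    negative for long-range inter-hemispheric hypo-connectivity, positive for
    local intra-hemispheric hyper-connectivity.

    Site batch effects: explicit per-site dicts (``site_location`` additive
    offsets, ``site_scale`` multiplicative factors for structural features,
    ``site_rho`` additive off-diagonal correlation offsets for functional
    data) take precedence; when empty they are realized from the ``*_sd``
    hyperparameters at cohort-generation time and stored back, so the truth
    attached to a cohort is always fully explicit.
    """

    informative_structural: dict[str, float] = field(default_factory=dict)
    informative_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    site_location: dict[str, float] = field(default_factory=dict)
    site_scale: dict[str, float] = field(default_factory=dict)
    site_rho: dict[str, float] = field(default_factory=dict)
    site_location_sd: float = 0.0
    site_scale_sd: float = 0.0
    site_rho_sd: float = 0.0
    #: polynomial coefficients c of the age trend c0 + c1*u + c2*u^2 + c3*u^3,
    #: u = (age - 15)/10; added to every structural feature.
    age_coefs: tuple[float, ...] = ()
    noise_sd: float = 1.0
    #: within-block correlation of the base (TD, site-free) FC structure
    base_rho: float = 0.3
    n_blocks: int = 5

    def validate(self, n_regions: int, feature_names: list[str]) -> None:
        known = set(feature_names)
        unknown = sorted(set(self.informative_structural) - known)
        if unknown:
            raise ValueError(f"informative_structural names not in schema: {unknown}")
        for i, j, _ in self.informative_pairs:
            if not (0 <= i < n_regions and 0 <= j < n_regions and i != j):
                raise ValueError(f"informative pair ({i},{j}) outside 0..{n_regions - 1}")
        for site, d in self.site_scale.items():
            if np.any(np.asarray(d) <= 0):
                raise ValueError(f"site_scale for {site!r} must be positive")

    def to_json(self) -> str:
        d = asdict(self)
        d["informative_pairs"] = [list(p) for p in self.informative_pairs]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EffectSpec":
        d = json.loads(text)
        d["informative_pairs"] = [tuple(p) for p in d["informative_pairs"]]
        d["age_coefs"] = tuple(d["age_coefs"])
        return cls(**d)

    @classmethod
    def null(cls) -> "EffectSpec":
        """No diagnosis effects, no site effects, no age trend."""
        return cls()


def default_effects(n_regions: int = 50) -> EffectSpec:
    """Default planted structure at the package's standard synthetic scale.

    Mimics the qualitative pattern reported in multi-site ASD studies:
    inter-hemispheric hypo-connectivity over long-range pairs, local
    intra-hemispheric hyper-connectivity, a few cortical thickness/volume
    shifts, moderate site batch effects and a decreasing nonlinear age trend.
    Region ids alternate hemisphere (even = left, odd = right), so pairs with
    opposite parity are inter-hemispheric.
    """
    if n_regions < 10:
        raise ValueError("default planted pairs need at least 10 regions")
    hypo = [  # distant opposite-parity pairs, correlation lowered in ASD
        (0, n_regions - 1, -0.30),
        (2, n_regions - 3, -0.30),
        (4, n_regions - 5, -0.30),
    ]
    hyper = [  # adjacent same-parity pairs, correlation raised in ASD
        (1, 3, 0.30),
        (6, 8, 0.30),
    ]
    return EffectSpec(
        informative_structural={
            "lh_superiortemporal_ThickAvg": 0.8,
            "rh_medialorbitofrontal_ThickAvg": 0.8,
            "lh_pericalcarine_GrayVol": -0.8,
        },
        informative_pairs=hypo + hyper,
        site_location_sd=0.8,
        site_scale_sd=0.15,
        site_rho_sd=0.03,
        age_coefs=(0.0, -0.8, 0.25, 0.0),
        noise_sd=1.0,
    )


def complementary_effects(n_regions: int = 50) -> EffectSpec:
    """Complementary-signal variant: disjoint structural and functional
    effect sets of *matched discriminability*, so each modality carries
    comparable independent diagnostic information and their fusion has
    something to gain.

    Matching is done in standardized feature units: a structural effect is
    d = 0.8 directly, and a correlation shift of delta-rho = 0.07 gives the
    scaled Fisher feature (unit null SD) a mean shift of
    arctanh(0.07) * sqrt(147) ~ 0.85 at T = 150 — the same order.  Larger
    shifts like 0.3 would make single connectivity features worth d ~ 4.6
    and let one modality dominate any fusion.
    """
    struct = {
        "lh_superiortemporal_ThickAvg": 0.8,
        "rh_superiortemporal_ThickAvg": 0.8,
        "rh_medialorbitofrontal_ThickAvg": 0.8,
        "lh_fusiform_ThickAvg": -0.8,
        "lh_pericalcarine_GrayVol": -0.8,
        "rh_middletemporal_GrayVol": -0.8,
        "lh_posteriorcingulate_ThickAvg": -0.8,
        "rh_parstriangularis_ThickAvg": -0.8,
    }
    dr = 0.07
    hypo = [(0, n_regions - 1, -dr), (2, n_regions - 3, -dr), (4, n_regions - 5, -dr),
            (6, n_regions - 7, -dr), (8, n_regions - 9, -dr)]
    hyper = [(1, 3, dr), (5, 7, dr), (11, 13, dr)]
    return EffectSpec(
        informative_structural=struct,
        informative_pairs=hypo + hyper,
        site_location_sd=0.8,
        site_scale_sd=0.15,
        site_rho_sd=0.03,
        age_coefs=(0.0, -0.8, 0.25, 0.0),
    )


# ---------------------------------------------------------------------------
# cohort containers


@dataclass
class TimeseriesSet:
    """Regional timeseries of one subject: ``data`` is regions x T."""

    regions: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.regions):
            raise ValueError("data must be (len(regions), T)")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region ids")
        if self.T < 4:
            raise ValueError("need T >= 4 timepoints")

    @property
    def T(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectRecord:
    id: str
    site: str
    age: float
    diagnosis: str
    timeseries: TimeseriesSet | None = None
    structural: pd.Series | None = None


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    sites: pd.DataFrame  # columns: site, n_ASD, n_TD
    truth: EffectSpec
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def participants(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.subjects],
                "site": [s.site for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "diagnosis": [s.diagnosis for s in self.subjects],
            }
        ).set_index("id")

    def structural_table(self) -> pd.DataFrame:
        rows = {s.id: s.structural for s in self.subjects if s.structural is not None}
        return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# generation


def base_correlation(n_regions: int, rho: float = 0.3, n_blocks: int = 5) -> np.ndarray:
    """Block-structured base correlation matrix (within-block ``rho``),
    regularized to positive-definite by eigenvalue clipping."""
    R = np.eye(n_regions)
    bounds = np.linspace(0, n_regions, n_blocks + 1).astype(int)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        R[lo:hi, lo:hi] = rho
    np.fill_diagonal(R, 1.0)
    return _pd_clip(R)


def _pd_clip(R: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Clip eigenvalues to ``floor`` and rescale back to a correlation matrix."""
    w, V = np.linalg.eigh(R)
    if w.min() >= floor:
        return R
    R2 = (V * np.maximum(w, floor)) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def _age_trend(spec: EffectSpec, age: float | np.ndarray) -> np.ndarray:
    if not spec.age_coefs:
        return np.zeros_like(np.asarray(age, dtype=float))
    u = (np.asarray(age, dtype=float) - 15.0) / 10.0
    return np.polyval(list(reversed(spec.age_coefs)), u)


def _target_correlation(spec: EffectSpec, site: str, diagnosis: str, n_regions: int) -> np.ndarray:
    R = base_correlation(n_regions, spec.base_rho, spec.n_blocks)
    if diagnosis == ASD and spec.informative_pairs:
        for i, j, drho in spec.informative_pairs:
            R[i, j] += drho
            R[j, i] += drho
        w = np.linalg.eigvalsh(R)
        if w.min() < 1e-8:
            raise ValueError(
                "correlation shifts make the target matrix non-positive-definite; "
                f"offending pairs: {spec.informative_pairs}"
            )
    s = spec.site_rho.get(site, 0.0)
    if s:
        off = ~np.eye(n_regions, dtype=bool)
        R = R.copy()
        R[off] = np.clip(R[off] + s, -0.99, 0.99)
        R = _pd_clip(R)
    return R


def _structural_baseline(names: list[str]) -> pd.Series:
    """Plausible morphometric magnitudes per feature class (mm / mm^3)."""
    vals = np.empty(len(names))
    for k, name in enumerate(names):
        if name.endswith("ThickAvg") or name.endswith("MeanThickness"):
            vals[k] = 2.5
        elif name.endswith("ThickStd"):
            vals[k] = 0.5
        elif name in schema.GLOBAL_MEASURES:
            vals[k] = 2.0e5
        elif name.endswith("GrayVol"):
            vals[k] = 5.0e3
        else:  # subcortical volumes
            vals[k] = 3.0e3
    return pd.Series(vals, index=names)


def generate_subject_data(
    subject: SubjectRecord,
    truth: EffectSpec,
    n_regions: int,
    T: int,
    seed: int,
    missing_regions: list[str] | None = None,
) -> SubjectRecord:
    """Fill both modalities of ``subject`` from the planted ground truth.

    Timeseries are zero-mean multivariate normal draws whose correlation is
    the base matrix plus the diagnosis-conditional pair shifts and the site
    offset.  The structural vector is baseline + age trend + diagnosis effect
    + site location, with site-scaled residual noise.
    """
    if T < 4:
        raise ValueError("need T >= 4")
    names = schema.structural_feature_names()
    truth.validate(n_regions, names)
    rng = np.random.default_rng(seed)

    # functional: MVN timeseries
    R = _target_correlation(truth, subject.site, subject.diagnosis, n_regions)
    L = np.linalg.cholesky(R)
    ts = L @ rng.standard_normal((n_regions, T))
    region_ids = schema.atlas_region_ids(n_regions)
    if missing_regions:
        keep = [k for k, r in enumerate(region_ids) if r not in set(missing_regions)]
        ts = ts[keep]
        region_ids = [region_ids[k] for k in keep]
    subject.timeseries = TimeseriesSet(regions=region_ids, data=ts)

    # structural: additive model in feature space
    x = _structural_baseline(names).to_numpy().copy()
    x += _age_trend(truth, subject.age)
    if subject.diagnosis == ASD:
        for name, d in truth.informative_structural.items():
            x[names.index(name)] += d * truth.noise_sd
    gamma = truth.site_location.get(subject.site, 0.0)
    delta = truth.site_scale.get(subject.site, 1.0)
    x += gamma + delta * truth.noise_sd * rng.standard_normal(len(names))
    subject.structural = pd.Series(x, index=names)
    return subject


def _realize_site_effects(truth: EffectSpec, sites: list[str], rng: np.random.Generator) -> EffectSpec:
    """Fill in per-site batch parameters from the spec's hyperparameters."""
    loc = dict(truth.site_location)
    scl = dict(truth.site_scale)
    rho = dict(truth.site_rho)
    for site in sites:
        if site not in loc:
            loc[site] = float(rng.normal(0.0, truth.site_location_sd)) if truth.site_location_sd else 0.0
        if site not in scl:
            scl[site] = float(np.exp(rng.normal(0.0, truth.site_scale_sd))) if truth.site_scale_sd else 1.0
        if site not in rho:
            rho[site] = float(rng.normal(0.0, truth.site_rho_sd)) if truth.site_rho_sd else 0.0
    out = EffectSpec(**{**asdict(truth), "site_location": loc, "site_scale": scl, "site_rho": rho})
    out.informative_pairs = list(truth.informative_pairs)
    return out


def generate_cohort(
    site_plan: list[tuple] | tuple,
    age_range: tuple[float, float] = AGE_RANGE,
    truth: EffectSpec | None = None,
    seed: int = 0,
    n_regions: int = 50,
    T: int = 150,
    with_data: bool = True,
    missing_spec: dict[str, float] | None = None,
) -> Cohort:
    """Generate a deterministic multi-site cohort.

    ``site_plan`` is a list of ``(n_ASD, n_TD)`` or ``(site, n_ASD, n_TD)``
    tuples; group sizes per site are exactly as requested.  Ages follow a
    truncated normal (mean 15 y, SD 7 y) restricted to ``age_range``.
    ``missing_spec`` maps region ids to the probability a given subject's
    timeseries for that region is absent (emulating regions dropped by the
    extraction pipeline for some scans).
    """
    if not site_plan:
        raise ValueError("site_plan is empty")
    lo, hi = age_range
    if lo >= hi:
        raise ValueError(f"degenerate age_range {age_range}")
    plan = []
    for k, entry in enumerate(site_plan):
        if len(entry) == 3:
            plan.append((str(entry[0]), int(entry[1]), int(entry[2])))
        else:
            plan.append((f"site{k + 1:02d}", int(entry[0]), int(entry[1])))

    truth = truth if truth is not None else EffectSpec.null()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    truth = _realize_site_effects(truth, [p[0] for p in plan], rng)

    a, b = (lo - AGE_MEAN) / AGE_SD, (hi - AGE_MEAN) / AGE_SD
    subjects: list[SubjectRecord] = []
    for site, n_asd, n_td in plan:
        for dx, n in ((ASD, n_asd), (TD, n_td)):
            ages = stats.truncnorm.rvs(a, b, loc=AGE_MEAN, scale=AGE_SD, size=n, random_state=rng)
            for i in range(n):
                subjects.append(
                    SubjectRecord(
                        id=f"{site}_{dx}_{i + 1:04d}",
                        site=site,
                        age=float(ages[i]),
                        diagnosis=dx,
                    )
                )

    if with_data:
        child_seeds = ss.spawn(len(subjects) + 1)[1:]
        for subj, cs in zip(subjects, child_seeds):
            sub_rng = np.random.default_rng(cs)
            missing = None
            if missing_spec:
                missing = [r for r, frac in missing_spec.items() if sub_rng.random() < frac]
            generate_subject_data(
                subj, truth, n_regions, T,
                seed=int(sub_rng.integers(2**31)), missing_regions=missing,
            )

    sites_df = pd.DataFrame(plan, columns=["site", "n_ASD", "n_TD"])
    return Cohort(subjects=subjects, sites=sites_df, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write participants.tsv, structural.tsv, per-subject timeseries and truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.tsv", sep="\t")
    st = cohort.structural_table()
    if not st.empty:
        st.rename_axis("id").to_csv(out / "structural.tsv", sep="\t")
    tsdir = out / "timeseries"
    tsdir.mkdir(exist_ok=True)
    for s in cohort.subjects:
        if s.timeseries is not None:
            df = pd.DataFrame(s.timeseries.data.T, columns=s.timeseries.regions)
            df.to_csv(tsdir / f"{s.id}.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "truth.json").write_text(cohort.truth.to_json())
    (out / "meta.json").write_text(json.dumps({"seed": cohort.seed}))


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    ind = Path(indir)
    parts = pd.read_csv(ind / "participants.tsv", sep="\t", index_col="id")
    truth = EffectSpec.from_json((ind / "truth.json").read_text())
    seed = json.loads((ind / "meta.json").read_text())["seed"]
    structural = None
    if (ind / "structural.tsv").exists():
        structural = pd.read_csv(ind / "structural.tsv", sep="\t", index_col="id")
    subjects = []
    for sid, row in parts.iterrows():
        ts = None
        f = ind / "timeseries" / f"{sid}.tsv"
        if f.exists():
            df = pd.read_csv(f, sep="\t")
            ts = TimeseriesSet(regions=list(df.columns), data=df.to_numpy().T)
        struct = structural.loc[sid] if structural is not None and sid in structural.index else None
        subjects.append(
            SubjectRecord(id=str(sid), site=str(row["site"]), age=float(row["age"]),
                          diagnosis=str(row["diagnosis"]), timeseries=ts, structural=struct)
        )
    sites = (
        parts.groupby("site")["diagnosis"]
        .agg(n_ASD=lambda d: int((d == ASD).sum()), n_TD=lambda d: int((d == TD).sum()))
        .reset_index()
    )
    return Cohort(subjects=subjects, sites=sites, truth=truth, seed=seed)
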
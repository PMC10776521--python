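"""Control-anchored site harmonization with a preserved nonlinear age trend.

Per feature v the model is

    y = alpha_v + f_v(age) + gamma_iv + delta_iv * eps,   eps ~ N(0, sigma_v^2)

with additive site location gamma and multiplicative site scale delta.  The
age trend f_v is a natural cubic spline fit jointly with the site terms on
control subjects only; per-site location/scale estimates on the standardized
residuals are shrunk by parametric empirical Bayes (normal prior on gamma,
inverse-gamma on delta^2, moment-matched, iterated to the posterior mode) in
the ComBat tradition.  The fitted model is then applied to the whole sample
— cases and controls — so the diagnosis label never enters the adjustment:

    y_adj = sigma_v * (z - gamma*_iv) / delta*_iv + alpha_v + f_v(age)

where z is the standardized residual of y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureTable

SCHEMA_VERSION = "harmonization-model/1"


# ---------------------------------------------------------------------------
# natural cubic spline basis


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    For K knots returns K-1 columns: x itself plus the K-2 standard truncated
    power-basis combinations d_k(x) - d_{K-1}(x).
    """
    x = np.asarray(x, dtype=float)
    K = len(knots)
    if K < 3:
        raise ValueError("need at least 3 knots")

    def d(k):
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def spline_knots(x: np.ndarray, df: int) -> np.ndarray:
    """df+1 knots at equally spaced quantiles (boundary knots included)."""
    qs = np.linspace(0, 1, df + 1)
    knots = np.quantile(np.asarray(x, dtype=float), qs)
    if len(np.unique(knots)) != len(knots):
        raise ValueError("degenerate age distribution: duplicate spline knots")
    return knots


# ---------------------------------------------------------------------------
# model container


@dataclass
class HarmonizationModel:
    features: list[str]
    sites: list[str]
    knots: np.ndarray
    grand_mean: np.ndarray          # (F,) alpha_v
    beta_age: np.ndarray            # (df, F) spline coefficients
    var_pooled: np.ndarray          # (F,) sigma_v^2
    gamma_star: np.ndarray          # (S, F)
    delta_star_sq: np.ndarray       # (S, F)
    fitted_on: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=lambda: ["age"])
    eb: bool = True

    def __post_init__(self) -> None:
        if np.any(self.delta_star_sq <= 0):
            raise ValueError("site scale parameters must be positive")

    def _site_index(self, site: str) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(
                f"site {site!r} unseen at fit time; refusing transductive refit"
            ) from None

    def age_effect(self, age: np.ndarray) -> np.ndarray:
        """f_v(age) for each feature: (n, F) matrix."""
        return natural_spline_basis(np.asarray(age, dtype=float), self.knots) @ self.beta_age

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "schema": SCHEMA_VERSION,
            "features": self.features,
            "sites": self.sites,
            "knots": self.knots.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "beta_age": self.beta_age.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star_sq": self.delta_star_sq.tolist(),
            "fitted_on": self.fitted_on,
            "covariates": self.covariates,
            "eb": self.eb,
        }
        text = json.dumps(d)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HarmonizationModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        if d.pop("schema") != SCHEMA_VERSION:
            raise ValueError("unknown model schema version")
        for k in ("knots", "grand_mean", "beta_age", "var_pooled", "gamma_star", "delta_star_sq"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# empirical Bayes machinery (parametric, moment-matched priors)


def _aprior(delta_hat_sq: np.ndarray) -> float:
    m, s2 = delta_hat_sq.mean(), delta_hat_sq.var()
    return (2 * s2 + m**2) / s2 if s2 > 0 else 2.0

def _bprior(delta_hat_sq: np.ndarray) -> float:
    m, s2 = delta_hat_sq.mean(), delta_hat_sq.var()
    return (m * s2 + m**3) / s2 if s2 > 0 else delta_hat_sq.mean()


def _eb_site(z_site: np.ndarray, gamma_hat: np.ndarray, delta_hat_sq: np.ndarray,
             tol: float = 1e-4, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Iterated posterior estimates for one site's (gamma, delta^2) vectors."""
    n = z_site.shape[0]
    g_bar, t2 = gamma_hat.mean(), gamma_hat.var()
    a, b = _aprior(delta_hat_sq), _bprior(delta_hat_sq)
    g, d = gamma_hat.copy(), delta_hat_sq.copy()
    if t2 == 0:  # single feature or identical estimates: no pooling possible
        return g, d
    for _ in range(max_iter):
        g_new = (t2 * n * gamma_hat + d * g_bar) / (t2 * n + d)
        sum2 = ((z_site - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(np.abs(g_new - g).max(), np.abs(d_new - d).max())
        g, d = g_new, d_new
        if change < tol:
            break
    return g, d


# ---------------------------------------------------------------------------
# fit / apply


def fit_harmonizer(
    table: FeatureTable,
    site: pd.Series,
    age: pd.Series,
    spline_df: int = 5,
    eb: bool = True,
    diagnosis: pd.Series | None = None,
    allow_cases: bool = False,
) -> HarmonizationModel:
    """Fit the harmonization model on control subjects.

    ``site``/``age`` (and optional ``diagnosis``) are indexed by subject id.
    The fit refuses tables containing case subjects unless ``allow_cases`` is
    set, to keep the protocol controls-anchored by construction.
    """
    ids = table.subjects
    site = site.reindex(ids)
    age = age.reindex(ids).astype(float)
    if site.isna().any() or age.isna().any() or not np.isfinite(age).all():
        raise ValueError("every subject needs a finite age and a site label")
    if diagnosis is not None and not allow_cases:
        dx = diagnosis.reindex(ids)
        cases = sorted(set(dx.unique()) - {"TD", "control", "CN", "HC"})
        if cases:
            raise ValueError(
                f"fit table contains non-control labels {cases}; the model is "
                "fit on controls only (pass allow_cases=True to override)"
            )

    sites = sorted(site.unique())
    counts = site.value_counts()
    small = [s for s in sites if counts[s] < 3]
    if small:
        raise ValueError(f"sites with <3 control subjects (scale inestimable): {small}")

    Y = table.df.to_numpy(dtype=float)
    n, F = Y.shape
    const = Y.std(axis=0) == 0
    if const.any():
        bad = [table.df.columns[k] for k in np.flatnonzero(const)[:5]]
        raise ValueError(f"constant features (sigma undefined): {bad}")

    knots = spline_knots(age.to_numpy(), spline_df)
    S_age = natural_spline_basis(age.to_numpy(), knots)         # (n, df)
    D_site = pd.get_dummies(site).reindex(columns=sites).to_numpy(dtype=float)  # (n, S)
    X = np.hstack([D_site, S_age])
    B = np.linalg.lstsq(X, Y, rcond=None)[0]                    # (S+df, F)
    m = len(sites)
    n_per = D_site.sum(axis=0)
    grand_mean = (n_per / n) @ B[:m]                            # (F,)
    beta_age = B[m:]                                            # (df, F)
    resid = Y - X @ B
    var_pooled = (resid**2).mean(axis=0)                        # (F,)
    sd = np.sqrt(var_pooled)

    stand_mean = grand_mean[None, :] + S_age @ beta_age
    Z = (Y - stand_mean) / sd[None, :]

    gamma_star = np.empty((m, F))
    delta_star_sq = np.empty((m, F))
    for i, s in enumerate(sites):
        zi = Z[D_site[:, i] == 1]
        g_hat = zi.mean(axis=0)
        d_hat = zi.var(axis=0, ddof=1)
        d_hat = np.maximum(d_hat, 1e-8)
        if eb and F > 1:
            gamma_star[i], delta_star_sq[i] = _eb_site(zi, g_hat, d_hat)
        else:
            gamma_star[i], delta_star_sq[i] = g_hat, d_hat
    delta_star_sq = np.maximum(delta_star_sq, 1e-8)

    return HarmonizationModel(
        features=list(table.df.columns),
        sites=sites,
        knots=knots,
        grand_mean=grand_mean,
        beta_age=beta_age,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        fitted_on=list(ids),
        eb=eb,
    )


def apply_harmonizer(model: HarmonizationModel, table: FeatureTable,
                     site: pd.Series, age: pd.Series) -> FeatureTable:
    """Remove the fitted site effects from ``table`` (any subjects).

    Diagnosis is never an input: the adjustment depends only on site and age.
    """
    cols = list(table.df.columns)
    unknown = sorted(set(cols) - set(model.features))
    if unknown:
        raise ValueError(f"features unseen at fit time: {unknown[:5]}")
    ids = table.subjects
    site = site.reindex(ids)
    age = age.reindex(ids).astype(float)
    idx = [model.features.index(c) for c in cols]
    site_rows = np.array([model._site_index(s) for s in site])

    Y = table.df.to_numpy(dtype=float)
    sd = np.sqrt(model.var_pooled[idx])[None, :]
    stand_mean = model.grand_mean[idx][None, :] + model.age_effect(age.to_numpy())[:, idx]
    Z = (Y - stand_mean) / sd
    g = model.gamma_star[np.ix_(site_rows, idx)]
    dsd = np.sqrt(model.delta_star_sq[np.ix_(site_rows, idx)])
    Y_adj = sd * (Z - g) / dsd + stand_mean

    df = pd.DataFrame(Y_adj, index=ids, columns=cols)
    prov = dict(table.provenance)
    prov["harmonized"] = sorted(table.modality.unique())
    return FeatureTable(df, table.modality[cols], prov)
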
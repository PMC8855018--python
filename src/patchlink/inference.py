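"""Statistical layer: scaling, collinearity screening, fixed-structure
Gaussian linear models, cross-metric Pearson correlations and diagnostics.

Each community response is modelled with exactly three explanatory
variables — one herbicide variable, one connectivity variable, one local
variable — to avoid overfitting at n ~ 35 sites:

    response ~ herbicide + connectivity + local

Continuous predictors are z-scored; candidate predictors within and across
categories are screened so that no retained pair has |r| > 0.3.  Models are
ordinary least squares with Gaussian errors; rows with any missing input are
dropped (complete cases) and the n used is recorded.

The modelling interface follows the statsmodels idiom: ``DiversityLM`` is
built from a site-level DataFrame and a ``ModelSpec``; ``fit()`` returns a
``DiversityLMResults`` carrying coefficients, standard errors, p-values,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "DiversityLM",
    "DiversityLMResults",
    "CorrelationReport",
    "zscore_scale",
    "collinearity_screen",
    "fit_gaussian_lm",
    "pearson_matrix",
    "morans_i",
    "diagnostics",
    "COLLINEARITY_CUTOFF",
]

#: Pairwise |r| above this excludes variables from co-selection.
COLLINEARITY_CUTOFF = 0.3


def zscore_scale(values: pd.Series | np.ndarray, name: str = "variable") -> np.ndarray:
    """Scale to zero mean and unit sample SD (n-1) over non-missing entries.

    Missing values are preserved.  A variable with fewer than two observed
    values or zero spread cannot be scaled and raises ``ValueError`` naming
    it.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError(f"cannot scale {name!r}: fewer than 2 observed values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError(f"cannot scale {name!r}: zero spread")
    return (x - obs.mean()) / sd


def collinearity_screen(
    data: pd.DataFrame,
    categories: dict[str, list[str]],
    cutoff: float = COLLINEARITY_CUTOFF,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Select one variable per category with all pairwise |r| <= cutoff.

    ``categories`` maps category name (e.g. herbicide / connectivity /
    local) to its candidate column names.  Categorical (non-numeric)
    candidates are treated as always co-selectable.  Among feasible
    selections, the one minimising the maximum pairwise |r| wins; ties are
    broken by category order then name order.  Returns the selection and an
    exclusion log listing every rejected pair with its correlation.

    Raises ``ValueError`` listing the offending correlations when no
    feasible selection exists.
    """
    numeric = [
        c for cols in categories.values() for c in cols
        if c in data.columns and pd.api.types.is_numeric_dtype(data[c])
    ]
    corr = data[numeric].corr(method="pearson") if numeric else pd.DataFrame()

    def r_of(a: str, b: str) -> float:
        if a in corr.index and b in corr.index:
            return float(corr.loc[a, b])
        return 0.0  # categorical pairs are not screened

    log_rows = []
    for a, b in itertools.combinations(numeric, 2):
        r = r_of(a, b)
        if abs(r) > cutoff:
            log_rows.append({"var_a": a, "var_b": b, "r": r, "excluded": True})
    log = pd.DataFrame(log_rows, columns=["var_a", "var_b", "r", "excluded"])

    cat_names = list(categories)
    best: tuple | None = None
    for combo in itertools.product(*(categories[c] for c in cat_names)):
        rs = [abs(r_of(a, b)) for a, b in itertools.combinations(combo, 2)]
        max_r = max(rs, default=0.0)
        if max_r > cutoff:
            continue
        if best is None or (max_r, combo) < (best[0], best[1]):
            best = (max_r, combo)
    if best is None:
        offending = log.to_string(index=False) if len(log) else "(none logged)"
        raise ValueError(
            "no feasible selection with all pairwise |r| <= "
            f"{cutoff}; offending correlations:\n{offending}"
        )
    selection = dict(zip(cat_names, best[1]))
    return selection, log


@dataclass
class ModelSpec:
    """Fixed three-predictor structure for one response."""

    response: str
    herbicide: str
    connectivity: str
    local: str
    categorical_local: bool = False  # e.g. soil type (sandy vs clay)
    reference_level: str = "clay"

    @property
    def predictors(self) -> list[str]:
        return [self.herbicide, self.connectivity, self.local]


class DiversityLM:
    """Gaussian linear model for one community response at the site level.

    Built from a site-level DataFrame; continuous predictors are z-scored
    (sample SD), a categorical local variable is dummy-coded against its
    reference level (clay by default, so the reported contrast reads
    "sandy versus clay"), and rows with any missing input are dropped.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec, scale: bool = True):
        self.spec = spec
        cols = [spec.response] + spec.predictors
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"columns absent from site table: {missing}")
        df = data[cols].copy()
        df = df.dropna()
        self.n = len(df)
        if self.n <= 5:
            raise ValueError(
                f"only {self.n} complete cases; need > 5 for 3 slopes + intercept"
            )
        y = df[spec.response].to_numpy(dtype=float)
        X = pd.DataFrame(index=df.index)
        for name in (spec.herbicide, spec.connectivity):
            x = df[name].to_numpy(dtype=float)
            X[name] = zscore_scale(x, name) if scale else x
        if spec.categorical_local:
            levels = sorted(df[spec.local].astype(str).unique())
            if spec.reference_level not in levels:
                raise ValueError(
                    f"reference level {spec.reference_level!r} absent from "
                    f"{spec.local!r} (levels: {levels})"
                )
            for lev in levels:
                if lev == spec.reference_level:
                    continue
                X[f"{spec.local}[{lev} vs {spec.reference_level}]"] = (
                    (df[spec.local].astype(str) == lev).astype(float)
                )
        else:
            x = df[spec.local].to_numpy(dtype=float)
            X[spec.local] = zscore_scale(x, spec.local) if scale else x
        self.endog = y
        self.exog = sm.add_constant(X, prepend=True)
        self.data_used = df
        if np.linalg.matrix_rank(self.exog.to_numpy()) < self.exog.shape[1]:
            raise ValueError("rank-deficient design matrix")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec, **kw) -> "DiversityLM":
        return cls(data, spec, **kw)

    def fit(self) -> "DiversityLMResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return DiversityLMResults(self, res)


class DiversityLMResults:
    """OLS results for one response: estimates, uncertainty, diagnostics."""

    def __init__(self, model: DiversityLM, res):
        self.model = model
        self._res = res
        self.params = res.params
        self.bse = res.bse
        self.tvalues = res.tvalues
        self.pvalues = res.pvalues
        self.resid = res.resid
        self.fittedvalues = res.fittedvalues
        self.n = model.n
        self.rsquared = res.rsquared

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._res.conf_int(alpha=alpha)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: beta, SE, t, p per term (printed-table shape)."""
        return pd.DataFrame({
            "term": self.params.index,
            "beta": self.params.values,
            "se": self.bse.values,
            "t": self.tvalues.values,
            "p": self.pvalues.values,
        }).set_index("term")

    def diagnostics(self, site_xy: np.ndarray | None = None,
                    n_permutations: int = 999, seed: int = 0) -> dict:
        return diagnostics(self, site_xy, n_permutations=n_permutations, seed=seed)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<DiversityLMResults {self.model.spec.response!r} n={self.n} "
            f"R2={self.rsquared:.3f}>"
        )


def fit_gaussian_lm(data: pd.DataFrame, spec: ModelSpec, scale: bool = True
                    ) -> DiversityLMResults:
    """Convenience wrapper: build a :class:`DiversityLM` and fit it."""
    return DiversityLM(data, spec, scale=scale).fit()


# ---------------------------------------------------------------------------
# Correlations between community metrics
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with per-pair n and 0.01-level flags."""

    r: pd.DataFrame
    n: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # at the 0.01 level
    alpha: float = 0.01


def pearson_matrix(metrics: pd.DataFrame, alpha: float = 0.01,
                   min_pairs: int = 3) -> CorrelationReport:
    """Pairwise-complete Pearson correlations over a site x metric table.

    Significance uses the exact t transform t = r sqrt((n-2)/(1-r^2)) with
    df = n - 2.  Pairs with fewer than ``min_pairs`` joint observations get
    NaN (logged in the n matrix).
    """
    cols = list(metrics.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        n.loc[a, a] = metrics[a].notna().sum()
        for b in cols[i + 1:]:
            both = metrics[[a, b]].dropna()
            nn = len(both)
            n.loc[a, b] = n.loc[b, a] = nn
            if nn < min_pairs:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(both[a], both[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    sig = (p < alpha) & r.notna()
    np.fill_diagonal(sig.values, False)
    return CorrelationReport(r=r, n=n, p=p, significant=sig, alpha=alpha)


def critical_r(n: int, alpha: float = 0.01) -> float:
    """Smallest |r| significant at ``alpha`` for a sample of ``n`` pairs."""
    if n < 3:
        return float("nan")
    t = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t / np.sqrt(n - 2 + t**2))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def morans_i(values: np.ndarray, xy: np.ndarray,
             n_permutations: int = 999, seed: int = 0) -> tuple[float, float]:
    """Moran's I with inverse-distance weights and a permutation p-value.

    A numeric version of the usual graphical residual-map check for spatial
    autocorrelation.  Weights are 1/d between distinct locations (row
    standardised); the p-value is two-sided from ``n_permutations`` random
    relabellings.
    """
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    xy = np.asarray(xy, dtype=float)
    n = len(z)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w = w / w.sum(axis=1, keepdims=True)
    s0 = w.sum()
    denom = (z**2).sum()

    def stat(zz: np.ndarray) -> float:
        return float(n / s0 * (zz @ w @ zz) / (zz**2).sum()) if denom > 0 else 0.0

    i_obs = stat(z)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for b in range(n_permutations):
        perm[b] = stat(rng.permutation(z))
    p = (1 + np.sum(np.abs(perm - perm.mean()) >= abs(i_obs - perm.mean()))) / (
        n_permutations + 1
    )
    return i_obs, float(p)


def diagnostics(results: DiversityLMResults, site_xy: np.ndarray | None = None,
                n_permutations: int = 999, seed: int = 0) -> dict:
    """Model-adequacy report: influence, heteroscedasticity, spatial signal.

    Returns a dict with a residual-vs-fitted table, per-site Cook's
    distances (flagging > 4/n), a spread-vs-fitted slope statistic (slope of
    |resid| on fitted values with its p, a numeric funnel check) and, when
    site coordinates are supplied, Moran's I of the residuals with its
    permutation p.
    """
    res = results._res
    infl = res.get_influence()
    cooks = infl.cooks_distance[0]
    n = results.n
    tab = pd.DataFrame({
        "fitted": results.fittedvalues,
        "resid": results.resid,
        "cooks_d": cooks,
        "influential": cooks > 4.0 / n,
    })
    slope_fit = stats.linregress(results.fittedvalues, np.abs(results.resid))
    out = {
        "residuals": tab,
        "cooks_threshold": 4.0 / n,
        "spread_slope": float(slope_fit.slope),
        "spread_slope_p": float(slope_fit.pvalue),
    }
    if site_xy is not None:
        i_obs, p = morans_i(np.asarray(results.resid), site_xy,
                            n_permutations=n_permutations, seed=seed)
        out["morans_i"] = i_obs
        out["morans_i_p"] = p
    return out
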
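"""Binomial GEE modelling of narwhal acoustic presence.

The statistical protocol: Pearson screening of covariate pairs (|r| > 0.6),
GVIF-based stepwise collinearity removal (cutoff 3.0), cluster sizing from
the autocorrelation function of the presence series, binomial GEE with a
logit link fitted under an independence or AR(1) working correlation
(chosen by lowest QIC), cyclic day-of-year splines (4 df), cubic B-spline
smooth terms with no inner knots, a ship-presence x ship-proximity
interaction so bins without ships contribute a well-defined reference
level, backward elimination on per-term Wald tests (alpha = 0.05), marginal
R-squared, and parametric-bootstrap prediction curves.

Estimation is delegated to :class:`statsmodels` GEE; the design
construction, spline bases, QIC, Wald blocks, GVIF, and bootstrap logic
live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Autoregressive, Independence
from statsmodels.tsa.stattools import acf as sample_acf

log = logging.getLogger(__name__)

__all__ = [
    "Term",
    "GEEFit",
    "bspline_basis",
    "cyclic_spline_basis",
    "build_design",
    "pearson_screen",
    "gvif_stepwise",
    "acf_cluster_size",
    "fit_gee",
    "select_corstr",
    "backward_select",
    "bootstrap_curves",
    "marginal_r2",
]


# --------------------------------------------------------------------------
# spline bases and design construction
# --------------------------------------------------------------------------

def bspline_basis(x, df: int = 3, degree: int = 3, bounds=None) -> np.ndarray:
    """Cubic B-spline basis, first column dropped (absorbed by the intercept).

    With ``df == degree`` there are no interior knots — the third-degree
    polynomial smooth used for environmental covariates.  Columns are all
    zero at the left boundary, which anchors interaction terms at a
    well-defined reference.
    """
    x = np.asarray(x, dtype=float)
    if bounds is None:
        bounds = (float(np.min(x)), float(np.max(x)))
    a, b = bounds
    n_interior = df - degree
    if n_interior < 0:
        raise ValueError("df must be >= degree")
    interior = np.linspace(a, b, n_interior + 2)[1:-1]
    knots = np.concatenate([[a] * (degree + 1), interior, [b] * (degree + 1)])
    design = BSpline.design_matrix(
        np.clip(x, a, b), knots, degree, extrapolate=False
    ).toarray()
    return design[:, 1:]  # drop first basis function


def cyclic_spline_basis(x, df: int = 4, degree: int = 3, period: float = 366.0) -> np.ndarray:
    """Periodic cubic B-spline basis with ``df`` columns on [0, period].

    Built by folding an ordinary B-spline basis on wrap-around knots so every
    basis function (and any fitted curve) is smoothly periodic.  One basis
    function is dropped for identifiability with the intercept.
    """
    x = np.mod(np.asarray(x, dtype=float), period)
    nb = df + 1  # periodic functions before the identifiability drop
    knots = period * np.arange(-degree, nb + degree + 1) / nb
    full = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    folded = full[:, :nb].copy()
    folded[:, :degree] += full[:, nb : nb + degree]
    return folded[:, 1:]


@dataclass(frozen=True)
class Term:
    """One model term: a named block of design columns.

    kind: linear | categorical | bspline | cyclic | interaction.
    ``interaction`` multiplies a B-spline basis of ``var`` by the binary
    column ``with_var`` (the ship_present x rnv contract).
    """

    name: str
    var: str
    kind: str = "linear"
    df: int = 3
    degree: int = 3
    bounds: tuple[float, float] | None = None
    period: float = 366.0
    with_var: str | None = None

    def columns(self, frame: pd.DataFrame, levels=None) -> tuple[np.ndarray, list[str]]:
        x = frame[self.var]
        if self.kind == "linear":
            return np.asarray(x, dtype=float)[:, None], [self.var]
        if self.kind == "categorical":
            cats = levels if levels is not None else sorted(pd.unique(x))
            cols = [(np.asarray(x) == c).astype(float) for c in cats[1:]]
            names = [f"{self.var}[{c}]" for c in cats[1:]]
            return (np.column_stack(cols) if cols else np.empty((len(frame), 0))), names
        if self.kind == "bspline":
            b = bspline_basis(x, self.df, self.degree, self.bounds)
            return b, [f"bs({self.var})[{j}]" for j in range(b.shape[1])]
        if self.kind == "cyclic":
            b = cyclic_spline_basis(x, self.df, self.degree, self.period)
            return b, [f"cc({self.var})[{j}]" for j in range(b.shape[1])]
        if self.kind == "interaction":
            b = bspline_basis(x, self.df, self.degree, self.bounds)
            w = np.asarray(frame[self.with_var], dtype=float)[:, None]
            return b * w, [
                f"{self.with_var}:bs({self.var})[{j}]" for j in range(b.shape[1])
            ]
        raise ValueError(f"unknown term kind {self.kind!r}")


@dataclass
class DesignInfo:
    terms: tuple[Term, ...]
    colnames: list[str]
    slices: dict[str, slice]
    cat_levels: dict[str, list]

    def build(self, frame: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(frame), 1))]
        for t in self.terms:
            x, _ = t.columns(frame, self.cat_levels.get(t.name))
            blocks.append(x)
        return np.hstack(blocks)


def build_design(frame: pd.DataFrame, terms) -> tuple[np.ndarray, DesignInfo]:
    """Assemble the intercept-plus-term-blocks design matrix."""
    terms = tuple(terms)
    blocks = [np.ones((len(frame), 1))]
    names = ["Intercept"]
    slices: dict[str, slice] = {}
    cat_levels: dict[str, list] = {}
    # freeze bounds and category levels from the training frame
    frozen = []
    for t in terms:
        if t.kind in ("bspline", "interaction") and t.bounds is None:
            t = replace(
                t, bounds=(float(frame[t.var].min()), float(frame[t.var].max()))
            )
        if t.kind == "categorical":
            cat_levels[t.name] = sorted(pd.unique(frame[t.var]))
        frozen.append(t)
    terms = tuple(frozen)
    for t in terms:
        x, cn = t.columns(frame, cat_levels.get(t.name))
        slices[t.name] = slice(len(names), len(names) + x.shape[1])
        blocks.append(x)
        names.extend(cn)
    X = np.hstack(blocks)
    return X, DesignInfo(terms, names, slices, cat_levels)


# --------------------------------------------------------------------------
# collinearity screening
# --------------------------------------------------------------------------

def pearson_screen(frame: pd.DataFrame, columns=None, threshold: float = 0.6):
    """Pairwise Pearson correlations with |r| > threshold flagged.

    Constant columns (undefined r) are flagged separately.
    """
    cols = list(columns) if columns is not None else [
        c for c in frame.columns if np.issubdtype(frame[c].dtype, np.number)
    ]
    constant = [c for c in cols if frame[c].nunique() <= 1]
    use = [c for c in cols if c not in constant]
    corr = frame[use].corr(method="pearson")
    flagged = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(use)
        for b in use[i + 1 :]
        if abs(corr.loc[a, b]) > threshold
    ]
    return corr, flagged, constant


def _gvif(X_blocks: dict[str, np.ndarray]) -> dict[str, tuple[float, float]]:
    """Generalized VIF per term block via the correlation-determinant formula.

    GVIF_j = det(R_jj) det(R_not_j) / det(R); the df-normalized statistic is
    GVIF^(1/(2 df_j)).
    """
    names = list(X_blocks)
    X = np.hstack([X_blocks[n] for n in names])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant design column in GVIF computation")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    idx = {}
    k = 0
    for n in names:
        d = X_blocks[n].shape[1]
        idx[n] = np.arange(k, k + d)
        k += d
    det_R = np.linalg.det(R)
    out = {}
    for n in names:
        j = idx[n]
        other = np.setdiff1d(np.arange(k), j)
        det_jj = np.linalg.det(R[np.ix_(j, j)])
        det_oo = np.linalg.det(R[np.ix_(other, other)]) if len(other) else 1.0
        gvif = det_jj * det_oo / det_R
        out[n] = (float(gvif), float(gvif ** (1.0 / (2.0 * len(j)))))
    return out


def gvif_stepwise(frame: pd.DataFrame, terms, cutoff: float = 3.0):
    """Iteratively remove the worst collinear term until all pass the cutoff.

    The per-term statistic is GVIF^(1/(2 df)); the term with the largest
    statistic exceeding ``cutoff`` is removed each round (alphabetical
    tie-break, and a deterministic alphabetical removal when the design is
    exactly singular).  Returns (retained_terms, removal_log).
    """
    terms = list(terms)
    if len(terms) < 2:
        return terms, []
    removal_log = []
    while len(terms) > 1:
        blocks = {}
        for t in terms:
            x, _ = t.columns(frame, None if t.kind != "categorical" else sorted(pd.unique(frame[t.var])))
            blocks[t.name] = x
        try:
            stats = _gvif(blocks)
        except np.linalg.LinAlgError:
            stats = None
        if stats is None or not np.isfinite([v[0] for v in stats.values()]).all() or min(
            abs(v[0]) for v in stats.values()
        ) == np.inf:
            victim = sorted(t.name for t in terms)[0]
            removal_log.append({"term": victim, "gvif": np.inf, "stat": np.inf})
            terms = [t for t in terms if t.name != victim]
            continue
        exceed = {
            n: v for n, v in stats.items() if (not np.isfinite(v[1])) or v[1] > cutoff
        }
        if not exceed:
            break
        victim = sorted(
            exceed, key=lambda n: (-(exceed[n][1] if np.isfinite(exceed[n][1]) else np.inf), n)
        )[0]
        removal_log.append(
            {"term": victim, "gvif": exceed[victim][0], "stat": exceed[victim][1]}
        )
        terms = [t for t in terms if t.name != victim]
    return terms, removal_log


# --------------------------------------------------------------------------
# cluster sizing from the ACF
# --------------------------------------------------------------------------

def acf_cluster_size(series, sustain: int = 10, max_frac: float = 0.1):
    """Decorrelation length of a presence series, in bins, from its ACF.

    L is the smallest lag at which the sample autocorrelation enters the
    +/-1.96/sqrt(n) white-noise band and stays inside for ``sustain``
    consecutive lags.  Cluster ids are consecutive non-overlapping blocks of
    length L.  If the ACF never decays, L is capped at n * max_frac with a
    warning.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    cap = max(1, int(n * max_frac))
    if np.std(y) == 0:
        warnings.warn("constant series: ACF undefined, cluster size capped")
        return cap, np.arange(n) // cap
    nlags = min(n - 1, cap + sustain + 1)
    r = sample_acf(y, nlags=nlags, fft=True)
    band = 1.96 / np.sqrt(n)
    inside = np.abs(r[1:]) < band  # lag 1..nlags
    L = None
    for lag in range(1, len(inside) - sustain + 2):
        if inside[lag - 1 : lag - 1 + sustain].all():
            L = lag
            break
    if L is None:
        warnings.warn("ACF never decays into the white-noise band; capping L")
        L = cap
    return L, np.arange(n) // L


# --------------------------------------------------------------------------
# GEE fitting
# --------------------------------------------------------------------------

@dataclass
class GEEFit:
    coef: pd.Series
    robust_cov: pd.DataFrame
    wald: pd.DataFrame
    qic: float
    corstr: str
    marginal_r2: float
    info: DesignInfo = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)
    converged: bool = True


def _quasi_loglik_binom(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _qic(y, mu, X, robust_cov) -> float:
    """QIC = -2 Q(mu) + 2 tr(Omega_I V_robust), binomial quasi-likelihood."""
    w = mu * (1 - mu)
    a_i = (X * w[:, None]).T @ X
    return -2.0 * _quasi_loglik_binom(y, mu) + 2.0 * float(np.trace(a_i @ robust_cov))


def _wald_table(params, cov, info: DesignInfo) -> pd.DataFrame:
    rows = []
    for t in info.terms:
        s = info.slices[t.name]
        b = params[s]
        V = cov[s, s]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        df_t = len(b)
        rows.append(
            {
                "term": t.name,
                "chi2": stat,
                "df": df_t,
                "p": float(chi2_dist.sf(stat, df_t)) if np.isfinite(stat) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def marginal_r2(fitted: np.ndarray, response: np.ndarray) -> float:
    """Squared Pearson correlation of fitted probabilities with the response.

    Constant fitted values give an undefined correlation, coerced to 0 with
    a warning.
    """
    if np.std(fitted) == 0 or np.std(response) == 0:
        warnings.warn("constant fitted values or response: marginal R2 set to 0")
        return 0.0
    return float(np.corrcoef(fitted, response)[0, 1] ** 2)


def fit_gee(
    frame: pd.DataFrame,
    terms,
    corstr: str = "independence",
    response: str = "present",
    groups: str = "cluster_id",
) -> GEEFit:
    """Fit a binomial logit GEE with the requested working correlation.

    Robust (sandwich) covariance throughout; per-term Wald blocks test whole
    spline blocks; QIC is computed from the independence quasi-likelihood
    plus the trace penalty so values are comparable across working
    structures.
    """
    y = np.asarray(frame[response], dtype=float)
    X, info = build_design(frame, terms)
    cov_struct = {"independence": Independence, "ar1": lambda: Autoregressive(grid=True)}[
        corstr
    ]()
    model = sm.GEE(
        y,
        X,
        groups=np.asarray(frame[groups]),
        family=sm.families.Binomial(),
        cov_struct=cov_struct,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    mu = np.asarray(res.fittedvalues)
    fit = GEEFit(
        coef=pd.Series(params, index=info.colnames),
        robust_cov=pd.DataFrame(cov, index=info.colnames, columns=info.colnames),
        wald=_wald_table(params, cov, info),
        qic=_qic(y, mu, X, cov),
        corstr=corstr,
        marginal_r2=marginal_r2(mu, y),
        info=info,
        fitted=mu,
        response=y,
        converged=bool(getattr(res, "converged", True)),
    )
    if not fit.converged:
        raise RuntimeError("GEE did not converge within 100 iterations")
    return fit


def select_corstr(frame, terms, response="present", groups="cluster_id", tie_tol=0.01):
    """Fit independence and AR(1) working structures; keep the lower QIC.

    QIC values within ``tie_tol`` of each other count as identical and the
    tie goes to independence (the simpler structure); on a QIC of order
    10^3-10^4 a difference below 0.01 is numerical noise, not evidence.
    Returns (chosen_name, chosen_fit, {name: qic}).
    """
    fits = {}
    for name in ("independence", "ar1"):
        fits[name] = fit_gee(frame, terms, corstr=name, response=response, groups=groups)
    qics = {k: f.qic for k, f in fits.items()}
    chosen = "independence" if qics["independence"] <= qics["ar1"] + tie_tol else "ar1"
    log.info("QIC: independence=%.2f ar1=%.2f -> %s", qics["independence"], qics["ar1"], chosen)
    return chosen, fits[chosen], qics


def backward_select(
    frame, terms, alpha: float = 0.05, corstr: str = "independence",
    response: str = "present", groups: str = "cluster_id",
):
    """Backward elimination on per-term Wald tests.

    Each round drops the term with the largest p-value above ``alpha`` and
    refits, stopping when every remaining term is significant.  A main
    effect is never dropped while an interaction referencing it remains.
    A term at exactly p = alpha is retained.  If every term is dropped the
    intercept-only fit is returned with a note in the log.
    """
    terms = list(terms)
    drop_log = []
    while True:
        fit = fit_gee(frame, terms, corstr=corstr, response=response, groups=groups)
        protected = {
            t.with_var for t in terms if t.kind == "interaction" and t.with_var
        }
        droppable = fit.wald[
            ~fit.wald["term"].isin(
                {t.name for t in terms if t.kind == "linear" and t.var in protected}
            )
        ]
        worst = droppable.sort_values("p", ascending=False).iloc[0] if len(droppable) else None
        if worst is None or not (worst["p"] > alpha):
            return fit, terms, drop_log
        drop_log.append({"term": worst["term"], "p": float(worst["p"])})
        terms = [t for t in terms if t.name != worst["term"]]
        if not terms:
            log.warning("all terms dropped; returning intercept-only model")
            fit = fit_gee(frame, [], corstr=corstr, response=response, groups=groups)
            return fit, terms, drop_log


# --------------------------------------------------------------------------
# bootstrap prediction curves
# --------------------------------------------------------------------------

def _nearest_psd(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((a + a.T) / 2.0)
    if vals.min() >= 0:
        return a
    warnings.warn("covariance not PSD; clipping negative eigenvalues")
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def bootstrap_curves(
    fit: GEEFit,
    var: str,
    grid,
    reference: dict,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Parametric-bootstrap prediction curve with 95% CI over a predictor grid.

    Coefficient vectors are drawn from N(coef, robust_cov); the response
    probability is predicted over ``grid`` for ``var`` with every other
    covariate held at its value in ``reference``; the CI is the pointwise
    2.5/97.5 percentile band.  Same seed, same curves.
    """
    grid = np.asarray(grid, dtype=float)
    pred_frame = pd.DataFrame({var: grid})
    for k, v in reference.items():
        if k != var:
            pred_frame[k] = v
    for t in fit.info.terms:
        for v in filter(None, (t.var, t.with_var)):
            if v not in pred_frame.columns:
                if t.kind == "categorical":
                    pred_frame[v] = fit.info.cat_levels[t.name][0]
                else:
                    raise KeyError(
                        f"reference values must set {v!r} for prediction"
                    )
    X = fit.info.build(pred_frame)
    rng = np.random.default_rng(seed)
    cov = _nearest_psd(fit.robust_cov.to_numpy())
    draws = rng.multivariate_normal(fit.coef.to_numpy(), cov, size=n_boot, method="svd")
    probs = expit(draws @ X.T)  # (n_boot, len(grid))
    return pd.DataFrame(
        {
            "grid": grid,
            "fit": expit(X @ fit.coef.to_numpy()),
            "lo95": np.percentile(probs, 2.5, axis=0),
            "hi95": np.percentile(probs, 97.5, axis=0),
        }
    )
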
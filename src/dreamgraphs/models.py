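"""Weighted linear models over per-dreamer average graph attributes.

Two analyses are supported, both fitted by weighted least squares with
per-dreamer weights w = ln(n_dreams + 1) so prolific dreamers inform the fit
without dominating it:

* condition comparison — attribute ~ condition, an omnibus F test on the
  condition factor plus all pairwise contrasts;
* attribute association — response ~ covariate × condition (full
  interaction model), the condition×covariate interaction F test plus the
  fitted slope of each condition.

The factor uses treatment (dummy) coding with NN — the non-lucid control
condition — as the reference level whenever it is present. F tests use
Type II sums of squares by default: each term is tested by comparing the
model without it against the model with it, never retaining an interaction
while testing its own main effect. Pairwise contrast P values are reported
unadjusted by default (Bonferroni/Holm available via configuration), and
contrasts are evaluated at the weighted grand mean of the covariate when
one is present. All P values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .aggregate import DreamerAverage


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows.copy()
    return pd.DataFrame([r.as_dict() if isinstance(r, DreamerAverage) else dict(r)
                         for r in rows])


def _order_levels(levels) -> list[str]:
    """Reference level first: NN when present, else lexicographic head."""
    levels = sorted(set(levels))
    if "NN" in levels:
        levels.remove("NN")
        levels = ["NN"] + levels
    return levels


@dataclass
class ModelFit:
    """A fitted weighted linear model plus everything needed to re-test it."""

    response: str
    covariate: str | None
    levels: list[str]                     # reference first
    param_names: list[str]
    params: np.ndarray
    cov_params: np.ndarray
    wrss: float
    df_resid: int
    weights: np.ndarray
    # raw data kept for nested refits (Type II / III F tests)
    y: np.ndarray = field(repr=False, default=None)
    factor_values: np.ndarray = field(repr=False, default=None)
    covariate_values: np.ndarray | None = field(repr=False, default=None)

    @property
    def reference(self) -> str:
        return self.levels[0]

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])


@dataclass
class ComparisonResult:
    attribute: str
    F: float
    df_num: int
    df_den: int
    P: float
    contrasts: list[tuple[tuple[str, str], float, float, float]]
    group_means: dict[str, float]
    fit: ModelFit = field(repr=False, default=None)


@dataclass
class AssociationResult:
    response: str
    covariate: str
    F: float
    df_num: int
    df_den: int
    P: float
    slopes: list[tuple[str, float, float, int, float]]
    fit: ModelFit = field(repr=False, default=None)


def _design(factor: np.ndarray, covariate: np.ndarray | None,
            levels: list[str],
            include: tuple[bool, bool, bool]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with treatment coding.

    ``include`` toggles (factor dummies, covariate, interaction)."""
    n = len(factor)
    cols = [np.ones(n)]
    names = ["Intercept"]
    inc_factor, inc_cov, inc_inter = include
    dummies = {}
    for lev in levels[1:]:
        dummies[lev] = (factor == lev).astype(float)
    if inc_factor:
        for lev in levels[1:]:
            cols.append(dummies[lev])
            names.append(f"C[{lev}]")
    if inc_cov:
        cols.append(covariate)
        names.append("x")
    if inc_inter:
        for lev in levels[1:]:
            cols.append(dummies[lev] * covariate)
            names.append(f"C[{lev}]:x")
    return np.column_stack(cols), names


def _wls(y, X, w, names):
    rank = np.linalg.matrix_rank(X * np.sqrt(w)[:, None])
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design (rank {rank} < "
                         f"{X.shape[1]} columns: {names})")
    res = sm.WLS(y, X, weights=w).fit()
    return res


def fit_weighted_lm(rows, response: str, covariate: str | None = None,
                    factor: str = "condition",
                    weights: str | np.ndarray = "weight") -> ModelFit:
    """Fit response ~ factor [+ covariate + factor:covariate] by WLS.

    With a covariate present the design is the full interaction model:
    intercept, factor dummies, covariate, and factor×covariate terms.
    """
    df = _as_frame(rows)
    y = df[response].to_numpy(dtype=float)
    fac = df[factor].to_numpy(dtype=str)
    w = (df[weights].to_numpy(dtype=float) if isinstance(weights, str)
         else np.asarray(weights, dtype=float))
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    levels = _order_levels(fac)
    counts = pd.Series(fac).value_counts()
    if len(levels) > 1 and (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"factor level(s) with < 2 rows: {bad}")
    cov = df[covariate].to_numpy(dtype=float) if covariate else None
    multi = len(levels) > 1
    X, names = _design(fac, cov, levels,
                       include=(multi, covariate is not None,
                                multi and covariate is not None))
    if len(y) < X.shape[1]:
        raise ValueError(f"need at least {X.shape[1]} rows, got {len(y)}")
    res = _wls(y, X, w, names)
    return ModelFit(response=response, covariate=covariate, levels=levels,
                    param_names=names, params=np.asarray(res.params),
                    cov_params=np.asarray(res.cov_params()),
                    wrss=float(res.ssr), df_resid=int(res.df_resid),
                    weights=w, y=y, factor_values=fac, covariate_values=cov)


def _nested_f(fit: ModelFit, reduced_include, full_include):
    """F test comparing two nested designs refit on the stored data."""
    Xr, nr = _design(fit.factor_values, fit.covariate_values, fit.levels,
                     reduced_include)
    Xf, nf = _design(fit.factor_values, fit.covariate_values, fit.levels,
                     full_include)
    rr = _wls(fit.y, Xr, fit.weights, nr)
    rf = _wls(fit.y, Xf, fit.weights, nf)
    df_num = Xf.shape[1] - Xr.shape[1]
    df_den = int(rf.df_resid)
    F = ((rr.ssr - rf.ssr) / df_num) / (rf.ssr / df_den)
    P = float(stats.f.sf(F, df_num, df_den))
    return float(F), df_num, df_den, P


def anova_term_test(fit: ModelFit, term: str,
                    ss_type: str = "II") -> tuple[float, int, int, float]:
    """Type II (default) or III F test for one term of the fitted model.

    ``term`` is one of ``factor``, ``covariate``, ``interaction``. Type II
    respects marginality: a main effect is tested with its interaction
    absent from both models.
    """
    has_cov = fit.covariate is not None
    multi = len(fit.levels) > 1
    if term == "factor" and not multi:
        raise ValueError("cannot test the factor in a single-level design")
    if term == "covariate" and not has_cov:
        raise ValueError("no covariate in this model")
    if term == "interaction" and not (has_cov and multi):
        raise ValueError("no interaction term in this model")
    if ss_type not in ("II", "III"):
        raise ValueError(f"unknown sums-of-squares type {ss_type!r}")

    if term == "interaction":
        return _nested_f(fit, (True, True, False), (True, True, True))
    if ss_type == "II":
        if term == "factor":
            return _nested_f(fit, (False, has_cov, False),
                             (True, has_cov, False))
        # covariate
        return _nested_f(fit, (multi, False, False), (multi, True, False))
    # Type III: drop the term's columns from the otherwise full model.
    full = (multi, has_cov, multi and has_cov)
    if term == "factor":
        reduced = (False, has_cov, multi and has_cov)
    else:
        reduced = (multi, False, multi and has_cov)
    return _nested_f(fit, reduced, full)


def _contrast_test(fit: ModelFit, c: np.ndarray):
    est = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov_params @ c))
    t = est / se
    p = 2.0 * float(stats.t.sf(abs(t), fit.df_resid))
    return est, t, p


def _adjust(pvals: list[float], method: str) -> list[float]:
    m = len(pvals)
    if method == "none" or m == 0:
        return pvals
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    if method == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        return adj.tolist()
    raise ValueError(f"unknown adjustment {method!r}")


def pairwise_contrasts(fit: ModelFit, p_adjust: str = "none"
                       ) -> list[tuple[tuple[str, str], float, float, float]]:
    """All pairwise differences of adjusted condition means.

    With a covariate present, means are evaluated at its weighted grand
    mean (where the interaction contributes). t uses the model's residual
    variance; df = residual df.
    """
    if len(fit.levels) < 2:
        raise ValueError("pairwise contrasts need >= 2 factor levels")
    xbar = (float(np.average(fit.covariate_values, weights=fit.weights))
            if fit.covariate is not None else None)
    k = len(fit.param_names)

    def mean_vec(level: str) -> np.ndarray:
        c = np.zeros(k)
        c[fit.param_names.index("Intercept")] = 1.0
        if level != fit.reference:
            c[fit.param_names.index(f"C[{level}]")] = 1.0
        if xbar is not None:
            c[fit.param_names.index("x")] = xbar
            if level != fit.reference:
                c[fit.param_names.index(f"C[{level}]:x")] = xbar
        return c

    out = []
    raw_ps = []
    for a, b in combinations(fit.levels, 2):
        est, t, p = _contrast_test(fit, mean_vec(b) - mean_vec(a))
        out.append([(a, b), est, t, p])
        raw_ps.append(p)
    for row, p in zip(out, _adjust(raw_ps, p_adjust)):
        row[3] = p
    return [tuple(r) for r in out]


def group_slopes(fit: ModelFit) -> list[tuple[str, float, float, int, float]]:
    """Per-condition slope of the covariate: the covariate coefficient plus
    that condition's interaction coefficient (zero for the reference)."""
    if fit.covariate is None:
        raise ValueError("model has no covariate, so no slopes")
    k = len(fit.param_names)
    out = []
    for lev in fit.levels:
        c = np.zeros(k)
        c[fit.param_names.index("x")] = 1.0
        name = f"C[{lev}]:x"
        if lev != fit.reference and name in fit.param_names:
            c[fit.param_names.index(name)] = 1.0
        est, t, p = _contrast_test(fit, c)
        out.append((lev, est, t, fit.df_resid, p))
    return out


def compare_attribute(cohort, attribute: str, conditions=None,
                      ss_type: str = "II",
                      p_adjust: str = "none") -> ComparisonResult:
    """Omnibus condition comparison of one attribute plus pairwise contrasts."""
    df = _as_frame(cohort)
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    if df["condition"].nunique() < 2:
        raise ValueError("need >= 2 conditions to compare")
    fit = fit_weighted_lm(df, response=attribute)
    F, dfn, dfd, P = anova_term_test(fit, "factor", ss_type=ss_type)
    contrasts = pairwise_contrasts(fit, p_adjust=p_adjust)
    gm = {lev: float(np.average(df.loc[df.condition == lev, attribute],
                                weights=df.loc[df.condition == lev, "weight"]))
          for lev in fit.levels}
    return ComparisonResult(attribute=attribute, F=F, df_num=dfn, df_den=dfd,
                            P=P, contrasts=contrasts, group_means=gm, fit=fit)


def associate_attributes(cohort, response: str, covariate: str,
                         conditions=None,
                         ss_type: str = "II") -> AssociationResult:
    """Full interaction model of one attribute pair across conditions.

    With a single condition present the model reduces to a simple weighted
    regression; the interaction F is then undefined (NaN) and one slope is
    returned.
    """
    df = _as_frame(cohort)
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    fit = fit_weighted_lm(df, response=response, covariate=covariate)
    if len(fit.levels) > 1:
        F, dfn, dfd, P = anova_term_test(fit, "interaction", ss_type=ss_type)
    else:
        F, dfn, dfd, P = float("nan"), 0, fit.df_resid, float("nan")
    return AssociationResult(response=response, covariate=covariate,
                             F=F, df_num=dfn, df_den=dfd, P=P,
                             slopes=group_slopes(fit), fit=fit)
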
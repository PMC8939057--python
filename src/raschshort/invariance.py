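"""Measurement invariance: Smith's unidimensionality test and DIF analysis.

Smith's test extracts the first principal component of the standardized
residual correlations, splits items into positively and negatively loading
subsets, re-estimates each person on both subsets with anchored item
parameters, and counts per-person t-tests outside +/-1.96.  The scale is
judged unidimensional when the exact binomial 95% confidence interval of
that percentage reaches below 5%.

DIF is tested per item by two-way ANOVA of standardized residuals on a
person factor and the class intervals along the trait: the factor main
effect is uniform DIF, the interaction non-uniform DIF.  Apparent DIF in
other items can be an artifact of one truly DIF item; splitting that item
into group-specific virtual items and re-testing resolves real from
artificial DIF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import diagnostics as dg
from .pcm import (
    ConvergenceError,
    ItemParameters,
    NullCategoryError,
    PersonEstimates,
    ResponseMatrix,
    estimate_persons,
    fit_items_cml,
    score_to_theta,
)

__all__ = [
    "SmithResult",
    "DIFTable",
    "DIFResolution",
    "smith_unidimensionality",
    "dif_anova",
    "resolve_artificial_dif",
    "median_split",
]


def median_split(age: pd.Series) -> pd.Series:
    """Dichotomise age at the sample median; ties go to the lower group."""
    med = float(age.median())
    return pd.Series(
        np.where(age <= med, "younger", "older"), index=age.index, name="age_group"
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion, as percentages."""
    if n == 0:
        return (0.0, 100.0)
    a = (1.0 - level) / 2.0
    lo = stats.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1.0 - a, k + 1, n - k) if k < n else 1.0
    return (100.0 * float(lo), 100.0 * float(hi))


# ---------------------------------------------------------------------------
# Smith's test
# ---------------------------------------------------------------------------


@dataclass
class SmithResult:
    loadings: pd.Series
    positive_items: list[str]
    negative_items: list[str]
    t_values: pd.Series
    n_tested: int
    pct_significant: float
    ci: tuple[float, float]
    unidimensional: bool


def _pc1_loadings(z: pd.DataFrame) -> pd.Series:
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    v = vecs[:, -1]
    nz = np.nonzero(np.abs(v) > 1e-12)[0]
    if nz.size and v[nz[0]] < 0:  # deterministic sign
        v = -v
    return pd.Series(v, index=z.columns, name="pc1_loading")


def smith_unidimensionality(
    responses: ResponseMatrix,
    items: ItemParameters,
    persons: PersonEstimates,
    *,
    loading_tol: float = 0.05,
    extreme_adjust: float = 0.3,
) -> SmithResult:
    """Smith's test of unidimensionality.

    Subset person estimates use the item parameters anchored from the full
    fit, so both estimates live on one metric; persons extreme on either
    subset are excluded from the t-tests.
    """
    z = dg.standardized_residuals(responses, items, persons)
    loadings = _pc1_loadings(z)
    pos = [i for i in loadings.index if loadings[i] >= loading_tol]
    neg = [i for i in loadings.index if loadings[i] <= -loading_tol]
    if not pos or not neg:
        raise ValueError(
            "all PC1 loadings share one sign: no subset split is possible"
        )

    theta_se = {}
    for name, subset in (("A", pos), ("B", neg)):
        sub_items = items.subset(subset)
        table = score_to_theta(sub_items, extreme_adjust=extreme_adjust)
        totals = responses.scores.loc[z.index, subset].sum(axis=1)
        est = table.loc[totals.to_numpy()].set_index(totals.index)
        theta_se[name] = est

    ok = ~(theta_se["A"]["extreme"] | theta_se["B"]["extreme"])
    a, b = theta_se["A"][ok], theta_se["B"][ok]
    t = (a["theta"] - b["theta"]) / np.sqrt(a["se"] ** 2 + b["se"] ** 2)
    n = int(ok.sum())
    k = int((t.abs() > 1.96).sum())
    pct = 100.0 * k / n if n else 0.0
    ci = clopper_pearson(k, n)
    return SmithResult(
        loadings=loadings,
        positive_items=pos,
        negative_items=neg,
        t_values=t,
        n_tested=n,
        pct_significant=pct,
        ci=ci,
        unidimensional=ci[0] < 5.0,
    )


# ---------------------------------------------------------------------------
# DIF ANOVA
# ---------------------------------------------------------------------------


@dataclass
class DIFTable:
    """Per item x factor DIF tests.

    ``table`` columns: item, factor, uniform_F, uniform_p, nonuniform_F,
    nonuniform_p, uniform_flag, nonuniform_flag.  Flags are Bonferroni
    comparisons at ``alpha / (n_items * n_factors)``.
    """

    table: pd.DataFrame
    alpha: float
    n_tests: int

    def flagged(self) -> pd.DataFrame:
        t = self.table
        return t[t["uniform_flag"] | t["nonuniform_flag"]]

    def max_uniform(self) -> pd.Series | None:
        fl = self.table[self.table["uniform_flag"]]
        if fl.empty:
            return None
        return fl.loc[fl["uniform_F"].idxmax()]


def _anova_two_way(z_col: np.ndarray, fac: np.ndarray, ci: np.ndarray):
    """Type-II two-way fixed-effects ANOVA of residuals on a person factor
    and class interval; returns (F_main, p_main, F_int, p_int)."""
    df = pd.DataFrame({"z": z_col, "g": fac, "ci": ci})
    if np.allclose(z_col.var(), 0.0):
        warnings.warn("degenerate residuals (zero variance): reporting no DIF")
        return 0.0, 1.0, 0.0, 1.0
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("z ~ C(g) * C(ci)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = sm.stats.anova_lm(model, typ=2)
    f_main = float(aov.loc["C(g)", "F"])
    p_main = float(aov.loc["C(g)", "PR(>F)"])
    f_int = float(aov.loc["C(g):C(ci)", "F"])
    p_int = float(aov.loc["C(g):C(ci)", "PR(>F)"])
    if not np.isfinite(f_main):
        f_main, p_main = 0.0, 1.0
    if not np.isfinite(f_int):
        f_int, p_int = 0.0, 1.0
    return f_main, p_main, f_int, p_int


def dif_anova(
    z: pd.DataFrame,
    person_factors: pd.DataFrame,
    class_interval: pd.Series,
    factors: list[str] | None = None,
    alpha: float = 0.01,
) -> DIFTable:
    """ANOVA-on-residuals DIF screen for every item x factor combination.

    ``class_interval`` must be aligned with the rows of ``z`` (extreme
    persons already excluded).  Class intervals empty within a factor level
    are tolerated by the fixed-effects fit; a factor with fewer than two
    observed levels is an error.
    """
    factors = factors or [c for c in person_factors.columns if c != "age"]
    rows = []
    ci = class_interval.loc[z.index].to_numpy()
    n_tests = len(z.columns) * len(factors)
    for fac_name in factors:
        fac = person_factors.loc[z.index, fac_name].astype(str).to_numpy()
        if len(np.unique(fac)) < 2:
            raise ValueError(f"factor {fac_name!r} has fewer than two levels")
        for item in z.columns:
            f_main, p_main, f_int, p_int = _anova_two_way(
                z[item].to_numpy(), fac, ci
            )
            rows.append(
                {
                    "item": item,
                    "factor": fac_name,
                    "uniform_F": f_main,
                    "uniform_p": p_main,
                    "nonuniform_F": f_int,
                    "nonuniform_p": p_int,
                }
            )
    table = pd.DataFrame(rows)
    thr = alpha / n_tests
    table["uniform_flag"] = table["uniform_p"] < thr
    table["nonuniform_flag"] = table["nonuniform_p"] < thr
    return DIFTable(table=table, alpha=alpha, n_tests=n_tests)


# ---------------------------------------------------------------------------
# artificial-DIF resolution
# ---------------------------------------------------------------------------


def _fit_item_anchored(
    responses: ResponseMatrix, items: ItemParameters, item: str
) -> tuple[np.ndarray, np.ndarray]:
    """Re-estimate one item's thresholds by CML with all other items
    anchored; returns (beta, se)."""
    from .pcm import _cml_grad_hess, _cml_loglik, _unflatten

    idx = items.index_of(item)
    X = responses.scores[items.item_ids].to_numpy()
    m = items.m
    counts = np.bincount(X[:, idx], minlength=m[idx] + 1)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise NullCategoryError(
            f"group split leaves item {item} with null category {int(empty[0])}; "
            f"collapse categories before resolving DIF"
        )
    totals = X.sum(axis=1)
    R = int(m.sum())
    n_r = np.bincount(totals, minlength=R + 1).astype(float)
    S_list = [
        np.array([(X[:, i] >= k).sum() for k in range(1, m[i] + 1)], dtype=float)
        for i in range(len(m))
    ]
    beta_list = [b.copy() for b in items.beta]
    sl = slice(int(m[:idx].sum()), int(m[: idx + 1].sum()))
    ll = _cml_loglik(beta_list, S_list, n_r)
    for _ in range(200):
        grad, H = _cml_grad_hess(beta_list, S_list, n_r)
        g = grad[sl]
        if np.abs(g).max() < 1e-8:
            break
        Hb = H[sl, sl]
        step = np.linalg.solve(Hb, -g)
        t = 1.0
        for _ in range(40):
            trial = [b.copy() for b in beta_list]
            trial[idx] = beta_list[idx] + t * step
            ll_new = _cml_loglik(trial, S_list, n_r)
            if ll_new > ll - 1e-10 * max(1.0, abs(ll)):
                break
            t /= 2.0
        beta_list, ll = trial, ll_new
    else:
        raise ConvergenceError(f"anchored refit of item {item} did not converge")
    _, H = _cml_grad_hess(beta_list, S_list, n_r)
    cov = np.linalg.pinv(-H[sl, sl], hermitian=True)
    return beta_list[idx], np.sqrt(np.clip(np.diag(cov), 0.0, None))


@dataclass
class DIFResolution:
    split_item: str
    factor: str
    group_locations: dict[str, float]
    group_location_ses: dict[str, float]
    difference: float
    difference_p: float
    vanished: list[tuple[str, str]]  # (item, factor) flags gone after split
    remaining: list[tuple[str, str]]
    dif_after: DIFTable


def resolve_artificial_dif(
    responses: ResponseMatrix,
    items: ItemParameters,
    persons: PersonEstimates,
    dif_table: DIFTable,
    *,
    factors: list[str] | None = None,
    person_factors: pd.DataFrame | None = None,
    n_class_intervals: int | None = None,
) -> DIFResolution | None:
    """Split the item with the highest flagged uniform-DIF F statistic into
    group-specific virtual items and re-test the remaining items.

    Returns None when nothing is flagged (resolution is idempotent).  The
    split is realised by re-estimating the item's thresholds separately per
    factor level with every other item anchored at the joint fit, so the
    group-specific locations are on the common metric; their difference is
    tested with a normal z-test from the CML standard errors.
    """
    top = dif_table.max_uniform()
    if top is None:
        return None
    item, factor = str(top["item"]), str(top["factor"])
    pf = person_factors if person_factors is not None else responses.person_factors
    levels = pf[factor].astype(str)

    group_beta, group_loc, group_se = {}, {}, {}
    for lev in sorted(levels.unique()):
        sub = responses.subset_persons(levels.index[levels == lev])
        beta, se = _fit_item_anchored(sub, items, item)
        group_beta[lev] = beta
        group_loc[lev] = float(beta.mean())
        group_se[lev] = float(np.sqrt((se**2).sum()) / se.size)

    levs = sorted(group_loc)
    diff = group_loc[levs[0]] - group_loc[levs[1]]
    se_diff = float(np.sqrt(group_se[levs[0]] ** 2 + group_se[levs[1]] ** 2))
    p = float(2.0 * stats.norm.sf(abs(diff) / se_diff)) if se_diff > 0 else np.nan

    # residuals with group-specific parameters for the split item
    z = dg.standardized_residuals(responses, items, persons)
    from .pcm import expected_score_and_variance

    theta = persons.persons.loc[z.index, "theta"]
    x_col = responses.scores.loc[z.index, item]
    z_new = z.copy()
    for lev, beta in group_beta.items():
        sel = z.index[levels.loc[z.index] == lev]
        ew = np.array([expected_score_and_variance(t, beta) for t in theta.loc[sel]])
        z_new.loc[sel, item] = (x_col.loc[sel] - ew[:, 0]) / np.sqrt(ew[:, 1])

    G = n_class_intervals or dg.default_class_intervals(len(z_new))
    ci = dg.class_intervals(theta, G)
    fac_list = factors or sorted(dif_table.table["factor"].unique())
    dif_after = dif_anova(
        z_new.drop(columns=[item]), pf, ci, fac_list, alpha=dif_table.alpha
    )

    before = {
        (r["item"], r["factor"])
        for _, r in dif_table.flagged().iterrows()
        if r["item"] != item
    }
    after = {
        (r["item"], r["factor"]) for _, r in dif_after.flagged().iterrows()
    }
    return DIFResolution(
        split_item=item,
        factor=factor,
        group_locations=group_loc,
        group_location_ses=group_se,
        difference=diff,
        difference_p=p,
        vanished=sorted(before - after),
        remaining=sorted(before & after),
        dif_after=dif_after,
    )
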
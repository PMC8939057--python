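"""Item- and person-fit diagnostics for a fitted partial credit model.

Four item-fit indicators drive the shortening procedure: the item fit
residual (screening band +/-2.5; negative values signal redundancy/overfit,
positive values misfit), the item-trait chi-square over class intervals,
residual correlations between items (local dependency when a pair exceeds
the average off-diagonal correlation by 0.2), and threshold ordering.
Summary statistics (residual means/SDs, total chi-square, the person
separation index) describe overall model fit at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pcm import ItemParameters, PersonEstimates, ResponseMatrix, expected_score_and_variance

__all__ = [
    "FitReport",
    "ResidualCorrelationReport",
    "standardized_residuals",
    "item_fit_residuals",
    "person_fit_residuals",
    "class_intervals",
    "item_trait_chi_square",
    "person_separation_index",
    "residual_correlations",
    "check_threshold_ordering",
    "summary_fit",
]

DEFAULT_ALPHA = 0.01
FIT_RESIDUAL_LIMIT = 2.5


def default_class_intervals(n: int) -> int:
    """Default number of class intervals: min(10, n/50), at least 2."""
    return max(2, min(10, n // 50))


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------


def expected_and_variance_matrix(
    responses: ResponseMatrix, items: ItemParameters, persons: PersonEstimates
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model expectation E_vi and variance W_vi at each person's theta-hat,
    for non-extreme persons."""
    keep = persons.nonextreme_index()
    theta = persons.persons.loc[keep, "theta"].to_numpy()
    uniq, inv = np.unique(theta, return_inverse=True)
    E = np.empty((uniq.size, len(items.item_ids)))
    W = np.empty_like(E)
    for j, t in enumerate(uniq):
        for i, b in enumerate(items.beta):
            E[j, i], W[j, i] = expected_score_and_variance(t, b)
    cols = items.item_ids
    return (
        pd.DataFrame(E[inv], index=keep, columns=cols),
        pd.DataFrame(W[inv], index=keep, columns=cols),
    )


def standardized_residuals(
    responses: ResponseMatrix, items: ItemParameters, persons: PersonEstimates
) -> pd.DataFrame:
    """z_vi = (x_vi - E_vi) / sqrt(W_vi) over non-extreme persons."""
    E, W = expected_and_variance_matrix(responses, items, persons)
    if (W.to_numpy() <= 0).any():
        r, c = np.argwhere(W.to_numpy() <= 0)[0]
        raise ValueError(
            f"zero model variance for person {W.index[r]!r}, item {W.columns[c]!r}"
        )
    X = responses.scores.loc[E.index, items.item_ids]
    z = (X - E) / np.sqrt(W)
    if not np.all(np.isfinite(z.to_numpy())):
        raise ValueError("non-finite standardized residuals")
    return z


def _wilson_hilferty(y: float, df: float) -> float:
    """Cube-root normalisation of a chi-square-like sum: approximately
    N(0,1) when y ~ chi2(df)."""
    c = 2.0 / (9.0 * df)
    return ((y / df) ** (1.0 / 3.0) - (1.0 - c)) / np.sqrt(c)


def item_fit_residuals(z: pd.DataFrame, W: pd.DataFrame | None = None) -> pd.Series:
    """One fit residual per item from the column sum of squared residuals,
    normalised to mean 0 / SD 1 under model fit.  Negative values indicate
    Guttman-like overfit (redundancy), positive values misfit.

    Because each person's location is estimated from their own responses,
    residuals sum to zero within person and the expected squared residual is
    below 1; when the model variances ``W`` are supplied the reference df is
    adjusted accordingly (df_i = sum_v (1 - W_vi / sum_j W_vj)), otherwise
    df is the person count.
    """
    if W is None:
        df = pd.Series(float(len(z)), index=z.columns)
    else:
        share = W.div(W.sum(axis=1), axis=0)
        df = (1.0 - share).sum(axis=0)
    y = z.pow(2).sum(axis=0)
    return pd.Series(
        [_wilson_hilferty(yi, di) for yi, di in zip(y, df)], index=z.columns
    )


def person_fit_residuals(z: pd.DataFrame) -> pd.Series:
    """Row-wise analogue of :func:`item_fit_residuals`; the within-person
    residual constraint leaves I - 1 degrees of freedom per person."""
    k = z.shape[1]
    df = max(k - 1, 1)
    return z.pow(2).sum(axis=1).apply(lambda y: _wilson_hilferty(y, df))


# ---------------------------------------------------------------------------
# item-trait chi-square
# ---------------------------------------------------------------------------


def class_intervals(theta: pd.Series, n_intervals: int) -> pd.Series:
    """Partition persons into equal-count intervals on the theta-hat rank.

    Ties are broken by stable person order so the split is deterministic.
    """
    if n_intervals < 2:
        raise ValueError("need at least 2 class intervals")
    n = len(theta)
    if n < n_intervals:
        raise ValueError("more class intervals than persons")
    order = np.argsort(theta.to_numpy(), kind="stable")
    labels = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, n_intervals)):
        if chunk.size == 0:
            raise ValueError("empty class interval")
        labels[chunk] = g
    return pd.Series(labels, index=theta.index, name="class_interval")


def item_trait_chi_square(
    responses: ResponseMatrix,
    items: ItemParameters,
    persons: PersonEstimates,
    n_class_intervals: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, dict]:
    """Per-item class-interval chi-square and the total item-trait statistic.

    chi2_i = sum_g (sum_{v in g} (x_vi - E_vi))^2 / sum_{v in g} W_vi with
    df = G - 1 per item; per-item p values are Bonferroni-compared against
    ``alpha / n_items``.
    """
    E, W = expected_and_variance_matrix(responses, items, persons)
    keep = E.index
    G = n_class_intervals or default_class_intervals(len(keep))
    ci = class_intervals(persons.persons.loc[keep, "theta"], G)
    X = responses.scores.loc[keep, items.item_ids]
    resid = X - E
    num = resid.groupby(ci).sum() ** 2
    den = W.groupby(ci).sum()
    chi2 = (num / den).sum(axis=0)
    df = G - 1
    p = pd.Series(stats.chi2.sf(chi2, df), index=chi2.index)
    n_items = len(items.item_ids)
    out = pd.DataFrame(
        {
            "chi2": chi2,
            "df": df,
            "p": p,
            "significant": p < alpha / n_items,
        }
    )
    total_chi2 = float(chi2.sum())
    total_df = n_items * df
    totals = {
        "chi2": total_chi2,
        "df": total_df,
        "p": float(stats.chi2.sf(total_chi2, total_df)),
        "n_class_intervals": G,
    }
    return out, totals


# ---------------------------------------------------------------------------
# summary indices
# ---------------------------------------------------------------------------


def person_separation_index(persons: PersonEstimates) -> float:
    """PSI = (Var(theta-hat) - mean(SE^2)) / Var(theta-hat), extremes
    excluded.  Analogous to Cronbach's alpha; negative raw values are
    reported as the raw value here and floored to 0 by report writers."""
    keep = persons.nonextreme_index()
    if len(keep) < 2:
        raise ValueError("PSI requires at least two non-extreme persons")
    theta = persons.persons.loc[keep, "theta"]
    var = float(theta.var(ddof=1))
    err = float((persons.persons.loc[keep, "se"] ** 2).mean())
    if var <= 0:
        raise ValueError("degenerate person variance")
    return (var - err) / var


@dataclass
class ResidualCorrelationReport:
    """Pairwise Pearson correlations of standardized-residual columns.

    ``critical`` is the average off-diagonal correlation plus 0.2; pairs
    above it are flagged as locally dependent.
    """

    matrix: pd.DataFrame
    average_offdiag: float
    critical: float
    flagged_pairs: list[tuple[str, str, float]]

    def excess(self, item: str) -> float:
        """Largest flagged exceedance involving ``item`` (0 if none)."""
        best = 0.0
        for a, b, r in self.flagged_pairs:
            if item in (a, b):
                best = max(best, r - self.critical)
        return best


def residual_correlations(z: pd.DataFrame, margin: float = 0.2) -> ResidualCorrelationReport:
    corr = z.corr()
    k = corr.shape[0]
    off = corr.to_numpy()[~np.eye(k, dtype=bool)]
    avg = float(off.mean()) if k > 1 else 0.0
    crit = avg + margin
    flagged = []
    cols = list(corr.columns)
    for a in range(k):
        for b in range(a + 1, k):
            r = float(corr.iloc[a, b])
            if r > crit:
                flagged.append((cols[a], cols[b], r))
    return ResidualCorrelationReport(corr, avg, crit, flagged)


def check_threshold_ordering(items: ItemParameters) -> pd.Series:
    """True iff an item's uncentered thresholds increase strictly."""
    return pd.Series(
        [bool(np.all(np.diff(b) > 0)) for b in items.beta],
        index=items.item_ids,
        name="ordered",
    )


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------


@dataclass
class FitReport:
    """Summary fit statistics for one analysis step plus per-item detail."""

    label: str
    n_items: int
    n_persons: int
    n_extreme: int
    item_residual_mean: float
    item_residual_sd: float
    person_residual_mean: float
    person_residual_sd: float
    total_chi2: float
    total_df: int
    total_chi2_p: float
    psi: float
    unidim_pct: float | None = None
    unidim_ci: tuple[float, float] | None = None
    item_table: pd.DataFrame | None = None
    item_fit: pd.Series | None = None
    person_fit: pd.Series | None = None

    def summary_row(self) -> dict:
        lo, hi = self.unidim_ci if self.unidim_ci is not None else (np.nan, np.nan)
        return {
            "analysis": self.label,
            "item_res_mean": self.item_residual_mean,
            "item_res_sd": self.item_residual_sd,
            "person_res_mean": self.person_residual_mean,
            "person_res_sd": self.person_residual_sd,
            "chisq": self.total_chi2,
            "chisq_p": self.total_chi2_p,
            "psi": max(self.psi, 0.0),
            "unidim_pct": np.nan if self.unidim_pct is None else self.unidim_pct,
            "unidim_ci_low": lo,
            "unidim_ci_high": hi,
        }


def summary_fit(
    label: str,
    responses: ResponseMatrix,
    items: ItemParameters,
    persons: PersonEstimates,
    *,
    n_class_intervals: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    unidim: tuple[float, tuple[float, float]] | None = None,
) -> FitReport:
    """Assemble the Table-1-shaped summary record for one analysis step."""
    E, W = expected_and_variance_matrix(responses, items, persons)
    X = responses.scores.loc[E.index, items.item_ids]
    z = (X - E) / np.sqrt(W)
    fr_items = item_fit_residuals(z, W)
    fr_persons = person_fit_residuals(z)
    chi_table, chi_tot = item_trait_chi_square(
        responses, items, persons, n_class_intervals, alpha
    )
    ordered = check_threshold_ordering(items)
    item_table = pd.DataFrame(
        {
            "fit_residual": fr_items,
            "chi2": chi_table["chi2"],
            "df": chi_table["df"],
            "p": chi_table["p"],
            "chi2_significant": chi_table["significant"],
            "ordered_thresholds": ordered,
            "location": pd.Series(items.delta, index=items.item_ids),
        }
    )
    n_extreme = int(persons.persons["extreme"].sum())
    pct, ci = (unidim if unidim is not None else (None, None))
    return FitReport(
        label=label,
        n_items=len(items.item_ids),
        n_persons=responses.n_persons,
        n_extreme=n_extreme,
        item_residual_mean=float(fr_items.mean()),
        item_residual_sd=float(fr_items.std(ddof=1)),
        person_residual_mean=float(fr_persons.mean()),
        person_residual_sd=float(fr_persons.std(ddof=1)),
        total_chi2=chi_tot["chi2"],
        total_df=chi_tot["df"],
        total_chi2_p=chi_tot["p"],
        psi=person_separation_index(persons),
        unidim_pct=pct,
        unidim_ci=ci,
        item_table=item_table,
        item_fit=fr_items,
        person_fit=fr_persons,
    )
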
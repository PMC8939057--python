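"""Testlet (super-item) analysis and ordinal-to-interval score conversion.

Local dependency within subscales is absorbed by summing each subscale's
items into one polytomous super-item (testlet) and re-fitting the PCM at
testlet level.  Subscale-level person estimates give disattenuated latent
correlations and the explained common variance (ECV) — how much of the
non-error variance a single common dimension carries.

The conversion table maps every raw total (equivalently the 1-5 ordinal
mean) through the Rasch person estimate to an interval 'metric' score, the
linear rescaling of the logit onto 1-5 anchored at the extrapolated
extreme-score estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diagnostics as dg
from .pcm import (
    ItemParameters,
    PersonEstimates,
    ResponseMatrix,
    estimate_persons,
    fit_items_cml,
    score_to_theta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TestletStructure",
    "ConversionTable",
    "LatentStructureReport",
    "form_testlets",
    "latent_structure",
    "build_conversion_table",
    "metric_from_logit",
    "apply_conversion",
]


# ---------------------------------------------------------------------------
# testlet formation
# ---------------------------------------------------------------------------


@dataclass
class TestletStructure:
    members: dict[str, list[str]]  # testlet -> item ids
    responses: ResponseMatrix  # testlet-level matrix
    collapse_maps: dict[str, dict[int, int]]  # raw testlet score -> recoded

    @property
    def max_scores(self) -> dict[str, int]:
        return dict(self.responses.max_scores)


def form_testlets(
    responses: ResponseMatrix, *, on_null_category: str = "collapse"
) -> TestletStructure:
    """Sum each subscale's items into one testlet super-item.

    A testlet score level that no person attains (a null category) cannot be
    located by CML; with ``on_null_category='collapse'`` the observed levels
    are recoded to consecutive integers (logged), with ``'error'`` a
    :class:`NullCategoryError` is raised.
    """
    members: dict[str, list[str]] = {}
    for item, sub in responses.subscale_map.items():
        members.setdefault(sub, []).append(item)
    data = {}
    collapse_maps: dict[str, dict[int, int]] = {}
    max_scores = {}
    for sub, items in members.items():
        total = responses.scores[items].sum(axis=1)
        mmax = int(sum(responses.max_scores[i] for i in items))
        observed = np.sort(total.unique())
        missing = sorted(set(range(mmax + 1)) - set(observed.tolist()))
        if missing:
            if on_null_category == "error":
                from .pcm import NullCategoryError

                raise NullCategoryError(
                    f"testlet {sub}: score level(s) {missing} never observed"
                )
            recode = {int(v): j for j, v in enumerate(observed)}
            logger.info(
                "testlet %s: collapsing %d null categories %s", sub, len(missing), missing
            )
            total = total.map(recode)
            collapse_maps[sub] = recode
            mmax = len(observed) - 1
        data[sub] = total
        max_scores[sub] = mmax
    scores = pd.DataFrame(data)
    tl = ResponseMatrix(
        scores=scores,
        person_factors=responses.person_factors,
        subscale_map={s: s for s in members},
        max_scores=max_scores,
    )
    return TestletStructure(members=members, responses=tl, collapse_maps=collapse_maps)


# ---------------------------------------------------------------------------
# latent structure (subscale correlations, ECV)
# ---------------------------------------------------------------------------


@dataclass
class LatentStructureReport:
    observed_correlations: pd.DataFrame
    reliabilities: dict[str, float]
    latent_correlations: pd.DataFrame
    average_latent_correlation: float
    ecv: float


def latent_structure(responses: ResponseMatrix) -> LatentStructureReport:
    """Disattenuated subscale correlations and explained common variance.

    Each subscale is fitted and scored separately (its own PCM and person
    estimates); reliabilities are the subscale PSIs.  Latent correlations
    r_kl = corr(theta_k, theta_l) / sqrt(rho_k rho_l), capped at 1.  ECV
    treats the average latent correlation as the share of true variance the
    common dimension explains: common = c_bar * (sum_k sqrt(t_k))^2 over
    total = sum t_k + sum_{k!=l} r_kl sqrt(t_k t_l), with t_k the true
    (reliability-weighted) variance; 1 when all r_kl = 1, 0 under
    independence.
    """
    subs: dict[str, list[str]] = {}
    for item, sub in responses.subscale_map.items():
        subs.setdefault(sub, []).append(item)
    if len(subs) < 2:
        raise ValueError("latent structure needs at least two subscales")
    theta = {}
    rho = {}
    for sub, items in subs.items():
        rm = responses.subset_items(items)
        fit = fit_items_cml(rm)
        pe = estimate_persons(rm, fit)
        rho_k = dg.person_separation_index(pe)
        if rho_k <= 0:
            raise ValueError(f"non-positive reliability for subscale {sub}")
        keep = pe.nonextreme_index()
        theta[sub] = pe.persons.loc[keep, "theta"]
        rho[sub] = rho_k
    names = sorted(subs)
    th = pd.DataFrame({s: theta[s] for s in names}).dropna()
    obs = th.corr()
    latent = obs.copy()
    for a in names:
        for b in names:
            if a != b:
                latent.loc[a, b] = min(
                    1.0, obs.loc[a, b] / np.sqrt(rho[a] * rho[b])
                )
    pairs = [
        latent.loc[a, b] for i, a in enumerate(names) for b in names[i + 1 :]
    ]
    cbar = float(np.mean(pairs))
    t = {s: rho[s] * float(th[s].var(ddof=1)) for s in names}
    total = sum(t.values()) + sum(
        latent.loc[a, b] * np.sqrt(t[a] * t[b])
        for a in names
        for b in names
        if a != b
    )
    common = cbar * sum(np.sqrt(t[s]) for s in names) ** 2
    ecv = float(np.clip(common / total, 0.0, 1.0)) if total > 0 else 0.0
    return LatentStructureReport(
        observed_correlations=obs,
        reliabilities=rho,
        latent_correlations=latent,
        average_latent_correlation=cbar,
        ecv=ecv,
    )


# ---------------------------------------------------------------------------
# ordinal -> interval conversion
# ---------------------------------------------------------------------------


def metric_from_logit(theta, theta_min: float, theta_max: float):
    """Linear rescaling of person logits onto the 1-5 interval metric:
    M = 1 + 4 (theta - theta_min) / (theta_max - theta_min).

    Values outside the anchors are clamped with a warning.
    """
    if not np.isfinite(theta_min) or not np.isfinite(theta_max) or theta_max <= theta_min:
        raise ValueError("need finite anchors with theta_min < theta_max")
    theta = np.asarray(theta, dtype=float)
    if (theta < theta_min).any() or (theta > theta_max).any():
        warnings.warn("theta outside anchor range: clamping to [1, 5]")
        theta = np.clip(theta, theta_min, theta_max)
    out = 1.0 + 4.0 * (theta - theta_min) / (theta_max - theta_min)
    return float(out) if out.ndim == 0 else out


@dataclass
class ConversionTable:
    """Raw-mean -> logit -> interval-metric lookup (one row per raw total)."""

    table: pd.DataFrame  # columns: total, raw_mean, logit, metric
    theta_min: float
    theta_max: float
    n_items: int

    def to_csv_frame(self, decimals: int = 2) -> pd.DataFrame:
        def round_half_away(x: float) -> float:
            return float(
                np.sign(x) * np.floor(np.abs(x) * 10**decimals + 0.5) / 10**decimals
            )

        out = self.table[["raw_mean", "metric", "logit"]].copy()
        for c in out.columns:
            out[c] = out[c].map(round_half_away)
        return out


def build_conversion_table(
    items: ItemParameters, *, extreme_adjust: float = 0.3
) -> ConversionTable:
    """Conversion table for a fitted instrument.

    One row per raw total 0..max; the ordinal raw mean on the 1-5 scale is
    1 + 4*total/max_total (step 1/I for I items with a full 5-category
    range); the metric column rescales the score's Rasch logit onto 1-5
    anchored at the extrapolated extreme-score estimates.
    """
    lookup = score_to_theta(items, extreme_adjust=extreme_adjust)
    theta = lookup["theta"].to_numpy()
    theta_min, theta_max = float(theta[0]), float(theta[-1])
    if theta_max <= theta_min:
        raise ValueError("degenerate anchors: theta_max <= theta_min")
    max_total = items.max_total
    totals = np.arange(max_total + 1)
    raw_mean = 1.0 + 4.0 * totals / max_total
    metric = 1.0 + 4.0 * (theta - theta_min) / (theta_max - theta_min)
    table = pd.DataFrame(
        {"total": totals, "raw_mean": raw_mean, "logit": theta, "metric": metric}
    )
    return ConversionTable(
        table=table,
        theta_min=theta_min,
        theta_max=theta_max,
        n_items=len(items.item_ids),
    )


def apply_conversion(raw_means, table: ConversionTable, *, tol: float = 1e-9):
    """Convert ordinal raw means (1-5) to interval metric scores.

    Raw means must lie on the table's grid to within ``tol`` (complete
    responses only; no imputation); an off-grid value raises an error naming
    the offending entry.
    """
    raw = pd.Series(raw_means, dtype=float)
    grid = table.table["raw_mean"].to_numpy()
    metric = table.table["metric"].to_numpy()
    out = np.empty(len(raw))
    for pos, (idx, val) in enumerate(raw.items()):
        if not np.isfinite(val):
            raise ValueError(f"incomplete response for person {idx!r}: no conversion")
        j = int(np.argmin(np.abs(grid - val)))
        if abs(grid[j] - val) > tol:
            raise ValueError(
                f"raw mean {val} for person {idx!r} is not on the 1/{table.n_items} grid"
            )
        out[pos] = metric[j]
    return pd.Series(out, index=raw.index, name="metric")
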
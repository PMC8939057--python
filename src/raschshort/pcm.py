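"""Partial credit model core: response containers, conditional maximum
likelihood (CML) item estimation, and person measurement.

The partial credit model (PCM) gives the probability that person ``v`` with
location ``theta_v`` (logits) responds in category ``x`` of item ``i`` with
ordered thresholds ``beta_i1 <= ... <= beta_im``::

    P(X_vi = x) = exp( sum_{k<=x} (theta_v - beta_ik) ) / sum_j exp( ... )

with the empty sum equal to 0.  The raw total score is sufficient for
``theta_v``, so item parameters can be estimated by conditioning on person
totals — the conditional likelihood is free of the person distribution,
which is the defining invariance property of Rasch models.  The conditional
likelihood is evaluated with polytomous elementary symmetric functions
(the summation algorithm) and maximised by Newton–Raphson with step halving.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "ItemParameters",
    "PersonEstimates",
    "NullCategoryError",
    "ConvergenceError",
    "category_probabilities",
    "expected_score_and_variance",
    "conditional_pattern_probability",
    "fit_items_cml",
    "estimate_persons",
    "score_to_theta",
]


class NullCategoryError(ValueError):
    """A score level that is never observed for an item (CML cannot locate
    the corresponding threshold)."""


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the gradient tolerance."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ResponseMatrix:
    """Complete person x item integer responses plus person covariates.

    Parameters
    ----------
    scores
        DataFrame, one row per person, one integer column per item, values
        ``0..m_i`` (survey categories 1..5 are stored recoded to 0..4).
    person_factors
        DataFrame aligned with ``scores`` holding categorical covariates
        (e.g. gender, country, age).
    subscale_map
        Mapping item id -> subscale label; every item must be mapped.
    max_scores
        Optional mapping item id -> maximum category ``m_i``; inferred from
        the observed maximum when omitted.
    """

    scores: pd.DataFrame
    person_factors: pd.DataFrame
    subscale_map: dict[str, str]
    max_scores: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.scores.isna().any().any():
            raise ValueError("missing responses: complete cases required")
        vals = self.scores.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("responses must be integers")
            self.scores = self.scores.astype(int)
            vals = self.scores.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative response category")
        missing = [c for c in self.scores.columns if c not in self.subscale_map]
        if missing:
            raise ValueError(f"items without subscale: {missing}")
        if self.max_scores is None:
            self.max_scores = {c: int(self.scores[c].max()) for c in self.scores.columns}
        for c in self.scores.columns:
            if int(self.scores[c].max()) > self.max_scores[c]:
                raise ValueError(f"score above declared maximum for item {c}")
        if not self.person_factors.index.equals(self.scores.index):
            raise ValueError("person_factors index must match scores index")

    # -- convenience -------------------------------------------------------

    @property
    def item_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_persons(self) -> int:
        return len(self.scores)

    def m_array(self) -> np.ndarray:
        return np.array([self.max_scores[c] for c in self.scores.columns], dtype=int)

    def subset_items(self, items: list[str]) -> "ResponseMatrix":
        """A new ResponseMatrix restricted to ``items`` (data are shared,
        never mutated)."""
        return ResponseMatrix(
            scores=self.scores[list(items)].copy(),
            person_factors=self.person_factors,
            subscale_map={i: self.subscale_map[i] for i in items},
            max_scores={i: self.max_scores[i] for i in items},
        )

    def subset_persons(self, index) -> "ResponseMatrix":
        return ResponseMatrix(
            scores=self.scores.loc[index].copy(),
            person_factors=self.person_factors.loc[index].copy(),
            subscale_map=dict(self.subscale_map),
            max_scores=dict(self.max_scores),
        )


@dataclass
class ItemParameters:
    """PCM item parameters on the CML metric.

    ``beta[i]`` holds the uncentered thresholds of item ``i``; the item
    location is ``delta_i = mean(beta_i)`` and the centered thresholds are
    ``tau_i = beta_i - delta_i`` (sum to zero within item).  Locations are
    normalised to mean zero across items.
    """

    item_ids: list[str]
    beta: list[np.ndarray]
    se_beta: list[np.ndarray] | None = None
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.beta = [np.asarray(b, dtype=float) for b in self.beta]
        for b in self.beta:
            if b.size < 1 or not np.all(np.isfinite(b)):
                raise ValueError("thresholds must be finite and m_i >= 1")

    @property
    def m(self) -> np.ndarray:
        return np.array([len(b) for b in self.beta], dtype=int)

    @property
    def delta(self) -> np.ndarray:
        return np.array([b.mean() for b in self.beta])

    @property
    def tau(self) -> list[np.ndarray]:
        return [b - b.mean() for b in self.beta]

    @property
    def max_total(self) -> int:
        return int(self.m.sum())

    def index_of(self, item_id: str) -> int:
        return self.item_ids.index(item_id)

    def subset(self, items: list[str]) -> "ItemParameters":
        """Anchored subset: thresholds kept exactly as fitted (no
        re-centering), so estimates stay on the parent metric."""
        idx = [self.index_of(i) for i in items]
        return ItemParameters(
            item_ids=list(items),
            beta=[self.beta[j].copy() for j in idx],
            se_beta=None if self.se_beta is None else [self.se_beta[j].copy() for j in idx],
            converged=self.converged,
            n_iter=self.n_iter,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, item in enumerate(self.item_ids):
            row = {"item": item, "location": self.beta[i].mean(), "m": len(self.beta[i])}
            for k, t in enumerate(self.beta[i] - self.beta[i].mean(), start=1):
                row[f"tau{k}"] = t
            rows.append(row)
        return pd.DataFrame(rows).set_index("item")


@dataclass
class PersonEstimates:
    """Per-person latent locations with a raw-score lookup table.

    ``score_table`` has one row per possible raw total with columns
    ``theta`` and ``se``; person rows are looked up by their total, which
    guarantees the sufficiency property (equal totals -> equal estimates).
    """

    persons: pd.DataFrame  # columns: total, theta, se, extreme
    score_table: pd.DataFrame  # index: total; columns: theta, se, extreme

    @property
    def theta(self) -> pd.Series:
        return self.persons["theta"]

    @property
    def se(self) -> pd.Series:
        return self.persons["se"]

    def nonextreme_index(self):
        return self.persons.index[~self.persons["extreme"]]


# ---------------------------------------------------------------------------
# category-level quantities
# ---------------------------------------------------------------------------


def _check_theta_beta(theta: float, beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    if not np.isfinite(theta) or not np.all(np.isfinite(beta)):
        raise ValueError("theta and thresholds must be finite")
    return beta


def category_probabilities(theta: float, beta: np.ndarray) -> np.ndarray:
    """PCM category probabilities for one item.

    Parameters are the uncentered thresholds ``beta_ik``; returns a vector of
    length ``m_i + 1`` summing to one.
    """
    beta = _check_theta_beta(theta, beta)
    kernel = np.concatenate(([0.0], np.cumsum(theta - beta)))
    kernel -= kernel.max()
    p = np.exp(kernel)
    return p / p.sum()


def expected_score_and_variance(theta: float, beta: np.ndarray) -> tuple[float, float]:
    """Mean and variance of the PCM category distribution at ``theta``."""
    p = category_probabilities(theta, beta)
    x = np.arange(p.size)
    e = float(p @ x)
    w = float(p @ x**2 - e**2)
    return e, max(w, 0.0)


# ---------------------------------------------------------------------------
# elementary symmetric functions (summation algorithm)
# ---------------------------------------------------------------------------


def _eps_and_offsets(beta_list: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-item category weights eps_ix = exp(-eta_ix), max-normalised for
    numerical range; the log offsets are returned so absolute log-gammas can
    be reconstructed."""
    eps, offs = [], []
    for b in beta_list:
        eta = np.concatenate(([0.0], np.cumsum(b)))
        a = (-eta).max()
        eps.append(np.exp(-eta - a))
        offs.append(a)
    return eps, np.asarray(offs)


def _poly_prod(polys: list[np.ndarray]) -> np.ndarray:
    out = np.array([1.0])
    for p in polys:
        out = np.convolve(out, p)
    return out


def _prefix_suffix(polys: list[np.ndarray]) -> tuple[list[np.ndarray], list[np.ndarray]]:
    n = len(polys)
    pre = [np.array([1.0])]
    for i in range(n):
        pre.append(np.convolve(pre[-1], polys[i]))
    suf = [np.array([1.0])] * (n + 1)
    for i in range(n - 1, -1, -1):
        suf[i] = np.convolve(polys[i], suf[i + 1])
    return pre, suf


def conditional_pattern_probability(items: ItemParameters, pattern) -> float:
    """Probability of a response pattern given its own total score.

    Free of theta; over all patterns sharing the total these probabilities
    sum to one.
    """
    pattern = np.asarray(pattern, dtype=int)
    m = items.m
    if pattern.size != len(items.item_ids):
        raise ValueError("pattern length does not match item count")
    if (pattern < 0).any() or (pattern > m).any():
        raise ValueError("pattern outside category range")
    eps, _ = _eps_and_offsets(items.beta)
    gamma = _poly_prod(eps)
    r = int(pattern.sum())
    num = float(np.prod([eps[i][pattern[i]] for i in range(pattern.size)]))
    return num / float(gamma[r])


# ---------------------------------------------------------------------------
# CML estimation
# ---------------------------------------------------------------------------


def _validate_categories(X: np.ndarray, m: np.ndarray, item_ids: list[str]) -> None:
    for i, item in enumerate(item_ids):
        counts = np.bincount(X[:, i], minlength=m[i] + 1)
        empty = np.nonzero(counts == 0)[0]
        if empty.size:
            raise NullCategoryError(
                f"item {item}: category {int(empty[0])} never observed "
                f"(null category); collapse categories or drop the item"
            )


def _cml_parts(beta_list: list[np.ndarray], n_r: np.ndarray):
    """Log conditional likelihood pieces shared by value/gradient/Hessian.

    Returns (loggamma over totals, per-item tail probabilities
    Pge[i][k, r] = P(X_i >= k | total r), eps list, leave-one-out ESFs).
    """
    eps, offs = _eps_and_offsets(beta_list)
    pre, suf = _prefix_suffix(eps)
    gamma = pre[-1]
    R = gamma.size - 1
    loggamma = np.log(gamma) + offs.sum()
    Pge = []
    loo = []
    for i in range(len(eps)):
        g_i = np.convolve(pre[i], suf[i + 1])
        loo.append(g_i)
        mi = eps[i].size - 1
        P = np.zeros((mi + 1, R + 1))
        for x in range(mi + 1):
            P[x, x : x + g_i.size] = eps[i][x] * g_i
        P /= gamma[np.newaxis, :]
        tail = np.flip(np.cumsum(np.flip(P, axis=0), axis=0), axis=0)
        Pge.append(tail)  # row k = P(X_i >= k | r); row 0 == 1
    return loggamma, Pge, eps, loo, gamma


def _cml_loglik(beta_list, S_list, n_r) -> float:
    eps, offs = _eps_and_offsets(beta_list)
    gamma = _poly_prod(eps)
    loggamma = np.log(gamma) + offs.sum()
    ll = -sum(float(b @ s) for b, s in zip(beta_list, S_list))
    ll -= float(n_r @ loggamma)
    return ll


def _cml_grad_hess(beta_list, S_list, n_r):
    m = np.array([b.size for b in beta_list])
    loggamma, Pge, eps, loo, gamma = _cml_parts(beta_list, n_r)
    nI = len(beta_list)
    # gradient
    grad = np.concatenate(
        [-S_list[i] + Pge[i][1:] @ n_r for i in range(nI)]
    )
    # Hessian = -sum_r n_r Cov_r(T), T_ik = 1[X_i >= k]
    P = int(m.sum())
    H = np.zeros((P, P))
    starts = np.concatenate(([0], np.cumsum(m)))
    w = np.where(gamma > 0, n_r / gamma, 0.0)
    # diagonal blocks
    for i in range(nI):
        W1 = Pge[i][1:] @ n_r  # sum_r n_r P(X_i>=k|r)
        ks = np.arange(1, m[i] + 1)
        M1 = W1[np.maximum.outer(ks, ks) - 1]
        M2 = (Pge[i][1:] * n_r) @ Pge[i][1:].T
        H[starts[i] : starts[i + 1], starts[i] : starts[i + 1]] = -(M1 - M2)
    # off-diagonal blocks via pairwise leave-two-out ESFs
    for i in range(nI):
        sub = [eps[j] for j in range(nI) if j != i]
        pre2, suf2 = _prefix_suffix(sub)
        pos = 0
        for j in range(nI):
            if j == i:
                continue
            g2 = np.convolve(pre2[pos], suf2[pos + 1])  # ESF without i and j
            pos += 1
            if j < i:
                continue  # fill upper triangle once (j > i)
            smax = m[i] + m[j]
            gs = np.zeros(smax + 1)
            for s in range(smax + 1):
                L = min(g2.size, w.size - s)
                if L > 0:
                    gs[s] = w[s : s + L] @ g2[:L]
            C = np.outer(eps[i], eps[j]) * gs[
                np.add.outer(np.arange(m[i] + 1), np.arange(m[j] + 1))
            ]
            tail = np.flip(np.cumsum(np.flip(C, 0), 0), 0)
            tail = np.flip(np.cumsum(np.flip(tail, 1), 1), 1)
            D = (Pge[i][1:] * n_r) @ Pge[j][1:].T
            block = -(tail[1:, 1:] - D)
            H[starts[i] : starts[i + 1], starts[j] : starts[j + 1]] = block
            H[starts[j] : starts[j + 1], starts[i] : starts[i + 1]] = block.T
    return grad, H


def fit_items_cml(
    responses: ResponseMatrix,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ItemParameters:
    """Estimate PCM thresholds by conditional maximum likelihood.

    Newton–Raphson with step halving on the conditional log likelihood;
    the likelihood is concave and invariant to adding a constant to all
    thresholds, so the step is solved on the regularised Hessian and the
    solution re-centered to mean item location zero.

    Raises
    ------
    NullCategoryError
        If some item never shows one of its score levels.
    ConvergenceError
        If the gradient infinity-norm does not reach ``tol`` within
        ``max_iter`` iterations.
    """
    item_ids = responses.item_ids
    if len(item_ids) < 2:
        raise ValueError("CML requires at least two items")
    X = responses.scores.to_numpy()
    m = responses.m_array()
    _validate_categories(X, m, item_ids)

    totals = X.sum(axis=1)
    R = int(m.sum())
    n_r = np.bincount(totals, minlength=R + 1).astype(float)
    # sufficient statistics S_ik = #{v: x_vi >= k}
    S_list = [
        np.array([(X[:, i] >= k).sum() for k in range(1, m[i] + 1)], dtype=float)
        for i in range(len(item_ids))
    ]

    beta_list = [np.zeros(mi) for mi in m]
    ll = _cml_loglik(beta_list, S_list, n_r)
    P = int(m.sum())
    u = np.ones(P) / np.sqrt(P)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad, H = _cml_grad_hess(beta_list, S_list, n_r)
        gnorm = float(np.abs(grad).max())
        if gnorm < tol:
            break
        lam = max(1.0, float(np.abs(np.diag(H)).mean()))
        step = np.linalg.solve(H - lam * np.outer(u, u), -grad)
        # step halving
        t = 1.0
        for _ in range(40):
            trial = _unflatten(np.concatenate(beta_list) + t * step, m)
            ll_new = _cml_loglik(trial, S_list, n_r)
            if ll_new > ll - 1e-10 * max(1.0, abs(ll)):
                break
            t /= 2.0
        else:
            raise ConvergenceError(
                f"step halving failed at gradient norm {gnorm:.3e}"
            )
        beta_list = trial
        ll = ll_new
    else:
        grad, _ = _cml_grad_hess(beta_list, S_list, n_r)
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(gradient norm {np.abs(grad).max():.3e})"
        )

    # identifiability: mean item location zero
    shift = float(np.mean([b.mean() for b in beta_list]))
    beta_list = [b - shift for b in beta_list]

    _, H = _cml_grad_hess(beta_list, S_list, n_r)
    cov = np.linalg.pinv(-H, hermitian=True)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se_list = _unflatten(se, m)

    return ItemParameters(
        item_ids=list(item_ids),
        beta=beta_list,
        se_beta=se_list,
        converged=True,
        n_iter=n_iter,
    )


def _unflatten(flat: np.ndarray, m: np.ndarray) -> list[np.ndarray]:
    out, pos = [], 0
    for mi in m:
        out.append(np.asarray(flat[pos : pos + mi], dtype=float).copy())
        pos += mi
    return out


# ---------------------------------------------------------------------------
# person estimation
# ---------------------------------------------------------------------------


def _solve_theta(target: float, beta_list: list[np.ndarray]) -> float:
    """Newton solve of sum_i E_i(theta) = target (monotone in theta)."""
    theta = 0.0
    for _ in range(100):
        e = w = 0.0
        for b in beta_list:
            ei, wi = expected_score_and_variance(theta, b)
            e += ei
            w += wi
        diff = target - e
        if abs(diff) < 1e-10:
            return theta
        step = diff / max(w, 1e-12)
        theta += float(np.clip(step, -2.0, 2.0))
    return theta


def score_to_theta(
    items: ItemParameters, *, extreme_adjust: float = 0.3
) -> pd.DataFrame:
    """Raw-total -> (theta, se) lookup for an anchored item set.

    Interior totals are maximum-likelihood estimates; the extreme totals 0
    and max are moved inward by ``extreme_adjust`` score units before
    solving, which yields finite endpoint estimates.
    """
    R = items.max_total
    rows = []
    for r in range(R + 1):
        extreme = r == 0 or r == R
        r_eff = float(np.clip(r, extreme_adjust, R - extreme_adjust))
        theta = _solve_theta(r_eff, items.beta)
        info = sum(expected_score_and_variance(theta, b)[1] for b in items.beta)
        se = 1.0 / np.sqrt(max(info, 1e-12))
        rows.append({"total": r, "theta": theta, "se": se, "extreme": extreme})
    return pd.DataFrame(rows).set_index("total")


def estimate_persons(
    responses: ResponseMatrix,
    items: ItemParameters,
    *,
    extreme_adjust: float = 0.3,
) -> PersonEstimates:
    """Per-person ML locations given anchored item parameters.

    The raw total is sufficient, so estimation runs once per possible total
    and persons are mapped through the lookup table.
    """
    if responses.item_ids != items.item_ids:
        raise ValueError("responses and item parameters must list the same items")
    table = score_to_theta(items, extreme_adjust=extreme_adjust)
    totals = responses.scores.sum(axis=1)
    persons = table.loc[totals.to_numpy()].set_index(totals.index)
    persons.insert(0, "total", totals)
    return PersonEstimates(persons=persons, score_table=table)
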
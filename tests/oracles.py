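"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's elementary-symmetric-function
machinery: conditional probabilities come from full pattern enumeration and
person estimates from a dense grid search, so agreement with the package is
a genuine cross-check.
"""

import itertools

import numpy as np
from scipy.optimize import minimize

from raschshort.pcm import category_probabilities


def enumerate_conditional_probability(beta_list, pattern):
    """P(pattern | its total) by enumerating every pattern with that total."""
    pattern = tuple(int(x) for x in pattern)
    r = sum(pattern)

    def weight(pat):
        w = 1.0
        for b, x in zip(beta_list, pat):
            eta = float(np.sum(b[:x]))
            w *= np.exp(-eta)
        return w

    ranges = [range(len(b) + 1) for b in beta_list]
    denom = sum(weight(p) for p in itertools.product(*ranges) if sum(p) == r)
    return weight(pattern) / denom


def brute_force_cml(X, m):
    """Maximise the conditional likelihood by direct pattern enumeration
    (quasi-Newton on the unconstrained thresholds, then centered)."""
    X = np.asarray(X, dtype=int)
    n_items = X.shape[1]
    totals = X.sum(axis=1)

    ranges = [range(mi + 1) for mi in m]
    patterns = np.array(list(itertools.product(*ranges)), dtype=int)
    pattern_totals = patterns.sum(axis=1)

    def nll(flat):
        beta_list, pos = [], 0
        for mi in m:
            beta_list.append(flat[pos : pos + mi])
            pos += mi
        etas = np.zeros(patterns.shape[0])
        for i, b in enumerate(beta_list):
            cum = np.concatenate(([0.0], np.cumsum(b)))
            etas += cum[patterns[:, i]]
        w = np.exp(-etas)
        denom = np.array(
            [w[pattern_totals == r].sum() for r in range(int(sum(m)) + 1)]
        )
        ll = 0.0
        for row, r in zip(X, totals):
            eta = sum(
                float(np.sum(beta_list[i][: row[i]])) for i in range(n_items)
            )
            ll += -eta - np.log(denom[r])
        return -ll

    res = minimize(nll, np.zeros(int(sum(m))), method="BFGS", options={"gtol": 1e-10})
    beta_list, pos = [], 0
    for mi in m:
        beta_list.append(res.x[pos : pos + mi].copy())
        pos += mi
    shift = float(np.mean([b.mean() for b in beta_list]))
    return [b - shift for b in beta_list]


def grid_person_mle(pattern, beta_list, lo=-8.0, hi=8.0, step=1e-3):
    """Grid-search ML person estimate for one response pattern."""
    grid = np.arange(lo, hi + step, step)
    best_theta, best_ll = None, -np.inf
    for theta in grid:
        ll = 0.0
        for b, x in zip(beta_list, pattern):
            ll += np.log(category_probabilities(theta, b)[int(x)])
        if ll > best_ll:
            best_ll, best_theta = ll, theta
    return best_theta
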
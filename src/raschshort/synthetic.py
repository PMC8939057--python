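"""Synthetic response generators emulating the survey's structure.

Two generators are provided: a strictly unidimensional partial-credit
sampler (the null model for every calibration check) and a questionnaire-like
generator with 23 items in four subscales (EX 8, MD 5, CI 5, EI 5), five
ordered categories, a dominant general burnout factor plus subscale-specific
nuisance factors (which induce within-subscale local dependency, the bifactor
mechanism behind testlet formation), gender x country strata and an age
covariate.  DIF can be injected with known ground truth, and stratified
subsampling mirrors the 4 x 200 cross-validation design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pcm import ResponseMatrix

__all__ = [
    "SyntheticSpec",
    "DIFInjection",
    "bat_item_bank",
    "unidimensional_item_bank",
    "simulate_unidimensional_pcm",
    "simulate_bat_like",
    "inject_dif",
    "stratified_subsample",
]

SUBSCALE_SIZES = {"EX": 8, "MD": 5, "CI": 5, "EI": 5}
# Subscale severity offsets (logits): exhaustion items are endorsed at the
# lowest burnout levels, emotional-impairment items at the highest.
SUBSCALE_OFFSETS = {"EX": -0.45, "MD": -0.05, "CI": 0.1, "EI": 0.4}
DEFAULT_TAU = np.array([-2.0, -0.7, 0.5, 1.15])


@dataclass(frozen=True)
class DIFInjection:
    """Ground-truth differential item functioning for one item.

    uniform: the item's location shifts by ``size`` logits for persons at
    ``level`` of ``factor``.  non-uniform: those persons respond with a
    discrimination of ``1 + size`` on theta for that item.
    """

    item: str
    factor: str
    level: str
    size: float
    kind: str = "uniform"

    def __post_init__(self):
        if self.kind not in ("uniform", "non-uniform"):
            raise ValueError("kind must be 'uniform' or 'non-uniform'")
        if not np.isfinite(self.size):
            raise ValueError("DIF size must be finite")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating configuration; the seed is mandatory.

    ``person_mean``/``person_sd`` describe the general factor; the survey's
    reported targeting (person mean -1.04, SD 1.045 against an item mean
    constrained to 0) is the default.  ``nuisance_sd`` is the SD of the
    subscale-specific person factors; 0.6 yields inter-subscale latent
    correlations near 0.7.
    """

    n_persons: int = 800
    person_mean: float = -1.04
    person_sd: float = 1.045
    nuisance_sd: float = 0.6
    seed: int = 0
    dif: tuple[DIFInjection, ...] = ()
    strata_proportions: dict | None = None  # (gender, country) -> prob

    def __post_init__(self):
        if self.person_sd < 0 or self.nuisance_sd < 0:
            raise ValueError("SDs must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def unidimensional_item_bank(n_items: int = 12, m: int = 4) -> tuple[list[str], list[np.ndarray]]:
    """Evenly spread item locations in [-1, 1] with equally spaced ordered
    thresholds; mean location 0."""
    ids = [f"I{i+1}" for i in range(n_items)]
    locs = np.linspace(-1.0, 1.0, n_items)
    locs -= locs.mean()
    if m == 4:
        tau = DEFAULT_TAU
    else:
        tau = np.linspace(-1.0, 1.0, m) * 1.5
    tau = tau - tau.mean()
    return ids, [d + tau for d in locs]


def bat_item_bank() -> tuple[list[str], list[np.ndarray], dict[str, str]]:
    """23-item generating bank: ids, uncentered thresholds, subscale map.

    Locations are staggered within subscale (span 0.8 logits) around the
    subscale offsets, normalised to overall mean 0; thresholds are ordered
    and shared in shape across items.
    """
    ids: list[str] = []
    betas: list[np.ndarray] = []
    submap: dict[str, str] = {}
    for sub, size in SUBSCALE_SIZES.items():
        spread = np.linspace(-0.35, 0.35, size)
        for j in range(size):
            item = f"{sub}{j+1}"
            ids.append(item)
            submap[item] = sub
            betas.append(SUBSCALE_OFFSETS[sub] + spread[j] + DEFAULT_TAU)
    shift = float(np.mean([b.mean() for b in betas]))
    betas = [b - shift for b in betas]
    return ids, betas, submap


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def _sample_categories(theta_eff: np.ndarray, beta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised PCM draw for one item; ``theta_eff`` is the per-person
    effective location (after any DIF adjustment)."""
    m = beta.size
    kernel = np.cumsum(theta_eff[:, None] - beta[None, :], axis=1)
    kernel = np.concatenate([np.zeros((theta_eff.size, 1)), kernel], axis=1)
    kernel -= kernel.max(axis=1, keepdims=True)
    p = np.exp(kernel)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(theta_eff.size)
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(int)


def _make_factors(n: int, rng: np.random.Generator, proportions: dict | None) -> pd.DataFrame:
    if proportions is None:
        cells = [("man", "NL"), ("man", "FL"), ("woman", "NL"), ("woman", "FL")]
        probs = np.full(4, 0.25)
    else:
        cells = list(proportions.keys())
        probs = np.array(list(proportions.values()), dtype=float)
        probs /= probs.sum()
    draw = rng.choice(len(cells), size=n, p=probs)
    gender = [cells[d][0] for d in draw]
    country = [cells[d][1] for d in draw]
    age = np.clip(np.round(rng.normal(41, 11, n)), 18, 67).astype(int)
    return pd.DataFrame({"gender": gender, "country": country, "age": age})


def _apply_dif(
    theta: np.ndarray,
    beta: np.ndarray,
    item: str,
    factors: pd.DataFrame,
    difs: tuple[DIFInjection, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-person effective theta and item thresholds under injected DIF."""
    theta_eff = theta.copy()
    shift = np.zeros(theta.size)
    for d in difs:
        if d.item != item:
            continue
        mask = (factors[d.factor].astype(str) == d.level).to_numpy()
        if d.kind == "uniform":
            shift[mask] -= d.size  # location shift: harder by `size` logits
        else:
            theta_eff[mask] = theta[mask] * (1.0 + d.size)
    return theta_eff + 0.0, shift


def _simulate(
    ids: list[str],
    betas: list[np.ndarray],
    submap: dict[str, str],
    theta: np.ndarray,
    factors: pd.DataFrame,
    rng: np.random.Generator,
    difs: tuple[DIFInjection, ...] = (),
    nuisance: dict[str, np.ndarray] | None = None,
) -> ResponseMatrix:
    n = theta.size
    X = np.zeros((n, len(ids)), dtype=int)
    for i, (item, beta) in enumerate(zip(ids, betas)):
        th = theta
        if nuisance is not None:
            th = theta + nuisance[submap[item]]
        theta_eff, shift = _apply_dif(th, beta, item, factors, difs)
        X[:, i] = _sample_categories(theta_eff + shift, beta, rng)
    scores = pd.DataFrame(X, columns=ids)
    return ResponseMatrix(
        scores=scores,
        person_factors=factors,
        subscale_map=dict(submap),
        max_scores={i: b.size for i, b in zip(ids, betas)},
    )


def simulate_unidimensional_pcm(
    spec: SyntheticSpec,
    n_items: int = 12,
    m: int = 4,
    item_bank: tuple[list[str], list[np.ndarray]] | None = None,
    theta: np.ndarray | None = None,
) -> ResponseMatrix:
    """Strictly unidimensional PCM data (the null model).

    ``theta`` overrides the person draw when supplied (e.g. for floor/ceiling
    checks); otherwise theta ~ N(person_mean, person_sd^2).
    """
    rng = np.random.default_rng(spec.seed)
    ids, betas = item_bank if item_bank is not None else unidimensional_item_bank(n_items, m)
    if theta is None:
        theta = rng.normal(spec.person_mean, spec.person_sd, spec.n_persons)
    theta = np.asarray(theta, dtype=float)
    factors = _make_factors(theta.size, rng, spec.strata_proportions)
    submap = {i: "ALL" for i in ids}
    return _simulate(ids, betas, submap, theta, factors, rng, spec.dif)


def simulate_bat_like(spec: SyntheticSpec) -> ResponseMatrix:
    """23-item, four-subscale data with a dominant general factor plus
    subscale nuisance factors and gender x country strata."""
    rng = np.random.default_rng(spec.seed)
    ids, betas, submap = bat_item_bank()
    theta = rng.normal(spec.person_mean, spec.person_sd, spec.n_persons)
    nuisance = {
        sub: rng.normal(0.0, spec.nuisance_sd, spec.n_persons)
        for sub in SUBSCALE_SIZES
    }
    factors = _make_factors(spec.n_persons, rng, spec.strata_proportions)
    return _simulate(ids, betas, submap, theta, factors, rng, spec.dif, nuisance)


def inject_dif(spec: SyntheticSpec, *injections: DIFInjection) -> SyntheticSpec:
    """A copy of ``spec`` with extra ground-truth DIF; size-0 injections
    leave the generator unchanged."""
    keep = tuple(d for d in injections if d.size != 0.0)
    return replace(spec, dif=spec.dif + keep)


# ---------------------------------------------------------------------------
# stratified subsampling
# ---------------------------------------------------------------------------


def stratified_subsample(
    responses: ResponseMatrix,
    strata_cols: tuple[str, str] = ("gender", "country"),
    k_per_stratum: int = 200,
    n_draws: int = 2,
    seed: int = 0,
) -> list[ResponseMatrix]:
    """Draw ``n_draws`` subsamples with exactly ``k_per_stratum`` persons
    per stratum (without replacement within a draw)."""
    rng = np.random.default_rng(seed)
    groups = responses.person_factors.groupby(list(strata_cols), sort=True).groups
    for key, idx in groups.items():
        if len(idx) < k_per_stratum:
            raise ValueError(f"stratum {key} has only {len(idx)} persons (< {k_per_stratum})")
    out = []
    for _ in range(n_draws):
        chosen = []
        for key in sorted(groups, key=str):
            idx = np.asarray(list(groups[key]))
            take = rng.choice(idx.size, size=k_per_stratum, replace=False)
            chosen.extend(idx[np.sort(take)])
        out.append(responses.subset_persons(pd.Index(chosen)))
    return out
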
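"""Independent oracles for the distribution fitter.

Dense grid search over each candidate family, computing expectations and
type-1 quartiles through scipy.stats frozen distributions — a separate
route from the closed forms used by the fitter — plus a scipy-based
re-computation of criterion C for any fitted parameter set.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

CONTINUOUS = ("truncated_normal", "gumbel", "lognormal", "weibull", "gamma")
DISCRETE = ("poisson", "zip", "negbinom")


def _c(mean_fit, q25_fit, q75_fit, mean, q25, q75):
    with np.errstate(invalid="ignore", over="ignore"):
        c = (mean_fit - mean) ** 2 + (q25_fit - q25) ** 2 + (q75_fit - q75) ** 2
    return np.where(np.isfinite(c), c, np.inf)


def scipy_stats_for(family: str, a: float, b: float):
    """Mean and quartiles of family (a, b) via scipy.stats objects."""
    if family == "point_mass":
        return a, a, a
    if family == "truncated_normal":
        alpha = (0.0 - a) / b
        d = stats.truncnorm(alpha, np.inf, loc=a, scale=b)
    elif family == "gumbel":
        d = stats.gumbel_r(loc=a, scale=b)
    elif family == "lognormal":
        d = stats.lognorm(s=b, scale=np.exp(a))
    elif family == "weibull":
        d = stats.weibull_min(c=a, scale=b)
    elif family == "gamma":
        d = stats.gamma(a=a, scale=b)
    elif family == "poisson":
        d = stats.poisson(a)
    elif family == "zip":
        pi, lam = a, b
        mean = (1 - pi) * lam

        def q(p):
            inner = (p - pi) / (1 - pi)
            return 0.0 if inner <= 0 else float(stats.poisson.ppf(inner, lam))

        return mean, q(0.25), q(0.75)
    elif family == "negbinom":
        d = stats.nbinom(a, b)
    else:
        raise ValueError(family)
    return float(d.mean()), float(d.ppf(0.25)), float(d.ppf(0.75))


def recompute_c(family: str, a: float, b: float,
                mean: float, q25: float, q75: float) -> float:
    mf, ql, qu = scipy_stats_for(family, a, b)
    return float((mf - mean) ** 2 + (ql - q25) ** 2 + (qu - q75) ** 2)


def _grid_min(mean_fit, q25_fit, q75_fit, mean, q25, q75):
    return float(np.min(_c(mean_fit, q25_fit, q75_fit, mean, q25, q75)))


def grid_oracle_continuous(mean: float, q25: float, q75: float,
                           n: int = 120) -> float:
    """Minimal C over all five continuous families on dense parameter grids."""
    iqr = q75 - q25
    s = iqr / 1.349 if iqr > 0 else 1e-3 * max(mean, 1.0)
    best = np.inf
    locs = np.linspace(mean - 6 * s, mean + 6 * s, n)
    scales = np.geomspace(s / 20, s * 20, n)

    # truncated normal
    L, S = np.meshgrid(locs, scales, indexing="ij")
    alpha = (0.0 - L) / S
    d = stats.truncnorm(alpha, np.inf, loc=L, scale=S)
    best = min(best, _grid_min(d.mean(), d.ppf(0.25), d.ppf(0.75), mean, q25, q75))

    # gumbel
    d = stats.gumbel_r(loc=L, scale=S)
    best = min(best, _grid_min(d.mean(), d.ppf(0.25), d.ppf(0.75), mean, q25, q75))

    # lognormal
    pos = max(mean, 1e-6)
    mus = np.linspace(np.log(pos) - 2.0, np.log(pos) + 2.0, n)
    sigs = np.geomspace(max(s / pos, 1e-4) / 20, 4.0, n)
    M, G = np.meshgrid(mus, sigs, indexing="ij")
    d = stats.lognorm(s=G, scale=np.exp(M))
    best = min(best, _grid_min(d.mean(), d.ppf(0.25), d.ppf(0.75), mean, q25, q75))

    # weibull
    shapes = np.geomspace(0.2, 60.0, n)
    wscales = np.geomspace(pos / 10, pos * 10, n)
    K, W = np.meshgrid(shapes, wscales, indexing="ij")
    d = stats.weibull_min(c=K, scale=W)
    best = min(best, _grid_min(d.mean(), d.ppf(0.25), d.ppf(0.75), mean, q25, q75))

    # gamma
    gshapes = np.geomspace(1e-2, 1e5, n)
    gscales = pos / gshapes  # keep the grid centred on the elicited mean
    grids = []
    for factor in np.geomspace(0.25, 4.0, 15):
        d = stats.gamma(a=gshapes, scale=gscales * factor)
        grids.append(_grid_min(d.mean(), d.ppf(0.25), d.ppf(0.75), mean, q25, q75))
    best = min(best, min(grids))
    return best


def grid_oracle_discrete(mean: float, q25: float, q75: float) -> float:
    """Minimal C over the three discrete families on dense parameter grids."""
    hi = max(mean, q75, 1.0)
    best = np.inf

    lams = np.unique(np.concatenate([np.linspace(1e-6, 3 * hi + 5, 4000), [mean]]))
    d = stats.poisson(lams)
    best = min(best, _grid_min(d.mean(), d.ppf(0.25), d.ppf(0.75), mean, q25, q75))

    pis = np.linspace(0.0, 0.95, 40)
    zlams = np.linspace(1e-6, 4 * hi + 5, 400)
    P, L = np.meshgrid(pis, zlams, indexing="ij")
    zmean = (1 - P) * L
    inner25 = np.clip((0.25 - P) / (1 - P), 0, 1)
    inner75 = np.clip((0.75 - P) / (1 - P), 0, 1)
    zq25 = np.where((0.25 - P) <= 0, 0.0, stats.poisson.ppf(inner25, L))
    zq75 = np.where((0.75 - P) <= 0, 0.0, stats.poisson.ppf(inner75, L))
    best = min(best, _grid_min(zmean, zq25, zq75, mean, q25, q75))

    sizes = np.geomspace(1e-2, 1e4, 120)
    mus = np.linspace(max(1e-6, 0.2 * hi), 3 * hi + 5, 200)
    Z, U = np.meshgrid(sizes, mus, indexing="ij")
    prob = Z / (Z + U)
    d = stats.nbinom(Z, prob)
    best = min(best, _grid_min(d.mean(), d.ppf(0.25), d.ppf(0.75), mean, q25, q75))
    return best


def grid_oracle(mean: float, q25: float, q75: float, kind: str) -> float:
    if kind == "continuous":
        return grid_oracle_continuous(mean, q25, q75)
    return grid_oracle_discrete(mean, q25, q75)


def elicitation_triples(n_continuous: int = 35, n_discrete: int = 15, seed: int = 20210419):
    """A fixed, seeded panel of elicitation triples of both variable kinds."""
    rng = np.random.default_rng(seed)
    triples = []
    for _ in range(n_continuous):
        mean = float(rng.lognormal(np.log(20.0), 1.0))
        rel = float(rng.uniform(0.05, 0.5))
        lo = float(rng.uniform(0.5, 1.5))
        hi = float(rng.uniform(0.5, 1.5))
        q25 = max(mean * (1 - lo * rel), 0.0)
        q75 = mean * (1 + hi * rel)
        triples.append((mean, q25, q75, "continuous"))
    for _ in range(n_discrete):
        lam = float(rng.uniform(0.5, 30.0))
        mean = lam * float(rng.uniform(0.85, 1.15))
        q25 = float(stats.poisson.ppf(0.25, lam))
        q75 = float(stats.poisson.ppf(0.75, lam)) + float(rng.integers(0, 2))
        triples.append((mean, min(q25, q75), q75, "discrete"))
    return triples
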
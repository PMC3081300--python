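"""Fit a two-parameter distribution to each elicited (mean, q25, q75) triple.

Experts report each observation as a mean plus lower (25%) and upper (75%)
quartiles. To propagate that numerical uncertainty, each triple is matched
to a parametric distribution L(a, b) by minimising the criterion

    C = m^2 + q_l^2 + q_u^2

where ``m`` is the deviation of the distribution's expectation from the
elicited mean and ``q_l``, ``q_u`` the deviations of its quartiles from the
elicited quartiles. Candidate families depend on the variable kind:

* continuous — truncated normal (truncated at 0), Gumbel, log-normal,
  Weibull, gamma;
* discrete — Poisson, zero-inflated Poisson, negative binomial.

A degenerate elicitation (mean = q25 = q75) becomes a point mass. The
winning family is the one with the smallest C; exact ties are broken by
the fixed order of ``CONTINUOUS_FAMILIES`` / ``DISCRETE_FAMILIES``.

Monte-Carlo replication of the data-collection process then draws, per
documented cell, a vector of ``n_sim`` values from the fitted distribution
(default 999). Cells in one duplication group — localities where the expert
copied a single elicited value — share one identical simulated vector, and
every cell draws from its own seeded substream so adding or removing a cell
never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaincinv, gammaln, ndtr, ndtri

from .data import CellKey, Dataset

CONTINUOUS_FAMILIES = ("truncated_normal", "gumbel", "lognormal", "weibull", "gamma")
DISCRETE_FAMILIES = ("poisson", "zip", "negbinom")

_EULER = float(np.euler_gamma)
# Gumbel quantile constants: q_p = a - b * ln(-ln p)
_GUMBEL_C25 = math.log(-math.log(0.25))   # +0.3266...
_GUMBEL_C75 = math.log(-math.log(0.75))   # -1.2459...


@dataclass(frozen=True)
class FittedDistribution:
    """The selected family L(a, b) for one elicited triple.

    ``m``, ``q_l`` and ``q_u`` are the residual deviations (expectation and
    quartiles, fitted minus elicited); ``c_value`` is their squared sum.
    For one-parameter families ``b`` is unused and stored as 0.
    """

    family: str
    a: float
    b: float
    c_value: float
    m: float
    q_l: float
    q_u: float


@dataclass(frozen=True)
class SimulatedValues:
    """Per-cell Monte-Carlo replicate vectors of the data-collection process."""

    values: dict[CellKey, np.ndarray]
    n_sim: int
    seed: int

    def __post_init__(self) -> None:
        for key, vec in self.values.items():
            if len(vec) != self.n_sim:
                raise ValueError(f"vector for {key} has length {len(vec)} != {self.n_sim}")


def criterion_c(m: float, q_l: float, q_u: float) -> float:
    """Discrepancy score combining expectation and quartile deviations.

    Symmetric least-squares form: ``m**2 + q_l**2 + q_u**2``. Zero iff the
    fitted distribution reproduces the elicited mean and both quartiles
    exactly. Kept as a separate function so the combination rule is
    swappable in one place.
    """
    if not (np.isfinite(m) and np.isfinite(q_l) and np.isfinite(q_u)):
        raise ValueError("criterion deviations must be finite")
    return float(m * m + q_l * q_l + q_u * q_u)


# ---------------------------------------------------------------------------
# family moment/quantile functions (vectorised over parameters)


def _truncnorm_stats(mu, sigma):
    """Mean and quartiles of N(mu, sigma) truncated to [0, inf)."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    alpha = -mu / sigma
    tail = 1.0 - ndtr(alpha)  # P(X > 0) before truncation
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.exp(-0.5 * alpha * alpha) / math.sqrt(2.0 * math.pi)
        mean = mu + sigma * phi / tail
        q25 = mu + sigma * ndtri(ndtr(alpha) + 0.25 * tail)
        q75 = mu + sigma * ndtri(ndtr(alpha) + 0.75 * tail)
    bad = tail < 1e-12
    return (
        np.where(bad, np.inf, mean),
        np.where(bad, np.inf, q25),
        np.where(bad, np.inf, q75),
    )


def _gumbel_stats(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return a + _EULER * b, a - b * _GUMBEL_C25, a - b * _GUMBEL_C75


def _lognormal_stats(mu, sigma):
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    with np.errstate(over="ignore"):
        mean = np.exp(mu + 0.5 * sigma * sigma)
        q25 = np.exp(mu + sigma * ndtri(0.25))
        q75 = np.exp(mu + sigma * ndtri(0.75))
    return mean, q25, q75


def _weibull_stats(shape, scale):
    shape = np.asarray(shape, float)
    scale = np.asarray(scale, float)
    with np.errstate(over="ignore", invalid="ignore"):
        mean = scale * np.exp(gammaln(1.0 + 1.0 / shape))
        q25 = scale * (-math.log(0.75)) ** (1.0 / shape)
        q75 = scale * (-math.log(0.25)) ** (1.0 / shape)
    return mean, q25, q75


def _gamma_stats(shape, scale):
    shape = np.asarray(shape, float)
    scale = np.asarray(scale, float)
    with np.errstate(over="ignore", invalid="ignore"):
        mean = shape * scale
        q25 = scale * gammaincinv(shape, 0.25)
        q75 = scale * gammaincinv(shape, 0.75)
    return mean, q25, q75


_CONTINUOUS_STATS = {
    "truncated_normal": _truncnorm_stats,
    "gumbel": _gumbel_stats,
    "lognormal": _lognormal_stats,
    "weibull": _weibull_stats,
    "gamma": _gamma_stats,
}


def _poisson_stats(lam):
    lam = np.asarray(lam, float)
    return lam, stats.poisson.ppf(0.25, lam), stats.poisson.ppf(0.75, lam)


def _zip_stats(pi, lam):
    """Zero-inflated Poisson: P(0 extra) = pi, else Poisson(lam)."""
    pi = np.asarray(pi, float)
    lam = np.asarray(lam, float)
    mean = (1.0 - pi) * lam

    def q(p):
        # smallest k with pi + (1-pi) F_pois(k) >= p
        inner = (p - pi) / (1.0 - pi)
        k = np.where(inner <= 0, 0.0, stats.poisson.ppf(np.clip(inner, 0, 1), lam))
        return k

    return mean, q(0.25), q(0.75)


def _negbinom_stats(size, prob):
    size = np.asarray(size, float)
    prob = np.asarray(prob, float)
    mean = size * (1.0 - prob) / prob
    return mean, stats.nbinom.ppf(0.25, size, prob), stats.nbinom.ppf(0.75, size, prob)


_DISCRETE_STATS = {
    "poisson": _poisson_stats,
    "zip": _zip_stats,
    "negbinom": _negbinom_stats,
}


def family_stats(family: str, a, b=None):
    """Mean and type-1 quartiles of family (a, b); vectorised over params."""
    if family == "point_mass":
        a = np.asarray(a, float)
        return a, a, a
    if family in _CONTINUOUS_STATS:
        return _CONTINUOUS_STATS[family](a, b)
    if family == "poisson":
        return _poisson_stats(a)
    if family in _DISCRETE_STATS:
        return _DISCRETE_STATS[family](a, b)
    raise ValueError(f"unknown family {family!r}")


def _c_array(mean_fit, q25_fit, q75_fit, mean, q25, q75):
    with np.errstate(invalid="ignore", over="ignore"):
        c = (
            (mean_fit - mean) ** 2
            + (q25_fit - q25) ** 2
            + (q75_fit - q75) ** 2
        )
    return np.where(np.isfinite(c), c, np.inf)


# ---------------------------------------------------------------------------
# continuous fitting: heuristic starts + Nelder-Mead in transformed space


def _spread(mean: float, q25: float, q75: float) -> float:
    iqr = q75 - q25
    if iqr > 0:
        return iqr / 1.349
    base = max(abs(mean), abs(q75), 1.0)
    return 1e-3 * base


def _starts_continuous(family: str, mean: float, q25: float, q75: float):
    """Heuristic (a, b) starting points per family."""
    s = _spread(mean, q25, q75)
    mid = 0.5 * (q25 + q75)
    pos_mean = max(mean, 1e-8)
    starts: list[tuple[float, float]] = []
    if family == "truncated_normal":
        starts += [(mean, s), (mid, s), (mean, 2 * s), (-0.5 * pos_mean, pos_mean + s)]
    elif family == "gumbel":
        b0 = (q75 - q25) / 1.5725 if q75 > q25 else s
        b0 = max(b0, 1e-8)
        starts += [(mean - _EULER * b0, b0)]
        # exact linear least squares on (mean, q25, q75)
        A = np.array([[1.0, _EULER], [1.0, -_GUMBEL_C25], [1.0, -_GUMBEL_C75]])
        sol, *_ = np.linalg.lstsq(A, np.array([mean, q25, q75]), rcond=None)
        if sol[1] > 1e-10:
            starts.append((float(sol[0]), float(sol[1])))
    elif family == "lognormal":
        if q25 > 0 and q75 > q25:
            sig0 = math.log(q75 / q25) / 1.349
        else:
            sig0 = s / pos_mean if pos_mean > 0 else 0.3
        sig0 = min(max(sig0, 1e-6), 5.0)
        starts += [
            (math.log(pos_mean) - 0.5 * sig0 * sig0, sig0),
            (math.log(max(mid, 1e-8)), sig0),
        ]
    elif family == "weibull":
        for k0 in (0.8, 1.5, 3.0, 6.0):
            scale0 = pos_mean / math.gamma(1.0 + 1.0 / k0)
            starts.append((k0, scale0))
    elif family == "gamma":
        cv = s / pos_mean
        shape0 = min(max(1.0 / (cv * cv), 1e-3), 1e6)
        starts += [(shape0, pos_mean / shape0), (1.0, pos_mean), (4.0, pos_mean / 4.0)]
    return starts


def _transform(family: str, a: float, b: float) -> np.ndarray:
    # positive-only parameters optimised on the log scale
    if family in ("truncated_normal", "gumbel", "lognormal"):
        return np.array([a, math.log(max(b, 1e-12))])
    return np.array([math.log(max(a, 1e-12)), math.log(max(b, 1e-12))])


def _untransform(family: str, theta: np.ndarray) -> tuple[float, float]:
    if family in ("truncated_normal", "gumbel", "lognormal"):
        return float(theta[0]), float(np.exp(theta[1]))
    return float(np.exp(theta[0])), float(np.exp(theta[1]))


def _fit_family_continuous(
    family: str, mean: float, q25: float, q75: float
) -> tuple[float, float, float]:
    """Minimise C for one continuous family; returns (a, b, C)."""
    fn = _CONTINUOUS_STATS[family]

    def objective(theta: np.ndarray) -> float:
        a, b = _untransform(family, theta)
        if not (np.isfinite(a) and np.isfinite(b)) or b <= 0 or b > 1e12:
            return np.inf
        if family in ("weibull", "gamma") and (a <= 0 or a > 1e9):
            return np.inf
        mf, ql, qu = fn(a, b)
        c = _c_array(mf, ql, qu, mean, q25, q75)
        return float(c)

    best = (np.nan, np.nan, np.inf)
    for a0, b0 in _starts_continuous(family, mean, q25, q75):
        theta0 = _transform(family, a0, b0)
        if not np.isfinite(objective(theta0)):
            continue
        res = optimize.minimize(
            objective, theta0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400},
        )
        if res.fun < best[2]:
            a, b = _untransform(family, res.x)
            best = (a, b, float(res.fun))
    return best


# ---------------------------------------------------------------------------
# discrete fitting: vectorised coarse grid + local polish


def _grid_minimum(stats_fn, grids, mean, q25, q75):
    """Evaluate C over a parameter grid; return (params, C)."""
    mesh = np.meshgrid(*grids, indexing="ij")
    flat = [m.ravel() for m in mesh]
    mf, ql, qu = stats_fn(*flat)
    c = _c_array(mf, ql, qu, mean, q25, q75)
    i = int(np.argmin(c))
    return tuple(float(f[i]) for f in flat), float(c[i])


def _fit_poisson(mean, q25, q75):
    hi = max(mean, q75, 1.0)
    grid = np.unique(np.concatenate([
        np.linspace(1e-6, 3.0 * hi + 5.0, 1500), [max(mean, 1e-6)],
    ]))
    (lam,), c = _grid_minimum(_poisson_stats, [grid], mean, q25, q75)
    step = grid[1] - grid[0]
    # refine around the coarse optimum; quantiles are piecewise-constant in
    # lambda so plateau edges need a fine sweep, and within a plateau the
    # mean term is optimised by lambda = mean
    fine = np.unique(np.concatenate([
        np.linspace(max(lam - 2 * step, 1e-9), lam + 2 * step, 600),
        [max(mean, 1e-9)],
    ]))
    (lam, ), c = _grid_minimum(_poisson_stats, [fine], mean, q25, q75)
    return (lam, 0.0), c


def _zip_with_mean_polish(pis, lams, mean, q25, q75):
    """Grid C over (pi, lam) plus the mean-exact lam = mean/(1-pi) line."""
    (pi, lam), c = _grid_minimum(_zip_stats, [pis, lams], mean, q25, q75)
    if mean > 0:
        cand = mean / (1.0 - pis)
        mf, ql, qu = _zip_stats(pis, cand)
        cc = _c_array(mf, ql, qu, mean, q25, q75)
        j = int(np.argmin(cc))
        if cc[j] < c:
            pi, lam, c = float(pis[j]), float(cand[j]), float(cc[j])
    return (pi, lam), c


def _fit_zip(mean, q25, q75):
    hi = max(mean, q75, 1.0)
    pis = np.linspace(0.0, 0.95, 58)
    lams = np.linspace(1e-6, 4.0 * hi + 5.0, 240)
    (pi, lam), c = _zip_with_mean_polish(pis, lams, mean, q25, q75)
    dpi, dlam = pis[1] - pis[0], lams[1] - lams[0]
    fine_pis = np.clip(np.linspace(pi - 2 * dpi, pi + 2 * dpi, 70), 0.0, 0.999)
    fine_lams = np.linspace(max(lam - 2 * dlam, 1e-9), lam + 2 * dlam, 70)
    (pi2, lam2), c2 = _zip_with_mean_polish(fine_pis, fine_lams, mean, q25, q75)
    if c2 < c:
        pi, lam, c = pi2, lam2, c2
    return (pi, lam), c


def _negbinom_grid(sizes, mus, mean, q25, q75):
    sz, mu = np.meshgrid(sizes, mus, indexing="ij")
    prob = sz / (sz + mu)
    mf, ql, qu = _negbinom_stats(sz.ravel(), prob.ravel())
    c = _c_array(mf, ql, qu, mean, q25, q75)
    i = int(np.argmin(c))
    best = (float(sz.ravel()[i]), float(mu.ravel()[i])), float(c[i])
    # at fixed size, the mean term is optimised by mu = mean exactly
    if mean > 0:
        prob2 = sizes / (sizes + mean)
        mf, ql, qu = _negbinom_stats(sizes, prob2)
        c2 = _c_array(mf, ql, qu, mean, q25, q75)
        j = int(np.argmin(c2))
        if c2[j] < best[1]:
            best = (float(sizes[j]), float(mean)), float(c2[j])
    return best


def _fit_negbinom(mean, q25, q75):
    hi = max(mean, q75, 1.0)
    sizes = np.geomspace(1e-2, 1e5, 140)
    mus = np.linspace(max(1e-6, 0.2 * hi), 3.0 * hi + 5.0, 160)
    (size, mu), c = _negbinom_grid(sizes, mus, mean, q25, q75)
    # second pass at fine mu resolution over the plausible central range:
    # the quantile terms are piecewise-constant with narrow plateaus there
    lo = max(1e-6, 0.8 * min(q25, mean))
    hi_mu = 1.2 * max(q75, mean) + 1.0
    (size1, mu1), c1 = _negbinom_grid(sizes, np.linspace(lo, hi_mu, 400),
                                      mean, q25, q75)
    if c1 < c:
        size, mu, c = size1, mu1, c1
    # the C surface is piecewise with several basins over size; refine
    # locally around the coarse optimum and around the mean-exact line
    dmu = mus[1] - mus[0]
    for size0, mu0 in ((size, mu), (size, mean if mean > 0 else mu)):
        fine_sizes = np.geomspace(size0 / 1.5, size0 * 1.5, 80)
        fine_mus = np.linspace(max(mu0 - 2 * dmu, 1e-9), mu0 + 2 * dmu, 80)
        (size2, mu2), c2 = _negbinom_grid(fine_sizes, fine_mus, mean, q25, q75)
        if c2 < c:
            size, mu, c = size2, mu2, c2
    return (size, size / (size + mu)), c


_DISCRETE_FITTERS = {
    "poisson": _fit_poisson,
    "zip": _fit_zip,
    "negbinom": _fit_negbinom,
}


# ---------------------------------------------------------------------------
# public fitting entry points


def _check_triple(mean: float, q25: float, q75: float) -> None:
    for name, v in (("mean", mean), ("q25", q25), ("q75", q75)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if q25 > q75:
        raise ValueError(f"q25={q25} > q75={q75}")


def fit_distribution(
    mean: float, q25: float, q75: float, variable_kind: str = "continuous"
) -> FittedDistribution:
    """Select the family and parameters minimising criterion C for one triple."""
    mean, q25, q75 = float(mean), float(q25), float(q75)
    _check_triple(mean, q25, q75)
    if q25 == q75 == mean:
        return FittedDistribution("point_mass", mean, 0.0, 0.0, 0.0, 0.0, 0.0)

    candidates: list[FittedDistribution] = []
    if variable_kind == "continuous":
        for family in CONTINUOUS_FAMILIES:
            a, b, c = _fit_family_continuous(family, mean, q25, q75)
            if np.isfinite(c):
                mf, ql, qu = family_stats(family, a, b)
                candidates.append(FittedDistribution(
                    family, a, b, c,
                    float(mf - mean), float(ql - q25), float(qu - q75),
                ))
    elif variable_kind == "discrete":
        for family in DISCRETE_FAMILIES:
            (a, b), c = _DISCRETE_FITTERS[family](mean, q25, q75)
            mf, ql, qu = family_stats(family, a, b)
            candidates.append(FittedDistribution(
                family, a, b, c,
                float(mf - mean), float(ql - q25), float(qu - q75),
            ))
    else:
        raise ValueError(f"unknown variable_kind {variable_kind!r}")

    if not candidates:
        raise RuntimeError("no candidate family produced a finite fit")
    # smallest C wins; near-exact ties resolved by the fixed family order
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.c_value < best.c_value - 1e-12:
            best = cand
    return best


def _rescale_fit(fit: FittedDistribution, c: float) -> FittedDistribution:
    """Exact rescaling of a continuous fit from triple/c back to triple.

    All continuous families respond to scaling x -> c*x by a known parameter
    map, and C scales by c^2 (deviations by c).
    """
    family = fit.family
    if family in ("truncated_normal", "gumbel"):
        a, b = fit.a * c, fit.b * c
    elif family == "lognormal":
        a, b = fit.a + math.log(c), fit.b
    elif family in ("weibull", "gamma"):
        a, b = fit.a, fit.b * c
    elif family == "point_mass":
        a, b = fit.a * c, 0.0
    else:
        raise ValueError(f"cannot rescale family {family!r}")
    return FittedDistribution(
        family, a, b, fit.c_value * c * c, fit.m * c, fit.q_l * c, fit.q_u * c
    )


def fit_dataset(dataset: Dataset) -> dict[CellKey, FittedDistribution]:
    """Fit every documented cell of a dataset.

    Continuous triples are fitted on a mean-normalised scale and the
    parameters rescaled exactly, so datasets with many cells sharing one
    relative quartile spread are fitted essentially once.
    """
    cache: dict[tuple, FittedDistribution] = {}
    out: dict[CellKey, FittedDistribution] = {}
    for r in dataset.records.itertuples():
        key: CellKey = (r.indicator_id, r.ecosystem_id, r.unit_id, int(r.date))
        mean, q25, q75 = float(r.mean_value), float(r.q25), float(r.q75)
        if r.variable_kind == "continuous" and mean > 0:
            norm_key = ("continuous", round(q25 / mean, 12), round(q75 / mean, 12))
            if norm_key not in cache:
                cache[norm_key] = fit_distribution(1.0, q25 / mean, q75 / mean, "continuous")
            out[key] = _rescale_fit(cache[norm_key], mean)
        else:
            triple_key = (r.variable_kind, mean, q25, q75)
            if triple_key not in cache:
                cache[triple_key] = fit_distribution(mean, q25, q75, r.variable_kind)
            out[key] = cache[triple_key]
    return out


def fits_to_frame(fits: Mapping[CellKey, FittedDistribution]):
    """Audit table of fitted families and parameters, one row per cell."""
    import pandas as pd

    rows = [
        {
            "indicator_id": k[0], "ecosystem_id": k[1], "unit_id": k[2], "date": k[3],
            "family": f.family, "a": f.a, "b": f.b, "C": f.c_value,
            "m": f.m, "q_l": f.q_l, "q_u": f.q_u,
        }
        for k, f in sorted(fits.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo replication


def _stream_entropy(key) -> int:
    digest = hashlib.sha256(repr(key).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") >> 1  # < 2**63


def _draw(fit: FittedDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    family, a, b = fit.family, fit.a, fit.b
    if family == "point_mass":
        return np.full(n, a, dtype=float)
    if family == "truncated_normal":
        # exact inverse-CDF sampling of N(a, b) conditioned on X >= 0
        alpha = -a / b
        lo = ndtr(alpha)
        u = rng.uniform(size=n)
        return a + b * ndtri(lo + u * (1.0 - lo))
    if family == "gumbel":
        return np.maximum(rng.gumbel(a, b, size=n), 0.0)
    if family == "lognormal":
        return rng.lognormal(a, b, size=n)
    if family == "weibull":
        return b * rng.weibull(a, size=n)
    if family == "gamma":
        return rng.gamma(shape=a, scale=b, size=n)
    if family == "poisson":
        return rng.poisson(a, size=n).astype(float)
    if family == "zip":
        pi, lam = a, b
        occupied = rng.uniform(size=n) >= pi
        return np.where(occupied, rng.poisson(lam, size=n), 0).astype(float)
    if family == "negbinom":
        return rng.negative_binomial(a, b, size=n).astype(float)
    raise ValueError(f"unknown family {family!r}")


def draw_replicates(
    fits: Mapping[CellKey, FittedDistribution],
    n_sim: int = 999,
    seed: int = 0,
    duplication_groups: Mapping[CellKey, str] | None = None,
) -> SimulatedValues:
    """Draw ``n_sim`` Monte-Carlo replicates of every documented cell.

    Each independent elicitation gets its own RNG substream derived from
    ``seed`` and a stable hash of its identity (the duplication-group id for
    duplicated cells, the cell key otherwise), so the draws of one cell are
    invariant to the presence of other cells, and cells in one duplication
    group carry bit-identical vectors.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    duplication_groups = dict(duplication_groups or {})
    group_vectors: dict[str, np.ndarray] = {}
    values: dict[CellKey, np.ndarray] = {}
    for key in sorted(fits):
        fit = fits[key]
        group = duplication_groups.get(key)
        stream_key = ("group", group) if group is not None else ("cell",) + key
        if group is not None and group in group_vectors:
            values[key] = group_vectors[group]
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), _stream_entropy(stream_key)])
        )
        vec = np.maximum(_draw(fit, n_sim, rng), 0.0)
        values[key] = vec
        if group is not None:
            group_vectors[group] = vec
    return SimulatedValues(values=values, n_sim=n_sim, seed=int(seed))
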
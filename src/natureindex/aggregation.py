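"""Index computation: weighted aggregation, confidence intervals, p-values.

For each Monte-Carlo replicate s, the index at date t over a scope
(a selection of indicators, ecosystems and spatial units) is

    NI_t(s) = sum_over_documented_cells W_ijkt * s_ijkt(s)

with the weights renormalised over the documented cells of the scope so
they sum to one at every date. The index is summarised by the median of
the n simulated values with a 95% confidence interval given by the 2.5%
and 97.5% quantiles (linear interpolation between order statistics).
Comparing two dates uses a simulation-based p-value: the fraction of
replicates in which one date's index exceeds the other's, ties counted
one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, DatasetError
from .scaling import ScaledSimulations


@dataclass(frozen=True)
class Scope:
    """An aggregation scope: which ecosystems / units / indicators to average.

    ``None`` on an axis means "all". The label is free text for reporting.
    """

    ecosystems: tuple[str, ...] | None = None
    units: tuple[str, ...] | None = None
    indicators: tuple[str, ...] | None = None
    label: str = ""

    @staticmethod
    def make(ecosystems=None, units=None, indicators=None, label="") -> "Scope":
        tup = lambda x: tuple(sorted(x)) if x is not None else None
        return Scope(tup(ecosystems), tup(units), tup(indicators), label)

    def same_selection(self, other: "Scope") -> bool:
        return (self.ecosystems, self.units, self.indicators) == (
            other.ecosystems, other.units, other.indicators)


@dataclass(frozen=True)
class IndexResult:
    """Simulated index values for one scope and date, with summaries."""

    scope: Scope
    date: int
    sims: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    n_documented: int
    source_counts: dict[str, int]
    weight_deficit: float = 0.0


@dataclass(frozen=True)
class ComparisonResult:
    """Simulation-based comparison of the index between two dates."""

    scope: Scope
    date1: int
    date2: int
    p_one_sided: float
    p_two_sided: float
    median_difference: float


def compute_index(
    scaled: ScaledSimulations,
    weights: pd.DataFrame,
    dataset: Dataset,
    scope: Scope,
    date: int,
) -> IndexResult:
    """Aggregate scaled simulations under a weight table for one date.

    ``weights`` is the table from :func:`natureindex.weighting.weight_table`
    (optionally passed through a thematic mask) restricted to ``date``;
    every weighted cell must have a scaled simulation vector. Weights are
    renormalised over documented cells; the pre-renormalisation deficit is
    reported on the result.
    """
    w = weights[weights["date"] == int(date)]
    if len(w) == 0:
        raise DatasetError(
            f"no documented indicators in scope {scope.label or scope} at date {date}"
        )
    keys = [
        (r.indicator_id, r.ecosystem_id, r.unit_id, int(r.date))
        for r in w.itertuples()
    ]
    missing = [k for k in keys if k not in scaled.values]
    if missing:
        raise DatasetError(f"no simulated values for weighted cell {missing[0]}")
    mat = np.stack([scaled.values[k] for k in keys])        # (cells, n_sim)
    wv = w["W"].to_numpy(float)
    total = wv.sum()
    if total <= 0:
        raise DatasetError("weights sum to zero over documented cells")
    sims = (wv / total) @ mat

    rec = dataset.records
    rec = rec[rec["date"] == int(date)]
    rec = rec.merge(
        w[["indicator_id", "ecosystem_id", "unit_id"]].drop_duplicates(),
        on=["indicator_id", "ecosystem_id", "unit_id"],
    )
    counts = {s: int((rec["source"] == s).sum()) for s in ("monitoring", "model", "expert")}

    return IndexResult(
        scope=scope,
        date=int(date),
        sims=sims,
        median=float(np.quantile(sims, 0.5)),
        ci_low=float(np.quantile(sims, 0.025)),
        ci_high=float(np.quantile(sims, 0.975)),
        n_documented=len(keys),
        source_counts=counts,
        weight_deficit=float(max(0.0, 1.0 - total)),
    )


def compare_dates(res1: IndexResult, res2: IndexResult) -> ComparisonResult:
    """Simulation-based p-values for index(date1) vs index(date2).

    One-sided p is the fraction of replicates with NI_t1 > NI_t2, ties
    counted one half (so identical vectors give p = 0.5); the two-sided p
    is 2 * min(p, 1 - p), capped at 1. The dates use independently drawn
    simulation vectors, so the test compares the two simulated index
    distributions as wholes.
    """
    if not res1.scope.same_selection(res2.scope):
        raise DatasetError("cannot compare results with different scopes")
    if len(res1.sims) != len(res2.sims):
        raise DatasetError("cannot compare results with different n_sim")
    n = len(res1.sims)
    greater = float(np.sum(res1.sims > res2.sims))
    ties = float(np.sum(res1.sims == res2.sims))
    p1 = (greater + 0.5 * ties) / n
    p2 = min(1.0, 2.0 * min(p1, 1.0 - p1))
    return ComparisonResult(
        scope=res1.scope,
        date1=res1.date,
        date2=res2.date,
        p_one_sided=float(p1),
        p_two_sided=float(p2),
        median_difference=float(res1.median - res2.median),
    )


def mountain_filter(dataset: Dataset, ecosystem_id: str, threshold: float = 0.2) -> list[str]:
    """Units where an ecosystem covers at least ``threshold`` of total area.

    The default 0.2 reproduces the convention of restricting mountain
    indexes to municipalities at least 20% mountainous.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    un = dataset.units
    sub = un[un["ecosystem_id"] == ecosystem_id]
    frac = sub["ecosystem_area"] / sub["total_area"]
    selected = set(sub[frac >= threshold]["unit_id"])
    if threshold == 0.0:
        selected |= set(un["unit_id"])
    return sorted(selected)


def gap_statistics(dataset: Dataset) -> pd.DataFrame:
    """Documentation-gap table: mean documented indicators per spatial unit.

    One row per (ecosystem, date, source) with the mean, over the units
    where the ecosystem is present (positive area; all units if the unit
    table has no row for it), of the number of documented indicators with
    that data-source tag — plus the expert-judgment proportion per
    ecosystem under source ``"expert_proportion"`` rows aside, returned by
    :func:`expert_proportion`.
    """
    un = dataset.units
    rows = []
    for j in dataset.ecosystem_ids:
        present = un[(un["ecosystem_id"] == j) & (un["ecosystem_area"] > 0)]["unit_id"]
        n_units = len(set(present)) or len(set(un["unit_id"]))
        for t in dataset.dates:
            sub = dataset.records
            sub = sub[(sub["ecosystem_id"] == j) & (sub["date"] == t)]
            for s in ("monitoring", "model", "expert"):
                count = int((sub["source"] == s).sum())
                rows.append({
                    "ecosystem_id": j, "date": int(t), "source": s,
                    "mean_documented_per_unit": count / n_units,
                })
    return pd.DataFrame(rows)


def expert_proportion(dataset: Dataset) -> pd.Series:
    """Share of documented values that are expert judgments, per ecosystem."""
    rec = dataset.records
    out = {}
    for j in dataset.ecosystem_ids:
        sub = rec[rec["ecosystem_id"] == j]
        out[j] = float((sub["source"] == "expert").mean()) if len(sub) else 0.0
    return pd.Series(out, name="expert_proportion")


def results_to_frame(results: Sequence[IndexResult | None]) -> pd.DataFrame:
    """Tabulate index results (gaps appear as rows of NaNs)."""
    rows = []
    for res in results:
        if res is None:
            rows.append({})
            continue
        rows.append({
            "scope": res.scope.label,
            "date": res.date,
            "median": res.median,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "n_documented": res.n_documented,
            "weight_deficit": res.weight_deficit,
            **{f"n_{s}": c for s, c in res.source_counts.items()},
        })
    return pd.DataFrame(rows)
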
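"""Hierarchical weights for aggregating scaled indicator states.

Weights W_ijkt control how documented cells combine into an index, built in
four sequential steps:

a. *Membership.* Within a major ecosystem, each indicator's base weight is
   its membership fraction for that ecosystem (an indicator representative
   of both mountain and forest may carry e.g. 0.7 / 0.3).
b. *Groups and extra-representative indicators.* Indicators flagged
   extra-representative (strongly correlated with overall ecosystem state)
   jointly receive exactly half of an ecosystem-unit slice whenever an
   ordinary indicator is documented there too (the 50% cap), the rest
   being divided equally among the trophic/functional groups present among
   documented ordinary indicators, then within each group proportionally
   to base weights. If only extra-representative indicators are documented
   they take the full share.
c. *Ecosystem equivalence.* Within a spatial unit every major ecosystem
   present (positive area) counts equally: each receives factor 1/E with E
   the number of present ecosystems — present, not merely documented, so
   that destroying an ecosystem shows up as a weight deficit rather than
   being silently renormalised away.
d. *Area.* Across spatial units, weights are proportional to area — the
   relevant ecosystem's area within each unit for a single-ecosystem
   scope, total unit area otherwise.

Undocumented cells always carry weight zero. The product of the four
factors sums to 1 over documented cells when documentation is complete;
any deficit caused by missing documentation is repaired by explicit
renormalisation at aggregation time and reported as a diagnostic.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, DatasetError

WEIGHT_COLUMNS = [
    "indicator_id", "ecosystem_id", "unit_id", "date",
    "base", "within_w", "eco_factor", "area_factor", "W",
]


def within_ecosystem_weights(slice_meta: pd.DataFrame) -> pd.Series:
    """Weights over the documented indicators of one (ecosystem, unit, date).

    ``slice_meta`` has one row per documented indicator with columns
    ``indicator_id``, ``membership`` (base weight for this ecosystem),
    ``group_id`` and ``extra_representative``. Returns weights indexed by
    indicator_id, summing to 1.
    """
    if len(slice_meta) == 0:
        raise DatasetError("no documented indicators in ecosystem-unit slice")
    sm = slice_meta.set_index("indicator_id")
    base = sm["membership"].astype(float)
    extra = sm["extra_representative"].astype(bool)
    w = pd.Series(0.0, index=sm.index)

    n_extra = int(extra.sum())
    n_ordinary = len(sm) - n_extra
    if n_extra and n_ordinary:
        extra_share = 0.5
    elif n_extra:
        extra_share = 1.0
    else:
        extra_share = 0.0

    if n_extra:
        eb = base[extra]
        w[extra] = extra_share * (eb / eb.sum() if eb.sum() > 0 else 1.0 / n_extra)
    if n_ordinary:
        ordinary = ~extra
        groups = sm.loc[ordinary, "group_id"].unique()
        group_share = (1.0 - extra_share) / len(groups)
        for g in groups:
            members = ordinary & (sm["group_id"] == g)
            gb = base[members]
            w[members] = group_share * (
                gb / gb.sum() if gb.sum() > 0 else 1.0 / members.sum()
            )
    total = w.sum()
    if total <= 0:
        raise DatasetError("degenerate weights: slice weights sum to zero")
    return w / total


def across_ecosystem_factor(dataset: Dataset, unit_id: str,
                            ecosystems: Sequence[str]) -> float:
    """Equal-share factor 1/E; E = ecosystems present (area > 0) in the unit."""
    un = dataset.units
    present = un[(un["unit_id"] == unit_id) & (un["ecosystem_area"] > 0)]["ecosystem_id"]
    e = len(set(present) & set(ecosystems))
    if e == 0:
        raise DatasetError(f"no ecosystem of scope present in unit {unit_id!r}")
    return 1.0 / e


def area_weights(dataset: Dataset, unit_ids: Sequence[str],
                 ecosystem_id: str | None = None) -> pd.Series:
    """Per-unit factors proportional to area over the selection, summing to 1.

    For a single-ecosystem scope pass ``ecosystem_id``: that ecosystem's
    area within each unit is used (falling back to total unit area when the
    unit has no row for it); otherwise total unit area.
    """
    un = dataset.units
    totals = un.drop_duplicates("unit_id").set_index("unit_id")["total_area"]
    areas = {}
    for k in unit_ids:
        if k not in totals.index:
            raise DatasetError(f"unknown unit {k!r}")
        if ecosystem_id is not None:
            sub = un[(un["unit_id"] == k) & (un["ecosystem_id"] == ecosystem_id)]
            areas[k] = float(sub["ecosystem_area"].iloc[0]) if len(sub) else float(totals[k])
        else:
            areas[k] = float(totals[k])
    s = pd.Series(areas)
    total = s.sum()
    if total <= 0:
        raise DatasetError("selected units have zero total area")
    return s / total


def weight_table(
    dataset: Dataset,
    date: int,
    ecosystems: Iterable[str] | None = None,
    units: Iterable[str] | None = None,
    indicators: Iterable[str] | None = None,
) -> pd.DataFrame:
    """The full weight table W_ijkt for one date and aggregation scope.

    One row per documented cell in scope, carrying the audit trail (base
    membership, within-slice weight, ecosystem factor, area factor) and
    the final product W. W sums to 1 when every present ecosystem of every
    selected unit is documented; otherwise the deficit 1 - sum(W) measures
    missing documentation and is renormalised away at aggregation time.
    """
    scope_units = sorted(units) if units is not None else dataset.unit_ids
    scope_ecos = sorted(ecosystems) if ecosystems is not None else dataset.ecosystem_ids
    if not scope_units or not scope_ecos:
        raise DatasetError("empty aggregation scope")
    single_eco = len(scope_ecos) == 1

    rec = dataset.records
    rec = rec[(rec["date"] == int(date))
              & rec["unit_id"].isin(scope_units)
              & rec["ecosystem_id"].isin(scope_ecos)]
    if indicators is not None:
        rec = rec[rec["indicator_id"].isin(set(indicators))]

    area = area_weights(dataset, scope_units,
                        ecosystem_id=scope_ecos[0] if single_eco else None)
    meta = dataset.meta

    rows = []
    for k in scope_units:
        urec = rec[rec["unit_id"] == k]
        if len(urec) == 0:
            continue
        for j in sorted(urec["ecosystem_id"].unique()):
            doc_ids = urec[urec["ecosystem_id"] == j]["indicator_id"]
            sm = meta[(meta["ecosystem_id"] == j) & meta["indicator_id"].isin(doc_ids)]
            w_within = within_ecosystem_weights(
                sm[["indicator_id", "membership", "group_id", "extra_representative"]]
            )
            eco_f = 1.0 if single_eco else across_ecosystem_factor(dataset, k, scope_ecos)
            for i, wv in w_within.items():
                rows.append({
                    "indicator_id": i, "ecosystem_id": j, "unit_id": k,
                    "date": int(date),
                    "base": float(sm.set_index("indicator_id").loc[i, "membership"]),
                    "within_w": float(wv),
                    "eco_factor": eco_f,
                    "area_factor": float(area[k]),
                    "W": float(wv) * eco_f * float(area[k]),
                })
    return pd.DataFrame(rows, columns=WEIGHT_COLUMNS)


def thematic_mask(
    weights: pd.DataFrame,
    indicators: Iterable[str] | None = None,
    ecosystems: Iterable[str] | None = None,
    units: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Binary thematic overlay: keep only cells in the theme, renormalise.

    A thematic sub-index (e.g. top predators, an acidification-sensitive
    set) selects indicators / ecosystems / units with binary weights; the
    surviving weights are rescaled to sum to 1.
    """
    m = pd.Series(True, index=weights.index)
    if indicators is not None:
        m &= weights["indicator_id"].isin(set(indicators))
    if ecosystems is not None:
        m &= weights["ecosystem_id"].isin(set(ecosystems))
    if units is not None:
        m &= weights["unit_id"].isin(set(units))
    masked = weights[m].copy()
    total = masked["W"].sum()
    if len(masked) == 0 or total <= 0:
        raise DatasetError("thematic selection contains no documented weight")
    masked["W"] = masked["W"] / total
    return masked.reset_index(drop=True)
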
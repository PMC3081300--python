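"""Shared fixtures: compact builders for hand-sized datasets."""

from __future__ import annotations

import pandas as pd
import pytest

from natureindex import load_dataset


def build_dataset(
    records: list[dict],
    references: list[dict] | None = None,
    meta: list[dict] | None = None,
    units: list[dict] | None = None,
    dates=None,
):
    """Assemble a validated dataset from terse row dicts.

    Missing tables are synthesised with benign defaults: reference value 50
    under the minimal model for every documented (indicator, ecosystem,
    unit); membership 1 in group "g1", not extra-representative; every unit
    100 km² fully covered by each ecosystem it hosts a record for.
    """
    rec_rows = []
    for r in records:
        rec_rows.append({
            "indicator_id": r["i"], "ecosystem_id": r.get("j", "eco"),
            "unit_id": r.get("k", "unit"), "date": r.get("t", 2010),
            "mean_value": r.get("mean", 50.0),
            "q25": r.get("q25", r.get("mean", 50.0)),
            "q75": r.get("q75", r.get("mean", 50.0)),
            "source": r.get("source", "expert"),
            "variable_kind": r.get("kind", "continuous"),
            "duplication_group": r.get("dup"),
        })
    rec = pd.DataFrame(rec_rows)

    if references is None:
        references = [
            {"i": i, "j": j, "k": k}
            for i, j, k in rec[["indicator_id", "ecosystem_id", "unit_id"]]
            .drop_duplicates().itertuples(index=False)
        ]
    ref = pd.DataFrame([{
        "indicator_id": r["i"], "ecosystem_id": r.get("j", "eco"),
        "unit_id": r.get("k", "unit"), "ref_value": r.get("ref", 50.0),
        "definition_tag": r.get("tag", "carrying_capacity"),
        "scaling_model": r.get("model", "minimal"),
    } for r in references])

    if meta is None:
        meta = [
            {"i": i, "j": j}
            for i, j in rec[["indicator_id", "ecosystem_id"]]
            .drop_duplicates().itertuples(index=False)
        ]
    met = pd.DataFrame([{
        "indicator_id": m["i"], "ecosystem_id": m.get("j", "eco"),
        "membership": m.get("membership", 1.0),
        "group_id": m.get("group", "g1"),
        "extra_representative": m.get("extra", False),
    } for m in meta])

    if units is None:
        pairs = rec[["unit_id", "ecosystem_id"]].drop_duplicates()
        units = [
            {"k": k, "j": j} for k, j in pairs.itertuples(index=False)
        ]
    un = pd.DataFrame([{
        "unit_id": u["k"], "total_area": u.get("area", 100.0),
        "ecosystem_id": u.get("j", "eco"),
        "ecosystem_area": u.get("eco_area", u.get("area", 100.0)),
    } for u in units])

    return load_dataset(rec, ref, met, un, dates=dates)


@pytest.fixture
def dataset_builder():
    return build_dataset
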
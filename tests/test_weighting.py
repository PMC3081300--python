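"""Hierarchical weighting: membership, groups, the 50% cap, areas, themes."""

import numpy as np
import pandas as pd
import pytest

from natureindex import (
    DatasetError, GeneratorConfig, area_weights, generate, thematic_mask,
    weight_table, within_ecosystem_weights,
)
from natureindex.weighting import across_ecosystem_factor
from conftest import build_dataset


def _slice(rows):
    return pd.DataFrame(rows, columns=[
        "indicator_id", "membership", "group_id", "extra_representative"])


def test_single_documented_indicator_gets_full_weight():
    w = within_ecosystem_weights(_slice([("a", 1.0, "g1", False)]))
    assert w["a"] == 1.0


def test_extra_representative_cap_hand_example():
    # 1 extra-representative + groups A (2 ordinary) and B (3 ordinary):
    # extra takes 0.5; A indicators 0.125 each; B indicators 1/12 each
    w = within_ecosystem_weights(_slice([
        ("x", 1.0, "gx", True),
        ("a1", 1.0, "A", False), ("a2", 1.0, "A", False),
        ("b1", 1.0, "B", False), ("b2", 1.0, "B", False), ("b3", 1.0, "B", False),
    ]))
    assert w["x"] == pytest.approx(0.5, abs=1e-12)
    assert w["a1"] == pytest.approx(0.125, abs=1e-12)
    assert w["a2"] == pytest.approx(0.125, abs=1e-12)
    for b in ("b1", "b2", "b3"):
        assert w[b] == pytest.approx(1 / 12, abs=1e-12)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_only_extra_representatives_take_full_share():
    w = within_ecosystem_weights(_slice([
        ("x1", 1.0, "gx", True), ("x2", 1.0, "gy", True)]))
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert w["x1"] == pytest.approx(0.5, abs=1e-12)


def test_membership_fractions_are_base_weights():
    # an indicator split 0.7 mountain / 0.3 forest enters each slice with
    # its membership as base weight
    ds = build_dataset(
        [{"i": "ptarmigan", "j": "mountain"}, {"i": "ptarmigan", "j": "forest"},
         {"i": "moose", "j": "forest"}],
        references=[{"i": "ptarmigan", "j": "mountain"},
                    {"i": "ptarmigan", "j": "forest"}, {"i": "moose", "j": "forest"}],
        meta=[{"i": "ptarmigan", "j": "mountain", "membership": 0.7},
              {"i": "ptarmigan", "j": "forest", "membership": 0.3},
              {"i": "moose", "j": "forest", "membership": 1.0, "group": "g2"}],
        units=[{"k": "unit", "j": "mountain", "eco_area": 40.0},
               {"k": "unit", "j": "forest", "eco_area": 60.0}],
    )
    wt = weight_table(ds, 2010)
    base = wt.set_index(["indicator_id", "ecosystem_id"])["base"]
    assert base[("ptarmigan", "mountain")] == 0.7
    assert base[("ptarmigan", "forest")] == 0.3
    assert wt["W"].sum() == pytest.approx(1.0, abs=1e-9)


def test_across_ecosystem_factor_counts_present_ecosystems():
    units = [{"k": "u", "j": f"e{n}", "eco_area": 10.0} for n in range(3)]
    ds = build_dataset(
        [{"i": "a", "j": "e0", "k": "u"}],
        references=[{"i": "a", "j": "e0", "k": "u"}],
        meta=[{"i": "a", "j": "e0"}],
        units=units,
    )
    assert across_ecosystem_factor(ds, "u", ["e0", "e1", "e2"]) == pytest.approx(1 / 3)
    assert across_ecosystem_factor(ds, "u", ["e0"]) == 1.0


def test_undocumented_present_ecosystem_leaves_weight_deficit():
    # three present ecosystems, one undocumented: raw weights sum to 2/3
    units = [{"k": "u", "j": f"e{n}", "eco_area": 10.0} for n in range(3)]
    ds = build_dataset(
        [{"i": "a", "j": "e0", "k": "u"}, {"i": "b", "j": "e1", "k": "u"}],
        references=[{"i": "a", "j": "e0", "k": "u"}, {"i": "b", "j": "e1", "k": "u"}],
        meta=[{"i": "a", "j": "e0"}, {"i": "b", "j": "e1"}],
        units=units,
    )
    wt = weight_table(ds, 2010)
    assert wt["W"].sum() == pytest.approx(2 / 3, abs=1e-9)
    assert np.allclose(wt["eco_factor"], 1 / 3)


@pytest.mark.parametrize("areas, expected", [
    ((100.0, 100.0), (0.5, 0.5)),
    ((100.0, 300.0), (0.25, 0.75)),
])
def test_area_weights_proportional(areas, expected):
    ds = build_dataset(
        [{"i": "a", "k": "u1"}, {"i": "a", "k": "u2"}],
        references=[{"i": "a", "k": "u1"}, {"i": "a", "k": "u2"}],
        units=[{"k": "u1", "area": areas[0]}, {"k": "u2", "area": areas[1]}],
    )
    w = area_weights(ds, ["u1", "u2"])
    assert w["u1"] == pytest.approx(expected[0])
    assert w["u2"] == pytest.approx(expected[1])


def test_single_ecosystem_scope_uses_ecosystem_area():
    ds = build_dataset(
        [{"i": "a", "j": "m", "k": "u1"}, {"i": "a", "j": "m", "k": "u2"}],
        references=[{"i": "a", "j": "m", "k": "u1"}, {"i": "a", "j": "m", "k": "u2"}],
        meta=[{"i": "a", "j": "m"}],
        units=[{"k": "u1", "j": "m", "area": 100.0, "eco_area": 10.0},
               {"k": "u2", "j": "m", "area": 100.0, "eco_area": 30.0}],
    )
    w = area_weights(ds, ["u1", "u2"], ecosystem_id="m")
    assert w["u1"] == pytest.approx(0.25)
    assert w["u2"] == pytest.approx(0.75)
    wt = weight_table(ds, 2010, ecosystems=["m"])
    assert wt["W"].sum() == pytest.approx(1.0, abs=1e-9)


def test_conservation_on_random_synthetic_datasets():
    for seed in range(5):
        synth = generate(GeneratorConfig(
            n_units=4, n_ecosystems=3, n_indicators=4, dates=(2000, 2010),
            missing_prob=0.0, seed=seed))
        ds = synth.dataset
        for t in ds.dates:
            wt = weight_table(ds, t)
            assert wt["W"].sum() == pytest.approx(1.0, abs=1e-9)
            for j in ds.ecosystem_ids:
                wj = weight_table(ds, t, ecosystems=[j])
                assert wj["W"].sum() == pytest.approx(1.0, abs=1e-9)


def test_extra_representative_share_capped_at_half():
    for seed in range(5):
        synth = generate(GeneratorConfig(
            n_units=3, n_ecosystems=2, n_indicators=6,
            extra_representative_fraction=0.5, dates=(2010,), seed=seed))
        ds = synth.dataset
        wt = weight_table(ds, 2010)
        extra_ids = set(ds.meta[ds.meta["extra_representative"]]["indicator_id"])
        for (j, k), grp in wt.groupby(["ecosystem_id", "unit_id"]):
            share = grp[grp["indicator_id"].isin(extra_ids)]["within_w"].sum()
            ordinary = (~grp["indicator_id"].isin(extra_ids)).any()
            if ordinary:
                assert share <= 0.5 + 1e-9


def test_thematic_mask_identity_and_single_indicator():
    ds = build_dataset([
        {"i": "a"}, {"i": "b"}],
        meta=[{"i": "a", "group": "g1"}, {"i": "b", "group": "g2"}],
    )
    wt = weight_table(ds, 2010)
    same = thematic_mask(wt, indicators=["a", "b"])
    pd.testing.assert_series_equal(same["W"], wt["W"])
    only_a = thematic_mask(wt, indicators=["a"])
    assert len(only_a) == 1 and only_a["W"].iloc[0] == pytest.approx(1.0)


def test_thematic_group_mask_renormalises():
    ds = build_dataset(
        [{"i": n} for n in ("a", "b", "c", "d")],
        meta=[{"i": "a", "group": "top_pred"}, {"i": "b", "group": "top_pred"},
              {"i": "c", "group": "other"}, {"i": "d", "group": "other"}],
    )
    wt = weight_table(ds, 2010)
    theme = thematic_mask(wt, indicators=["a", "b"])
    assert theme["W"].sum() == pytest.approx(1.0, abs=1e-9)


def test_empty_thematic_selection_rejected():
    ds = build_dataset([{"i": "a"}])
    wt = weight_table(ds, 2010)
    with pytest.raises(DatasetError):
        thematic_mask(wt, indicators=["nope"])


def test_group_equalisation_tends_to_uniform():
    # equally many identical-membership ordinary indicators per group ->
    # uniform weights within the slice
    rows = []
    for g in ("g1", "g2", "g3"):
        for n in range(4):
            rows.append((f"{g}_{n}", 1.0, g, False))
    w = within_ecosystem_weights(_slice(rows))
    assert np.allclose(w, 1 / 12, atol=1e-12)
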
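"""Index computation, date comparisons, trends, filters and gap statistics."""

import numpy as np
import pytest

from natureindex import (
    DatasetError, GeneratorConfig, Scope, compare_dates, expert_proportion,
    gap_statistics, generate, mountain_filter, nature_index, simulate_scaled,
    trend_series,
)
from conftest import build_dataset


def _two_cell_dataset(mean_a=10.0, mean_b=30.0):
    # two point-mass indicators (zero elicited spread), ref 50, minimal:
    # scaled constants mean/50
    return build_dataset(
        [{"i": "a", "mean": mean_a}, {"i": "b", "mean": mean_b}],
        meta=[{"i": "a", "group": "g1"}, {"i": "b", "group": "g2"}],
    )


def test_weighted_mean_of_constant_cells():
    # weights 0.5/0.5 over scaled constants 0.2 and 0.6 -> index 0.4 exactly
    ds = _two_cell_dataset()
    res = nature_index(ds, 2010, n_sim=99, seed=0)
    assert res.median == pytest.approx(0.4, abs=1e-12)
    assert res.ci_low == pytest.approx(0.4, abs=1e-12)
    assert res.ci_high == pytest.approx(0.4, abs=1e-12)
    assert res.n_documented == 2


def test_all_optimal_cells_give_index_one():
    ds = build_dataset([{"i": "a", "mean": 50.0}, {"i": "b", "mean": 50.0}])
    res = nature_index(ds, 2010, n_sim=99, seed=0)
    assert res.median == pytest.approx(1.0, abs=1e-12)
    assert res.ci_high - res.ci_low == 0.0


def test_single_cell_index_equals_cell_vector():
    ds = build_dataset([{"i": "a", "mean": 40.0, "q25": 35.0, "q75": 45.0}])
    scaled = simulate_scaled(ds, n_sim=199, seed=4)
    res = nature_index(ds, 2010, scaled=scaled)
    np.testing.assert_allclose(
        res.sims, scaled.values[("a", "eco", "unit", 2010)], rtol=0, atol=1e-15)


def test_empty_scope_errors_with_explicit_signal():
    ds = build_dataset([{"i": "a"}])
    with pytest.raises(DatasetError, match="no documented indicators"):
        nature_index(ds, 1950, n_sim=9, seed=0)


def test_index_draws_stay_in_unit_interval():
    synth = generate(GeneratorConfig(noise=0.3, seed=11))
    res = nature_index(synth.dataset, 1990, n_sim=499, seed=2)
    assert (res.sims >= 0).all() and (res.sims <= 1).all()
    assert res.ci_low <= res.median <= res.ci_high


def test_source_counts_reported():
    ds = build_dataset([
        {"i": "a", "source": "monitoring"},
        {"i": "b", "source": "expert"},
        {"i": "c", "source": "expert"},
    ], meta=[{"i": "a"}, {"i": "b", "group": "g2"}, {"i": "c", "group": "g3"}])
    res = nature_index(ds, 2010, n_sim=9, seed=0)
    assert res.source_counts == {"monitoring": 1, "model": 0, "expert": 2}


# -- comparisons -----------------------------------------------------------


def test_tie_convention_gives_half():
    ds = _two_cell_dataset()
    scaled = simulate_scaled(ds, n_sim=99, seed=0)
    r = nature_index(ds, 2010, scaled=scaled)
    cmp = compare_dates(r, r)
    assert cmp.p_one_sided == pytest.approx(0.5)
    assert cmp.p_two_sided == pytest.approx(1.0)


def test_clear_separation_gives_extreme_p():
    ds = build_dataset([
        {"i": "a", "t": 2000, "mean": 45.0},   # scaled 0.9
        {"i": "a", "t": 2010, "mean": 20.0},   # scaled 0.4
    ])
    scaled = simulate_scaled(ds, n_sim=999, seed=0)
    r1 = nature_index(ds, 2000, scaled=scaled)
    r2 = nature_index(ds, 2010, scaled=scaled)
    cmp = compare_dates(r1, r2)
    assert cmp.p_one_sided == 1.0
    assert cmp.p_two_sided < 1 / 999
    assert cmp.median_difference == pytest.approx(0.5, abs=1e-12)


def test_mismatched_scopes_rejected():
    synth = generate(GeneratorConfig(dates=(2000, 2010), seed=0))
    ds = synth.dataset
    scaled = simulate_scaled(ds, n_sim=49, seed=0)
    r1 = nature_index(ds, 2000, scope=Scope.make(ecosystems=["eco0"]), scaled=scaled)
    r2 = nature_index(ds, 2010, scope=Scope.make(ecosystems=["eco1"]), scaled=scaled)
    with pytest.raises(DatasetError, match="scope"):
        compare_dates(r1, r2)


# -- trends ----------------------------------------------------------------


def test_trend_recovers_drifting_truth():
    synth = generate(GeneratorConfig(true_states=(1.0, 0.83, 0.66, 0.5),
                                     missing_prob=0.0, seed=9))
    series = trend_series(synth.dataset, n_sim=499, seed=3)
    medians = [r.median for _, r in series]
    assert all(np.diff(medians) < 0)


def test_single_date_series():
    ds = build_dataset([{"i": "a"}])
    series = trend_series(ds, n_sim=9, seed=0)
    assert len(series) == 1 and series[0][0] == 2010


def test_undocumented_date_yields_gap_entry():
    ds = build_dataset([{"i": "a", "t": 2010}], dates=[2000, 2010])
    series = trend_series(ds, n_sim=9, seed=0)
    assert len(series) == 2
    assert series[0] == (2000, None)
    assert series[1][1] is not None


# -- unit filtering --------------------------------------------------------


def _units_with_fractions(fracs):
    units, refs, recs = [], [], []
    for n, f in enumerate(fracs):
        k = f"u{n}"
        units.append({"k": k, "j": "mountain", "area": 100.0, "eco_area": 100.0 * f})
        refs.append({"i": "a", "j": "mountain", "k": k})
        recs.append({"i": "a", "j": "mountain", "k": k})
    return build_dataset(recs, references=refs,
                         meta=[{"i": "a", "j": "mountain"}], units=units)


def test_mountain_area_threshold():
    ds = _units_with_fractions([0.199, 0.2, 0.5, 1.0])
    assert mountain_filter(ds, "mountain", 0.2) == ["u1", "u2", "u3"]
    assert mountain_filter(ds, "mountain", 0.0) == ["u0", "u1", "u2", "u3"]
    assert mountain_filter(ds, "mountain", 1.0) == ["u3"]


# -- gap statistics --------------------------------------------------------


def test_gap_statistics_hand_count():
    # 2 units; 3 and 5 documented expert-tagged indicators -> mean 4.0
    recs = [{"i": f"i{n}", "k": "u1"} for n in range(3)]
    recs += [{"i": f"i{n}", "k": "u2"} for n in range(5)]
    refs = [{"i": f"i{n}", "k": k} for n in range(5) for k in ("u1", "u2")]
    ds = build_dataset(
        recs, references=refs,
        meta=[{"i": f"i{n}"} for n in range(5)],
        units=[{"k": "u1"}, {"k": "u2"}],
    )
    table = gap_statistics(ds)
    row = table[(table["source"] == "expert")].iloc[0]
    assert row["mean_documented_per_unit"] == pytest.approx(4.0)
    assert (table[table["source"] != "expert"]["mean_documented_per_unit"] == 0).all()
    assert expert_proportion(ds)["eco"] == pytest.approx(1.0)


def test_gap_statistics_empty_records():
    ds = build_dataset([{"i": "a", "t": 2010}], dates=[2000, 2010])
    table = gap_statistics(ds)
    assert (table[table["date"] == 2000]["mean_documented_per_unit"] == 0).all()


# -- consistency and CI behaviour -----------------------------------------


def test_country_index_is_area_weighted_mean_of_unit_indexes():
    synth = generate(GeneratorConfig(
        noise=0.0, missing_prob=0.0, duplication_prob=0.0,
        true_states=0.6, seed=21))
    ds = synth.dataset
    scaled = simulate_scaled(ds, n_sim=49, seed=0)
    country = nature_index(ds, 1990, scaled=scaled)
    totals = ds.units.drop_duplicates("unit_id").set_index("unit_id")["total_area"]
    acc = np.zeros(49)
    for k in ds.unit_ids:
        res_k = nature_index(ds, 1990, scope=Scope.make(units=[k]), scaled=scaled)
        acc += (totals[k] / totals.sum()) * res_k.sims
    np.testing.assert_allclose(country.sims, acc, atol=1e-12)


def test_ci_width_shrinks_with_elicited_spread():
    widths = []
    for rel in (0.4, 0.1, 0.0):
        ds = build_dataset([{
            "i": "a", "mean": 25.0, "q25": 25.0 * (1 - rel), "q75": 25.0 * (1 + rel)}])
        res = nature_index(ds, 2010, n_sim=999, seed=5)
        widths.append(res.ci_high - res.ci_low)
    assert widths[0] > widths[1] > widths[2]
    assert widths[2] == 0.0
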
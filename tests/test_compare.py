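import itertools

import numpy as np
import pandas as pd
import pytest

from urbanveg.compare import (
    aggregate_distribution,
    city_season_summary,
    event_level_deltas,
    regional_split,
    significance_median,
)


def wilcoxon_enumeration_p(values):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    v = np.asarray(values, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(v))) + 1.0
    w_obs = ranks[v > 0].sum()
    total = ranks.sum()
    count = 0
    n_assign = 0
    for signs in itertools.product([0, 1], repeat=len(v)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        # two-sided: as or more extreme in either direction
        if min(w, total - w) <= min(w_obs, total - w_obs):
            count += 1
        n_assign += 1
    return count / n_assign


class TestSignificanceMedian:
    def test_ten_positive_matches_enumeration(self):
        values = np.arange(1, 11, dtype=float)
        p = significance_median(values)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)
        assert p == pytest.approx(wilcoxon_enumeration_p(values), rel=1e-9)

    def test_enumeration_oracle_random_small_samples(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            values = rng.normal(0.3, 1.0, n)
            assert significance_median(values) == pytest.approx(
                wilcoxon_enumeration_p(values), rel=1e-9
            )

    def test_symmetric_values_insignificant(self):
        values = np.array([-1.0, 1.0] * 6) + np.tile([1e-9, -1e-9], 6)
        assert significance_median(values) > 0.5

    def test_n_equals_one(self):
        assert significance_median([0.3]) == 1.0

    def test_all_zero_convention(self):
        assert significance_median(np.zeros(8)) == 1.0


def make_records(urban_vals, rural_vals, city="c", season="JJA"):
    rows = []
    for area, vals in (("urban", urban_vals), ("rural", rural_vals)):
        for i, v in enumerate(vals):
            rows.append(
                {"city": city, "dataset": "m0", "pixel": i, "area": area,
                 "event": 0, "season": season, "duration": 3, "intensity": 2.0,
                 "overlap": False, "resistance": v, "recovery": v / 2,
                 "valid_resistance": True, "valid_recovery": True}
            )
    return pd.DataFrame(rows)


class TestCitySeasonSummary:
    def test_opposite_signs(self):
        df = make_records([0.5] * 4, [-0.5] * 4)
        out = city_season_summary(df)
        row = out[out["metric"] == "resistance"].iloc[0]
        assert row["urban_frac_pos"] == 1.0
        assert row["rural_frac_pos"] == 0.0
        assert row["delta_frac_pos"] == pytest.approx(1.0)
        assert row["delta_median_abs"] == pytest.approx(0.0)

    def test_single_record(self):
        df = make_records([0.2], [])
        row = city_season_summary(df)
        r = row[row["metric"] == "resistance"].iloc[0]
        assert r["urban_frac_pos"] == 1.0
        assert r["urban_median_raw"] == pytest.approx(0.2)
        assert r["rural_n"] == 0
        assert np.isnan(r["rural_median_raw"])

    def test_mixed_signs(self):
        df = make_records([-0.1, 0.1], [])
        r = city_season_summary(df)
        r = r[r["metric"] == "resistance"].iloc[0]
        assert r["urban_frac_pos"] == 0.5
        assert r["urban_median_abs"] == pytest.approx(0.1)

    def test_decomposition_consistency(self, rng):
        """Pooled |median| lies within the range spanned by the positive-only
        and negative-only magnitude medians."""
        vals = rng.normal(0.05, 0.3, 200)
        df = make_records(vals, [])
        r = city_season_summary(df)
        r = r[r["metric"] == "resistance"].iloc[0]
        lo = min(r["urban_median_abs_pos"], r["urban_median_abs_neg"])
        hi = max(r["urban_median_abs_pos"], r["urban_median_abs_neg"])
        assert lo - 1e-12 <= r["urban_median_abs"] <= hi + 1e-12


class TestAggregateDistribution:
    def test_linear_interpolation_example(self):
        out = aggregate_distribution([1, 2, 3, 4, 5])
        assert out["p5"] == pytest.approx(1.2)
        assert out["p25"] == pytest.approx(2.0)
        assert out["p50"] == pytest.approx(3.0)
        assert out["p75"] == pytest.approx(4.0)
        assert out["p95"] == pytest.approx(4.8)

    def test_constant(self):
        out = aggregate_distribution(np.full(10, 0.7))
        assert all(out[f"p{p}"] == pytest.approx(0.7) for p in (5, 25, 50, 75, 95))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_distribution([])


class TestRegionalSplit:
    def test_all_west_flags_empty_east(self):
        df = make_records([0.5] * 3, [-0.5] * 3)
        stats = city_season_summary(df)
        out = regional_split(stats, {"c": "west"})
        assert set(out["region"]) == {"west"}

    def test_split_preserves_medians(self):
        a = make_records([0.5] * 3, [0.1] * 3, city="a")
        b = make_records([-0.5] * 3, [0.1] * 3, city="b")
        stats = city_season_summary(pd.concat([a, b], ignore_index=True))
        out = regional_split(stats, {"a": "east", "b": "west"})
        east = out[(out["region"] == "east") & (out["metric"] == "resistance")]
        west = out[(out["region"] == "west") & (out["metric"] == "resistance")]
        assert east["delta_frac_pos_median"].iloc[0] == pytest.approx(0.0)
        assert west["delta_frac_pos_median"].iloc[0] == pytest.approx(-1.0)


def test_event_level_deltas_shape(small_scene):
    from urbanveg.workbench import process_scene

    out = process_scene(small_scene)
    deltas = event_level_deltas(out["records"])
    assert {"delta_frac_pos", "delta_median_abs"} <= set(deltas.columns)
    assert set(deltas["metric"]) == {"resistance", "recovery"}
    # one row per (event, metric)
    n_events = out["records"]["event"].nunique()
    assert len(deltas) == 2 * n_events
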
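import numpy as np
import pandas as pd
import pytest

from seedviab import (
    ExpansionConfig,
    binned_curve,
    box_stats,
    compare_groups,
    expand,
    seed_composition,
    split_differential,
)
from seedviab.viabstats import NUCLEOTIDES


def literal_expand(table, weight_column, divisor):
    """Brute-force oracle: literally replicate each row's viability."""
    values = []
    for _, row in table.iterrows():
        copies = int(np.floor(row[weight_column] / divisor + 0.5))
        values.extend([row["viability"]] * copies)
    return np.array(values)


def test_expand_definition_and_rounding_floor_out():
    table = pd.DataFrame({"seed": ["AAAAAA"], "viability": [40.0], "w": [3000.0]})
    ev = expand(table, "w")
    assert sorted(ev.values) == [40.0, 40.0, 40.0]

    table.loc[0, "w"] = 400.0
    ev = expand(table, "w")
    assert ev.n == 0
    assert ev.n_dropped_rows == 1


def test_expand_rejects_negative_weights():
    table = pd.DataFrame({"seed": ["AAAAAA"], "viability": [40.0], "w": [-5.0]})
    with pytest.raises(ValueError, match="negative"):
        expand(table, "w")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_expand_matches_literal_replication_oracle(random_annotated, seed):
    rng = np.random.default_rng(seed)
    table = random_annotated(rng, 100)
    ev = expand(table, "weight")
    np.testing.assert_array_equal(
        np.sort(ev.values), np.sort(literal_expand(table, "weight", 1000))
    )


def test_box_stats_three_point_quantiles():
    bs = box_stats(np.array([10.0, 20.0, 30.0]))
    assert (bs.q1, bs.median, bs.q3) == (15.0, 20.0, 25.0)
    assert bs.outliers == ()


def test_box_stats_constant_data():
    bs = box_stats(np.full(100, 50.0))
    assert bs.median == bs.q1 == bs.q3 == 50.0
    assert bs.whisker_low == bs.whisker_high == 50.0
    assert bs.outliers == ()


def test_box_stats_median_matches_order_statistics_oracle():
    rng = np.random.default_rng(3)
    values = rng.uniform(0, 120, 500)
    bs = box_stats(values)
    s = np.sort(values)
    # 500 points: median is the mean of the 250th/251st order statistics
    assert bs.median == pytest.approx((s[249] + s[250]) / 2)
    assert bs.q1 <= bs.median <= bs.q3


def test_box_whiskers_and_outliers_follow_the_1p5_iqr_rule():
    rng = np.random.default_rng(8)
    for _ in range(20):
        values = rng.normal(60, 15, int(rng.integers(5, 400)))
        bs = box_stats(values)
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        inside = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
        assert bs.whisker_low == inside.min()
        assert bs.whisker_high == inside.max()
        expected_out = sorted(values[(values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)])
        assert list(bs.outliers) == pytest.approx(expected_out)


def test_compare_groups_identical_multisets_give_p_one():
    with pytest.warns(UserWarning, match="identical"):
        h, p = compare_groups([np.array([5.0, 5.0]), np.array([5.0, 5.0, 5.0])])
    assert (h, p) == (0.0, 1.0)


def test_compare_groups_hand_computed_rank_sums():
    # groups {1,2,3} and {101,102,103}: ranks 1-3 vs 4-6, no ties
    # H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 27/7
    h, p = compare_groups([np.array([1.0, 2.0, 3.0]), np.array([101.0, 102.0, 103.0])])
    assert h == pytest.approx(27 / 7)
    assert p < 0.06


def test_compare_groups_invariant_to_group_order():
    rng = np.random.default_rng(21)
    a, b, c = (rng.uniform(0, 100, n) for n in (30, 40, 50))
    h1, p1 = compare_groups([a, b, c])
    h2, p2 = compare_groups([c, a, b])
    assert h1 == pytest.approx(h2, rel=1e-12)
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_split_differential_partitions_by_delta_sign():
    table = pd.DataFrame(
        {"seed": ["AAAAAA"] * 3, "viability": [50.0] * 3, "delta": [10.0, -4.0, 7.0]}
    )
    enriched, depleted = split_differential(table)
    assert enriched["weight"].tolist() == [10.0, 7.0]
    assert depleted["weight"].tolist() == [4.0]


def test_binned_curve_collapses_then_bins():
    table = pd.DataFrame(
        {
            "seed": ["AAAAAA", "AAAAAA"],
            "rna_type": ["miRNA", "miRNA"],
            "viability": [19.2, 19.2],
            "w": [100.0, 200.0],
        }
    )
    curve = binned_curve(table, "w", bin_width=1.0)
    assert curve["weight"].sum() == 300.0
    assert curve.loc[curve["bin_left"] == 19.0, "weight"].item() == 300.0


def test_binned_curve_half_open_bins():
    table = pd.DataFrame(
        {
            "seed": ["AAAAAA", "AAAAAC"],
            "rna_type": ["miRNA", "miRNA"],
            "viability": [19.2, 19.9],
            "w": [1.0, 2.0],
        }
    )
    curve = binned_curve(table, "w", bin_width=1.0)
    assert curve.loc[curve["bin_left"] == 19.0, "weight"].item() == 3.0


@pytest.mark.parametrize("seed", [4, 5])
def test_binned_curve_matches_two_pass_oracle_and_conserves(random_annotated, seed):
    rng = np.random.default_rng(seed)
    table = random_annotated(rng, 200)
    curve = binned_curve(table, "weight", bin_width=1.0)
    # brute-force: collapse on (seed, rna_type), then accumulate per bin
    collapsed = {}
    for _, row in table.iterrows():
        key = (row["seed"], row["rna_type"])
        w, v = collapsed.get(key, (0.0, row["viability"]))
        collapsed[key] = (w + row["weight"], row["viability"])
    bins = {}
    for w, v in collapsed.values():
        bins[int(np.floor(v))] = bins.get(int(np.floor(v)), 0.0) + w
    for left, expected in bins.items():
        got = curve.loc[curve["bin_left"] == float(left), "weight"].item()
        assert got == pytest.approx(expected, rel=1e-12)
    assert curve["weight"].sum() == pytest.approx(table["weight"].sum(), rel=1e-12)


def test_seed_composition_forced_frequencies():
    table = pd.DataFrame({"seed": ["GGGGGC"], "viability": [10.0], "w": [5000.0]})
    comp = seed_composition(table, "w")
    for pos in range(1, 6):
        assert comp.loc["G", f"pos{pos}"] == 1.0
    assert comp.loc["C", "pos6"] == 1.0


def test_seed_composition_equal_weight_symmetry():
    table = pd.DataFrame(
        {"seed": ["AAAAAA", "UUUUUU"], "viability": [90.0, 80.0], "w": [2000.0, 2000.0]}
    )
    comp = seed_composition(table, "w")
    assert np.allclose(comp.loc["A"], 0.5)
    assert np.allclose(comp.loc["U"], 0.5)


def test_seed_composition_matches_literal_expansion_tally(random_annotated):
    rng = np.random.default_rng(17)
    table = random_annotated(rng, 50)
    comp = seed_composition(table, "weight")
    # brute force: expand seeds literally and count characters per position
    expanded_seeds = []
    for _, row in table.iterrows():
        copies = int(np.floor(row["weight"] / 1000 + 0.5))
        expanded_seeds.extend([row["seed"]] * copies)
    for pos in range(6):
        for nt in NUCLEOTIDES:
            freq = sum(1 for s in expanded_seeds if s[pos] == nt) / len(expanded_seeds)
            assert comp.loc[nt, f"pos{pos+1}"] == pytest.approx(freq)
    assert np.allclose(comp.sum(axis=0), 1.0)


def test_scale_equivariance_of_expansion_statistics(random_annotated):
    rng = np.random.default_rng(23)
    table = random_annotated(rng, 80)
    # make every weight an exact multiple of the divisor so nothing drops
    table["weight"] = (np.floor(table["weight"] / 1000 + 0.5) + 1) * 1000.0
    coarse = expand(table, "weight", ExpansionConfig(divisor=1000))
    fine_table = table.copy()
    fine_table["weight"] = table["weight"] / 1000.0
    fine = expand(fine_table, "weight", ExpansionConfig(divisor=1))
    assert box_stats(coarse) == box_stats(fine)
    pd.testing.assert_frame_equal(
        seed_composition(table, "weight", ExpansionConfig(divisor=1000)),
        seed_composition(fine_table, "weight", ExpansionConfig(divisor=1)),
    )


def test_adding_low_viability_weight_never_raises_the_median(random_annotated):
    rng = np.random.default_rng(29)
    table = random_annotated(rng, 60)
    ev = expand(table, "weight")
    med = np.median(ev.values)
    below = table[table["viability"] < med]
    boosted = table.copy()
    boosted.loc[below.index, "weight"] += 5000.0
    assert expand(boosted, "weight").median() <= med
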
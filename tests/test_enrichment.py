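"""Fisher/BH machinery and relative kinase activity against oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kinlink.enrichment import (bh_adjust, build_contingency, fisher_one_sided,
                                frequency_factor, kinase_enrichment,
                                relative_kinase_activity)
from kinlink.errors import ValidationError


def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) by explicit enumeration of the hypergeometric support."""
    N, K, n = a + b + c + d, a + c, a + b
    return sum(comb(K, k) * comb(N - K, n - k)
               for k in range(a, min(K, n) + 1)) / comb(N, n)


def bh_oracle(pvalues):
    """Step-up BH written independently: sort, scale by m/rank, enforce
    monotonicity from the largest rank down, cap at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


class TestContingency:
    def test_counting(self):
        fg = {f"f{i}" for i in range(10)}
        bg = {f"b{i}" for i in range(90)}
        members = {f"f{i}" for i in range(4)} | {f"b{i}" for i in range(9)}
        table = build_contingency(members, fg, bg)
        assert table.tolist() == [[4, 6], [9, 81]]

    def test_kinase_in_no_top_set(self):
        table = build_contingency(set(), {"a"}, {"b", "c"})
        assert table.tolist() == [[0, 1], [0, 2]]

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            build_contingency({"a"}, {"a", "b"}, set())


class TestFisher:
    def test_zero_foreground_hits_gives_p_one(self):
        assert fisher_one_sided([[0, 7], [3, 11]]) == pytest.approx(1.0)

    def test_perfect_separation(self):
        # all 5 hits in a foreground of 5 out of 10: 1 / C(10, 5)
        assert fisher_one_sided([[5, 0], [0, 5]]) == pytest.approx(1 / 252)

    def test_matches_enumeration_on_example(self):
        assert fisher_one_sided([[2, 8], [2, 88]]) == pytest.approx(
            hypergeom_tail_oracle(2, 8, 2, 88))

    def test_exhaustive_small_tables(self):
        # every nonnegative 2x2 table with total <= 24
        for total in range(25):
            for a, b, c in itertools.product(range(total + 1), repeat=3):
                d = total - a - b - c
                if d < 0:
                    continue
                assert fisher_one_sided([[a, b], [c, d]]) == pytest.approx(
                    hypergeom_tail_oracle(a, b, c, d), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_one_sided([[-1, 2], [3, 4]])


class TestBH:
    def test_hand_stepped_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_stepped_oracle_on_random_families(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40))).tolist()
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_adjusted_between_p_and_one(self, pvalues):
        adj = bh_adjust(pvalues)
        assert (adj >= np.asarray(pvalues) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestFrequencyFactor:
    def test_definition(self):
        # fg rate 0.4 vs bg rate 0.1 -> log2(4) = 2
        assert frequency_factor([[4, 6], [9, 81]]) == pytest.approx(2.0)

    def test_equal_rates_give_zero(self):
        assert frequency_factor([[5, 5], [50, 50]]) == pytest.approx(0.0)

    def test_zero_cell_stays_finite_via_continuity(self):
        value = frequency_factor([[3, 7], [0, 90]])
        assert np.isfinite(value)
        # +0.5 on all four cells: log2((3.5/11)/(0.5/91))
        assert value == pytest.approx(np.log2((3.5 / 11) / (0.5 / 91)))

    def test_no_continuity_when_all_cells_positive(self):
        assert frequency_factor([[2, 2], [1, 3]]) == pytest.approx(
            np.log2(0.5 / 0.25))


def _calls(up, down, total, comparison="c1"):
    sites = [f"s{i}" for i in range(total)]
    direction = ["up"] * up + ["down"] * down + ["ns"] * (total - up - down)
    return pd.DataFrame({"site": sites, "direction": direction,
                         "comparison": comparison})


class TestRelativeActivity:
    def test_most_significant_kinase_keeps_full_frequency_factor(self):
        calls = _calls(up=20, down=0, total=120)
        up_sites = set(calls.loc[calls["direction"] == "up", "site"])
        # KA hits every up site and few background; KB is uninformative
        membership = {
            "KA": up_sites | {"s30", "s31"},
            "KB": {f"s{i}" for i in range(0, 120, 2)},
            "KC": {"s40"},
        }
        enr = kinase_enrichment(membership, calls, "c1")
        act = relative_kinase_activity(enr)
        act = act.set_index("kinase")
        # KA has the smallest adj p -> normalized significance 1
        assert act.loc["KA", "activity"] == pytest.approx(
            act.loc["KA", "frequency_factor"])
        assert act.loc["KA", "direction"] == "up"
        assert act.loc["KA", "activity"] > 0

    def test_least_significant_kinase_gets_zero_activity(self):
        calls = _calls(up=20, down=0, total=120)
        up_sites = set(calls.loc[calls["direction"] == "up", "site"])
        membership = {"KA": up_sites, "KB": {"s100"}, "KC": {"s101", "s111"}}
        act = relative_kinase_activity(
            kinase_enrichment(membership, calls, "c1")).set_index("kinase")
        worst = act["adj_p"].idxmax()
        assert act.loc[worst, "activity"] == 0.0

    def test_down_direction_gives_negative_sign(self):
        calls = _calls(up=0, down=20, total=120)
        down_sites = set(calls.loc[calls["direction"] == "down", "site"])
        membership = {"KA": down_sites | {"s30"},
                      "KB": {f"s{i}" for i in range(0, 120, 3)}}
        act = relative_kinase_activity(
            kinase_enrichment(membership, calls, "c1")).set_index("kinase")
        assert act.loc["KA", "direction"] == "down"
        assert act.loc["KA", "activity"] < 0

    def test_activity_bounded_by_frequency_factor(self):
        calls = _calls(up=15, down=10, total=100)
        rng = np.random.default_rng(3)
        membership = {
            f"K{i}": {f"s{j}" for j in rng.choice(100, size=30, replace=False)}
            for i in range(8)
        }
        enr = kinase_enrichment(membership, calls, "c1")
        act = relative_kinase_activity(enr)
        max_ff = enr["frequency_factor"].abs().max()
        assert (act["activity"].abs() <= max_ff + 1e-12).all()

    def test_untestable_directions_excluded_from_family(self):
        calls = _calls(up=10, down=0, total=50)  # no down foreground
        membership = {"KA": {f"s{i}" for i in range(5)}}
        enr = kinase_enrichment(membership, calls, "c1")
        down = enr[enr["direction"] == "down"]
        assert not down["testable"].any()
        assert down["adj_p"].isna().all()

    def test_activity_invariant_under_site_relabeling(self):
        calls = _calls(up=10, down=5, total=60)
        membership = {"KA": {f"s{i}" for i in range(0, 20)},
                      "KB": {f"s{i}" for i in range(5, 40, 2)}}
        act1 = relative_kinase_activity(kinase_enrichment(membership, calls, "c1"))
        shuffled = calls.sample(frac=1.0, random_state=0).reset_index(drop=True)
        act2 = relative_kinase_activity(kinase_enrichment(membership, shuffled, "c1"))
        merged = act1.merge(act2, on="kinase", suffixes=("_a", "_b"))
        assert merged["activity_a"].to_numpy() == pytest.approx(
            merged["activity_b"].to_numpy())
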
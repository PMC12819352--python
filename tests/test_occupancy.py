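"""Shared-occupancy statistics, decay fits, quartiles, KS comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from motifturnover import (
    ExponentialDecay,
    OccupancyTable,
    fit_decay,
    global_shared_occupancy,
    ks_compare,
    local_shared_occupancy,
    occurrence_rate,
    occurrence_summary,
    quartile_classes,
    random_pair_baseline,
    shared_occupancy_orthogroup,
)
from motifturnover.occupancy import occurrence_rates, global_motif_density


def make_table(rows, regions=None):
    df = pd.DataFrame(rows, columns=["assembly", "orthogroup", "cluster", "count"])
    return OccupancyTable(df, regions or {})


class TestSharedOccupancy:
    def test_worked_example(self, worked_example):
        target, ref = worked_example
        so = shared_occupancy_orthogroup(target, ref)
        assert so.per_motif == {"A": 1.0, "B": 0.0, "C": 1.0}
        assert so.shared_count == 2
        assert so.ref_total == 3
        assert round(so.percent) == 67

    def test_identical_counts_full_sharing(self):
        so = shared_occupancy_orthogroup({"A": 2, "B": 3}, {"A": 2, "B": 3})
        assert so.fraction == 1.0

    def test_empty_target_zero_sharing(self):
        so = shared_occupancy_orthogroup({}, {"A": 2, "B": 1})
        assert so.fraction == 0.0

    def test_reference_only_clusters_excluded(self):
        # cluster D present only in target: ignored entirely
        so = shared_occupancy_orthogroup({"A": 1, "D": 5}, {"A": 1, "B": 0})
        assert so.per_motif == {"A": 1.0}
        assert so.ref_total == 1

    def test_all_zero_reference_raises(self):
        with pytest.raises(ValueError, match="excluded"):
            shared_occupancy_orthogroup({"A": 1}, {"A": 0})

    @given(
        st.dictionaries(st.sampled_from("ABCDE"), st.integers(0, 6), min_size=1),
        st.dictionaries(st.sampled_from("ABCDE"), st.integers(0, 6), min_size=1),
    )
    @settings(max_examples=150, deadline=None)
    def test_bounds_and_capping(self, target, ref):
        if sum(ref.values()) == 0:
            return
        so = shared_occupancy_orthogroup(target, ref)
        assert 0.0 <= so.fraction <= 1.0
        for c, f in so.per_motif.items():
            assert 0.0 <= f <= 1.0
            if target.get(c, 0) >= ref[c]:
                assert f == 1.0  # capped at the reference count
        # monotonicity: adding target instances never decreases sharing
        bigger = {c: v + 1 for c, v in target.items()} or {"A": 1}
        for c in ref:
            bigger.setdefault(c, 1)
        so2 = shared_occupancy_orthogroup(bigger, ref)
        assert so2.fraction >= so.fraction - 1e-12


class TestGlobalOccupancy:
    ROWS = [
        ("ref", "og1", "A", 2), ("ref", "og1", "B", 2),
        ("ref", "og2", "A", 1),
        ("tgt", "og1", "A", 1), ("tgt", "og1", "B", 1),
        ("tgt", "og2", "A", 1),
    ]

    def test_self_comparison_is_full(self):
        rows = [r for r in self.ROWS if r[0] == "ref"] + [
            ("tgt", og, c, n) for (_, og, c, n) in self.ROWS if _ == "ref"
        ]
        table = make_table(rows)
        out = global_shared_occupancy(table, "ref")
        assert out.loc[out["assembly"] == "tgt", "mean_fraction"].iloc[0] == 1.0

    def test_mean_of_orthogroup_fractions(self):
        table = make_table(self.ROWS)
        out = global_shared_occupancy(table, "ref")
        row = out[out["assembly"] == "tgt"].iloc[0]
        assert row["mean_fraction"] == pytest.approx((0.5 + 1.0) / 2)  # 75%
        assert row["pooled_fraction"] == pytest.approx(3 / 5)

    def test_zero_reference_orthogroup_excluded(self):
        rows = self.ROWS + [("ref", "og3", "A", 0), ("tgt", "og3", "A", 4)]
        table = make_table(rows)
        out = global_shared_occupancy(table, "ref")
        assert out[out["assembly"] == "tgt"]["n_orthogroups"].iloc[0] == 2

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="absent"):
            global_shared_occupancy(make_table(self.ROWS), "nope")


class TestRandomPairBaseline:
    def test_identical_genes_baseline_is_one(self, rng):
        rows = [("ref", f"og{i}", "A", 2) for i in range(5)]
        assert random_pair_baseline(make_table(rows), "ref", 500, rng) == 1.0

    def test_matches_exhaustive_all_pairs_mean(self, rng):
        counts = {"og0": {"A": 1}, "og1": {"A": 3, "B": 1}, "og2": {"B": 2},
                  "og3": {"A": 2, "B": 2}, "og4": {"A": 1, "B": 4}}
        rows = [("ref", og, c, n) for og, d in counts.items() for c, n in d.items()]
        table = make_table(rows)
        # exhaustive ordered-pair mean (the enumeration oracle)
        ogs = sorted(counts)
        clusters = ["A", "B"]
        vec = {og: np.array([counts[og].get(c, 0) for c in clusters]) for og in ogs}
        fracs = [
            np.minimum(vec[g1], vec[g2]).sum() / vec[g2].sum()
            for g1 in ogs for g2 in ogs if g1 != g2
        ]
        exact = np.mean(fracs)
        n_pairs = 40_000
        est = random_pair_baseline(table, "ref", n_pairs, rng)
        se = np.std(fracs) / np.sqrt(n_pairs)
        assert abs(est - exact) < 3 * se


class TestOccurrence:
    ROWS = [("a1", f"og{i}", "A", c) for i, c in enumerate([3, 4, 3])] + [
        ("a2", f"og{i}", "A", c) for i, c in enumerate([1, 1, 0])
    ]

    def test_rate_arithmetic(self):
        table = make_table(self.ROWS, {"a1": 5, "a2": 5})
        assert occurrence_rate(table, "a1", "A") == pytest.approx(10 / 5)
        assert occurrence_rate(table, "a2", "A") == pytest.approx(0.4)

    def test_zero_instances_zero_rate(self):
        table = make_table(self.ROWS + [("a1", "og0", "B", 0)], {"a1": 5, "a2": 5})
        assert occurrence_rate(table, "a2", "B") == 0.0

    def test_zero_regions_error(self):
        table = make_table(self.ROWS, {"a1": 5, "a2": 0})
        with pytest.raises(ValueError):
            occurrence_rate(table, "a2", "A")

    def test_global_density_is_sum_of_cluster_rates(self, rng):
        rows = [
            (a, f"og{i}", c, int(rng.integers(0, 4)))
            for a in ("a1", "a2") for i in range(6) for c in "ABC"
        ]
        table = make_table(rows, {"a1": 6, "a2": 6})
        rates = occurrence_rates(table)
        dens = global_motif_density(table)
        for a in ("a1", "a2"):
            assert dens[a] == pytest.approx(rates.loc[a].sum())

    def test_summary_median_and_cv(self):
        rows = [(f"a{k}", "og0", "A", v) for k, v in enumerate([1, 2, 3])]
        table = make_table(rows, {f"a{k}": 1 for k in range(3)})
        summ = occurrence_summary(table)
        assert summ.loc["A", "median_rate"] == pytest.approx(2.0)
        assert summ.loc["A", "cv"] == pytest.approx(1.0 / 2.0)  # sample sd / mean

    def test_identical_rates_cv_zero(self):
        rows = [(f"a{k}", "og0", "A", 2) for k in range(3)]
        table = make_table(rows, {f"a{k}": 1 for k in range(3)})
        assert occurrence_summary(table).loc["A", "cv"] == pytest.approx(0.0)

    def test_single_assembly_rejected(self):
        table = make_table([("a1", "og0", "A", 1)], {"a1": 1})
        with pytest.raises(ValueError, match="2"):
            occurrence_summary(table)


class TestDecayFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 3, 20)
        y = 0.5 * np.exp(-2.0 * x) + 0.48
        fit = fit_decay(x, y)
        assert fit.converged
        assert np.allclose(fit.params, [0.5, 2.0, 0.48], atol=1e-6)

    def test_flat_data_flagged(self):
        fit = fit_decay(np.linspace(0, 1, 10), np.full(10, 0.7))
        assert fit.flat and fit.converged
        assert fit.a == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(0.7)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fit_decay([0, 1, 2], [1, 0.5, 0.3])

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_decay([1.0] * 5, [1, 0.9, 0.8, 0.7, 0.6])

    def test_noisy_recovery_within_ten_percent(self, rng):
        x = np.linspace(0, 3, 40)
        truth = np.array([0.5, 2.0, 0.48])
        errs = []
        for _ in range(50):
            y = 0.5 * np.exp(-2.0 * x) + 0.48 + rng.normal(0, 0.02, x.size)
            fit = fit_decay(x, y)
            errs.append(np.abs(fit.params - truth) / truth)
        med = np.median(np.array(errs), axis=0)
        assert (med < 0.10).all()

    def test_grid_search_confirms_global_basin(self, rng):
        """Coarse grid over (a, b, c) finds no better residual than the fit."""
        x = np.linspace(0, 3, 40)
        y = 0.5 * np.exp(-2.0 * x) + 0.48 + rng.normal(0, 0.02, x.size)
        fit = fit_decay(x, y)
        best_grid = np.inf
        for a in np.linspace(0.1, 0.9, 9):
            for b in np.linspace(0.2, 5, 13):
                for c in np.linspace(0.2, 0.8, 13):
                    rss = np.sum((y - (a * np.exp(-b * x) + c)) ** 2)
                    best_grid = min(best_grid, rss)
        assert fit.rss <= best_grid + 1e-9


class TestQuartiles:
    def test_four_orthogroups_one_on_top(self):
        mean_f = {"a": 0.1, "b": 0.4, "c": 0.6, "d": 0.9}
        taxa = {k: 300 for k in mean_f}
        top, bottom = quartile_classes(mean_f, taxa, min_taxa=200)
        assert top == {"d"} and bottom == {"a"}

    def test_min_taxa_filter(self):
        mean_f = {"a": 0.1, "b": 0.4, "c": 0.6, "d": 0.9, "e": 1.0}
        taxa = {k: 300 for k in mean_f}
        taxa["e"] = 150
        top, _ = quartile_classes(mean_f, taxa, min_taxa=200)
        assert "e" not in top and top == {"d"}

    def test_boundary_ties_deterministic_and_idempotent(self):
        mean_f = {f"og{i}": v for i, v in enumerate([0.2, 0.2, 0.5, 0.8, 0.8, 0.8])}
        taxa = {k: 250 for k in mean_f}
        first = quartile_classes(mean_f, taxa, min_taxa=200)
        second = quartile_classes(mean_f, taxa, min_taxa=200)
        assert first == second
        top, bottom = first
        assert top == {"og3", "og4", "og5"}  # all tied values at the cut included
        assert bottom == {"og0", "og1"}

    def test_too_few_eligible(self):
        with pytest.raises(ValueError):
            quartile_classes({"a": 0.5, "b": 0.6}, {"a": 300, "b": 300})


class TestKS:
    def test_identical_samples(self):
        d, p = ks_compare([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_compare([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_statistic_matches_ecdf_enumeration(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.4, 1.3, 50)
        d, _ = ks_compare(a, b)
        grid = np.concatenate([a, b])
        ecdf_gap = max(
            abs((a <= t).mean() - (b <= t).mean()) for t in grid
        )
        assert d == pytest.approx(ecdf_gap)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])
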
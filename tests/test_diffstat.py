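"""Weir-Cockerham theta: tallies, components, quantile thresholds."""

import math

import numpy as np
import pandas as pd
import pytest

import helpers_oracle as oracle
from conftest import make_matrix
from dsrscan.diffstat import (
    Contrast,
    LocusCounts,
    ThresholdSet,
    fst_scan,
    locus_counts,
    manhattan_table,
    multilocus_theta,
    theta_quantile_thresholds,
    wc84_components,
)
from dsrscan.matrix import MISSING
from dsrscan.synthetic_data import SimConfig, simulate


def lc(n1, p1, h1, n2, p2, h2):
    return LocusCounts(
        n=np.array([n1, n2], float),
        p=np.array([p1, p2], float),
        h=np.array([h1, h2], float),
    )


class TestContrast:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Contrast("x", {"A", "B"}, {"B"})

    def test_unknown_breed_rejected(self, two_breed_matrix):
        with pytest.raises(ValueError, match="unknown"):
            Contrast("x", {"A"}, {"Z"}).validate_against(two_breed_matrix)


class TestLocusCounts:
    def test_all_hom_alt(self):
        m = make_matrix([[2], [2], [2], [2], [2], [0], [0], [0], [0], [0]],
                        ["A"] * 5 + ["B"] * 5)
        out = locus_counts(m, Contrast("c", {"A"}, {"B"}), 0)
        assert out.n[0] == 5 and out.p[0] == 1.0 and out.h[0] == 0.0

    def test_mixed_with_missing(self):
        m = make_matrix(
            [[0], [1], [1], [2], [MISSING], [0], [0], [0], [0], [0]],
            ["A"] * 5 + ["B"] * 5,
        )
        out = locus_counts(m, Contrast("c", {"A"}, {"B"}), 0)
        assert out.n[0] == 4
        assert out.p[0] == pytest.approx(0.5)
        assert out.h[0] == pytest.approx(0.5)

    def test_empty_group_gives_undefined_theta(self):
        m = make_matrix([[MISSING], [MISSING], [0], [0]], ["A", "A", "B", "B"])
        counts = locus_counts(m, Contrast("c", {"A"}, {"B"}), 0)
        res = wc84_components(counts)
        assert math.isnan(res.theta)


class TestComponents:
    def test_fixed_difference_closed_form(self):
        res = wc84_components(lc(5, 0.0, 0.0, 5, 1.0, 0.0))
        assert res.a == pytest.approx(0.5, abs=1e-15)
        assert res.b == pytest.approx(0.0, abs=1e-15)
        assert res.c == 0.0
        assert res.theta == pytest.approx(1.0, abs=1e-15)

    def test_all_heterozygote_closed_form(self):
        res = wc84_components(lc(5, 0.5, 1.0, 5, 0.5, 1.0))
        assert res.a == pytest.approx(0.0, abs=1e-15)
        assert res.b == pytest.approx(-0.25, abs=1e-15)
        assert res.c == pytest.approx(0.5, abs=1e-15)
        assert res.theta == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic_without_heterozygotes_is_undefined(self):
        res = wc84_components(lc(5, 0.0, 0.0, 5, 0.0, 0.0))
        assert math.isnan(res.theta)

    def test_single_individual_group_is_undefined(self):
        res = wc84_components(lc(1, 0.0, 0.0, 5, 0.5, 0.2))
        assert math.isnan(res.theta)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            counts = []
            for _g in range(2):
                genos = list(rng.integers(-1, 3, size=rng.integers(2, 9)))
                while sum(1 for g in genos if g >= 0) < 2:
                    genos = list(rng.integers(-1, 3, size=rng.integers(2, 9)))
                counts.append(oracle.counts_from_genotypes(genos))
            mine = wc84_components(
                lc(counts[0][0], counts[0][1], counts[0][2],
                   counts[1][0], counts[1][1], counts[1][2])
            )
            a, b, c, theta = oracle.wc84_oracle(counts)
            assert mine.a == pytest.approx(a, abs=1e-12)
            assert mine.b == pytest.approx(b, abs=1e-12)
            assert mine.c == pytest.approx(c, abs=1e-12)
            if math.isnan(theta):
                assert math.isnan(mine.theta)
            else:
                assert mine.theta == pytest.approx(theta, abs=1e-12)

    def test_specific_genotype_table(self):
        # pop1 (0,0,1,2), pop2 (1,2,2,2) against the hand algebra
        c1 = oracle.counts_from_genotypes([0, 0, 1, 2])
        c2 = oracle.counts_from_genotypes([1, 2, 2, 2])
        mine = wc84_components(lc(*c1, *c2))
        _, _, _, theta = oracle.wc84_oracle([c1, c2])
        assert mine.theta == pytest.approx(theta, abs=1e-12)


class TestScan:
    def test_vectorised_scan_matches_scalar_path(self, rng):
        g = rng.integers(-1, 3, size=(12, 60)).astype(np.int8)
        m = make_matrix(g, ["A"] * 6 + ["B"] * 6)
        contrast = Contrast("c", {"A"}, {"B"})
        table = fst_scan(m, contrast)
        for j in range(m.n_loci):
            res = wc84_components(locus_counts(m, contrast, j))
            row = table.iloc[j]
            if math.isnan(res.theta):
                assert math.isnan(row["theta"])
            else:
                assert row["theta"] == pytest.approx(res.theta, abs=1e-12)

    def test_group_swap_symmetry(self, rng):
        g = rng.integers(-1, 3, size=(12, 80)).astype(np.int8)
        m = make_matrix(g, ["A"] * 6 + ["B"] * 6)
        t1 = fst_scan(m, Contrast("c", {"A"}, {"B"}))["theta"]
        t2 = fst_scan(m, Contrast("c", {"B"}, {"A"}))["theta"]
        np.testing.assert_allclose(t1, t2, atol=1e-12, equal_nan=True)

    def test_duplicating_every_sample_barely_moves_multilocus_theta(self):
        cfg = SimConfig(
            breeds=[("A", 50), ("B", 50)], n_chrom=1, snps_per_chrom=5000,
            background_F=0.15, missing_rate=0.0, seed=11,
        )
        m, _ = simulate(cfg)
        contrast = Contrast("c", {"A"}, {"B"})
        base = multilocus_theta(fst_scan(m, contrast))
        doubled = make_matrix(
            np.vstack([m.genotypes, m.genotypes]),
            [m.breed_of[s] for s in m.sample_ids] * 2,
        )
        dup = multilocus_theta(fst_scan(doubled, contrast))
        assert abs(dup - base) < 0.005


class TestMultilocus:
    def test_all_fixed_differences_give_one(self):
        per = [wc84_components(lc(5, 0.0, 0.0, 5, 1.0, 0.0)) for _ in range(4)]
        assert multilocus_theta(per) == pytest.approx(1.0)

    def test_single_locus_equals_its_theta(self):
        res = wc84_components(lc(4, 0.25, 0.5, 6, 0.75, 0.3))
        assert multilocus_theta([res]) == pytest.approx(res.theta)

    def test_all_undefined_is_error(self):
        res = wc84_components(lc(5, 0.0, 0.0, 5, 0.0, 0.0))
        with pytest.raises(ValueError, match="defined"):
            multilocus_theta([res])

    def test_balding_nichols_recovery_at_f_015(self):
        cfg = SimConfig(
            breeds=[("A", 50), ("B", 50)], n_chrom=1, snps_per_chrom=10_000,
            background_F=0.15, missing_rate=0.0, seed=42,
        )
        m, _ = simulate(cfg)
        est = multilocus_theta(fst_scan(m, Contrast("c", {"A"}, {"B"})))
        assert 0.13 <= est <= 0.17

    def test_near_zero_divergence_limit(self):
        cfg = SimConfig(
            breeds=[("A", 50), ("B", 50)], n_chrom=1, snps_per_chrom=10_000,
            background_F=1e-6, missing_rate=0.0, seed=5,
        )
        m, _ = simulate(cfg)
        table = fst_scan(m, Contrast("c", {"A"}, {"B"}))
        assert abs(np.nanmean(table["theta"])) < 0.01


class TestThresholds:
    def test_uniform_grid_flags_exact_counts(self):
        thetas = np.arange(100) / 100.0
        t = theta_quantile_thresholds(thetas)
        assert t.q_core == pytest.approx(0.99)
        assert t.q_sig == pytest.approx(0.95)
        assert t.n_flagged_core == 1
        assert t.n_flagged_sig == 5

    def test_ceil_rule_on_200_grid(self):
        thetas = np.arange(200) / 200.0
        t = theta_quantile_thresholds(thetas)
        assert t.n_flagged_core == 2
        assert t.n_flagged_sig == 10

    def test_all_equal_values_all_flagged(self):
        t = theta_quantile_thresholds(np.full(150, 0.3))
        assert t.n_flagged_core == 150
        assert t.n_flagged_sig == 150

    def test_core_subset_of_sig(self, rng):
        thetas = rng.normal(0.05, 0.05, size=1000)
        t = theta_quantile_thresholds(thetas)
        assert t.q_core >= t.q_sig
        assert t.n_flagged_core <= t.n_flagged_sig

    def test_nan_excluded_and_empty_is_error(self):
        thetas = np.concatenate([np.arange(100) / 100.0, [np.nan] * 400])
        t = theta_quantile_thresholds(thetas)
        assert t.n_flagged_core == 1
        with pytest.raises(ValueError):
            theta_quantile_thresholds(np.array([np.nan]))


class TestManhattan:
    def test_flags_against_hand_expectation(self):
        per = pd.DataFrame(
            {
                "chrom": ["chr1"] * 10,
                "pos": np.arange(1, 11) * 100,
                "locus_id": [f"l{i}" for i in range(10)],
                "theta": [0.1, 0.96, np.nan, 0.5, 0.99, 0.2, 0.95, 0.0, 0.98, 0.3],
            }
        )
        t = ThresholdSet(q_sig=0.95, q_core=0.98, n_flagged_sig=4, n_flagged_core=2)
        table = manhattan_table(per, t)
        assert list(table["flag"]) == [
            "NONE", "SIG", "NONE", "NONE", "CORE", "NONE", "SIG", "NONE",
            "CORE", "NONE",
        ]
        assert math.isnan(table["theta"].iloc[2])
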
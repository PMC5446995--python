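import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cellage
from cellage import (
    AgeRanking,
    CellageError,
    OrthologMap,
    auroc,
    empirical_pq,
    fixed_set_test,
    map_sets,
    mw_pvalue,
    observed_aurocs,
    permutation_null,
    permuted_labels,
)
from cellage.enrichment import PermutationNull
from cellage.profiles import derive_gene_sets, filter_zero_genes, standardize, type_profile
from conftest import brute_force_auroc, brute_force_auroc_scores, make_ranking


class TestAuroc:
    def test_top_k_perfect_separation(self, rng):
        rk = make_ranking(20, rng)
        assert auroc(set(list(rk.genes)[:5]), rk) == pytest.approx(1.0)

    def test_reversal_symmetry(self, rng):
        rk = make_ranking(15, rng)
        rev = AgeRanking(tuple(reversed(rk.genes)), np.sort(rk.scores)[::-1])
        members = set(list(rk.genes)[2:7])
        assert auroc(members, rk) + auroc(members, rev) == pytest.approx(1.0)

    def test_hand_enumerated_example(self, rng):
        # 6-gene ranking, set at positions {1, 3, 4}: 9 member/non-member
        # pairs, 7 member wins -> 7/9
        rk = make_ranking(6, rng)
        members = {rk.genes[0], rk.genes[2], rk.genes[3]}
        assert auroc(members, rk) == pytest.approx(7 / 9)
        assert brute_force_auroc([1, 3, 4], 6) == pytest.approx(7 / 9)

    def test_complement_swap_identity(self, rng):
        rk = make_ranking(12, rng)
        members = set(list(rk.genes)[::3])
        complement = set(rk.genes) - members
        assert auroc(members, rk) + auroc(complement, rk) == pytest.approx(1.0)

    def test_members_absent_from_ranking_dropped(self, rng):
        rk = make_ranking(10, rng)
        members = {rk.genes[0], rk.genes[1], "not_in_ranking"}
        assert auroc(members, rk) == auroc({rk.genes[0], rk.genes[1]}, rk)

    def test_empty_set_and_full_set_errors_distinguished(self, rng):
        rk = make_ranking(5, rng)
        with pytest.raises(CellageError, match="no set member"):
            auroc({"missing"}, rk)
        with pytest.raises(CellageError, match="complement is empty"):
            auroc(set(rk.genes), rk)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_brute_force_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        # tied scores allowed: draw from a small value pool
        scores = np.sort(rng.choice(np.linspace(-2, 2, 7), size=n))[::-1]
        genes = tuple(f"g{i}" for i in range(n))
        rk = AgeRanking(genes, scores)
        n1 = int(rng.integers(1, n))
        members = set(rng.choice(genes, size=n1, replace=False))
        member_scores = [s for g, s in zip(genes, scores) if g in members]
        other_scores = [s for g, s in zip(genes, scores) if g not in members]
        expected = brute_force_auroc_scores(member_scores, other_scores)
        assert auroc(members, rk) == pytest.approx(expected, abs=1e-12)


class TestMwPvalue:
    def test_centered_set_p_near_one(self, rng):
        rk = make_ranking(400, rng)
        members = set(list(rk.genes)[::2])  # evenly interleaved
        assert mw_pvalue(members, rk) > 0.8

    def test_tiny_n_against_exact_enumeration(self, rng):
        rk = make_ranking(6, rng)
        members = {rk.genes[0], rk.genes[2], rk.genes[3]}
        # exhaustive C(6,3) oracle for the two-sided p of U at this placement
        observed_u = 7  # rank sum 13 - 6
        count = 0
        total = 0
        for combo in itertools.combinations(range(1, 7), 3):
            ranks = [7 - pos for pos in combo]
            u = sum(ranks) - 6
            if abs(u - 4.5) >= abs(observed_u - 4.5):
                count += 1
            total += 1
        exact = count / total
        assert exact == pytest.approx(0.4)
        # documented tolerance for the normal approximation at this tiny n
        assert mw_pvalue(members, rk) == pytest.approx(exact, abs=0.15)

    def test_strong_set_extreme_p(self, rng):
        rk = make_ranking(1000, rng)
        members = set(list(rk.genes)[:100])  # all in the top decile
        assert mw_pvalue(members, rk) < 1e-10

    def test_one_sided_halves_two_sided_far_from_null(self, rng):
        rk = make_ranking(200, rng)
        members = set(list(rk.genes)[:30])
        two = mw_pvalue(members, rk, sides="two")
        one = mw_pvalue(members, rk, sides="one")
        assert one == pytest.approx(two / 2, rel=1e-6)

    def test_invalid_sides(self, rng):
        rk = make_ranking(10, rng)
        with pytest.raises(CellageError, match="sides"):
            mw_pvalue({rk.genes[0]}, rk, sides="three")


def build_pipeline(cfg):
    expr, labels, truth = cellage.simulate_single_cell(cfg)
    z = standardize(filter_zero_genes(expr))
    table, _ = cellage.simulate_age_table(truth, cfg)
    rk = cellage.build_signed_ranking(table)
    return z, labels, rk, truth


class TestPermutationNull:
    def test_determinism(self, small_dataset):
        cfg, expr, labels, truth = small_dataset
        z = standardize(filter_zero_genes(expr))
        table, _ = cellage.simulate_age_table(truth, cfg)
        rk = cellage.build_signed_ranking(table)
        a = permutation_null(z, labels, rk, B=20, seed=11)
        b = permutation_null(z, labels, rk, B=20, seed=11)
        pd.testing.assert_frame_equal(a.aurocs, b.aurocs)

    def test_fast_path_equals_public_route(self, small_dataset):
        """Dual route: the vectorized permutation core must agree with
        composing type_profile -> derive_gene_sets -> map_sets -> auroc."""
        cfg, expr, labels, truth = small_dataset
        z = standardize(filter_zero_genes(expr))
        table, _ = cellage.simulate_age_table(truth, cfg)
        rk = cellage.build_signed_ranking(table)
        omap = OrthologMap({g: g.upper() for g in z.values.index})
        rk_h = AgeRanking(tuple(g.upper() for g in rk.genes), rk.scores)
        B, seed = 5, 21
        null = permutation_null(z, labels, rk_h, omap, tau=2.0, B=B, seed=seed)
        for b in range(B):
            shuffled = permuted_labels(labels, seed=seed, b=b, B=B)
            cat = map_sets(derive_gene_sets(type_profile(z, shuffled), 2.0), omap)
            for name, genes in cat.sets().items():
                got = null.aurocs.loc[b, name]
                effective = set(genes) & set(rk_h.genes)
                if not effective or len(effective) == len(rk_h):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(auroc(effective, rk_h), abs=1e-12)

    def test_null_centered_without_signal(self):
        # ranking independent of expression and no global shift: grand mean
        # of permuted AUROCs within 0.5 +/- 0.02 at B=200
        cfg = cellage.SimulationConfig(
            n_types=16, cells_per_type=3, n_genes=500, markers_per_type=0,
            marker_effect=0.0, stable_fraction=0.5, seed=13)
        z, labels, rk, _ = build_pipeline(cfg)
        null = permutation_null(z, labels, rk, B=200, seed=13)
        grand = float(np.nanmean(null.aurocs.to_numpy()))
        assert abs(grand - 0.5) < 0.02

    def test_inflated_baseline_with_nonspecific_downshift(self):
        # stable genes pushed down the ranking => threshold-derived sets
        # (which exclude them) score above 0.5 even for permuted labels
        cfg = cellage.SimulationConfig(
            n_types=16, cells_per_type=3, n_genes=500, markers_per_type=0,
            marker_effect=0.0, stable_fraction=0.5, nonspecific_shift=-0.8,
            seed=17)
        z, labels, rk, _ = build_pipeline(cfg)
        null = permutation_null(z, labels, rk, B=100, seed=17)
        enriched_cols = [c for c in null.aurocs.columns if c != "nonspecific"]
        assert float(np.nanmean(null.aurocs[enriched_cols].to_numpy())) > 0.5
        # while the derived non-specific set itself scores below 0.5
        assert float(np.nanmean(null.aurocs["nonspecific"].to_numpy())) < 0.5

    def test_b_must_be_positive(self, small_dataset):
        cfg, expr, labels, truth = small_dataset
        z = standardize(filter_zero_genes(expr))
        table, _ = cellage.simulate_age_table(truth, cfg)
        rk = cellage.build_signed_ranking(table)
        with pytest.raises(CellageError, match="B must be"):
            permutation_null(z, labels, rk, B=0, seed=0)


def null_from_matrix(values, seed=0):
    frame = pd.DataFrame(np.asarray(values, float))
    frame.columns = [f"T{j}" for j in range(frame.shape[1])]
    return PermutationNull(frame, seed=seed, B=frame.shape[0])


class TestEmpiricalPq:
    def test_floor_at_one_over_b(self, rng):
        null = null_from_matrix(rng.uniform(0.3, 0.7, size=(100, 1)))
        observed = pd.Series({"T0": 0.99})
        out = empirical_pq(observed, null)
        assert out.loc["T0", "p"] == pytest.approx(1 / 100)

    def test_single_type_q_equals_p(self, rng):
        null = null_from_matrix(rng.normal(0.5, 0.05, size=(500, 1)))
        for obs in [0.52, 0.58, 0.45]:
            out = empirical_pq(pd.Series({"T0": obs}), null)
            # with one type the min over types is the type's own p, and the
            # count of inner p <= k/B is exactly k for continuous values
            assert out.loc["T0", "q"] == pytest.approx(out.loc["T0", "p"])

    def test_min_p_fdr_independent_types_analytic(self, rng):
        # 49 independent types, observed at the floor: q ~= 1 - (1 - 1/B)^49
        B = 2000
        null = null_from_matrix(rng.normal(0.5, 0.05, size=(B, 49)))
        observed = pd.Series({f"T{j}": 0.99 for j in range(49)})
        out = empirical_pq(observed, null)
        assert np.allclose(out["p"], 1 / B)
        expected = 1 - (1 - 1 / B) ** 49
        assert np.allclose(out["q"], expected, atol=0.0015)

    def test_q_monotone_in_p(self, rng):
        null = null_from_matrix(rng.normal(0.5, 0.08, size=(300, 6)))
        observed = pd.Series(
            {f"T{j}": v for j, v in enumerate([0.5, 0.55, 0.6, 0.65, 0.7, 0.75])}
        )
        out = empirical_pq(observed, null).sort_values("p")
        assert out["q"].is_monotonic_increasing
        assert (out["p"] >= 1 / 300 - 1e-12).all()

    def test_sided_rule_matches_manual_counts(self):
        col = np.array([0.4, 0.45, 0.5, 0.55, 0.6])
        null = null_from_matrix(col.reshape(-1, 1))
        out = empirical_pq(pd.Series({"T0": 0.55}), null, rule="sided")
        # mean = 0.5, obs above: p = #{>= 0.55}/5 = 2/5
        assert out.loc["T0", "p"] == pytest.approx(2 / 5)
        out_low = empirical_pq(pd.Series({"T0": 0.42}), null, rule="sided")
        assert out_low.loc["T0", "p"] == pytest.approx(1 / 5)

    def test_symmetric_rule_matches_manual_counts(self):
        # binary-exact values so tie comparisons are exact
        col = np.array([0.25, 0.375, 0.5, 0.625, 0.75])
        null = null_from_matrix(col.reshape(-1, 1))
        out = empirical_pq(pd.Series({"T0": 0.625}), null)
        # deviations from mean 0.5: [.25, .125, 0, .125, .25]; obs dev 0.125
        assert out.loc["T0", "p"] == pytest.approx(4 / 5)

    def test_nan_columns_tolerated(self, rng):
        values = rng.normal(0.5, 0.05, size=(50, 2))
        values[::2, 1] = np.nan
        null = null_from_matrix(values)
        out = empirical_pq(pd.Series({"T0": 0.6, "T1": 0.6}), null)
        assert np.isfinite(out.loc["T1", "p"])

    def test_unknown_type_rejected(self, rng):
        null = null_from_matrix(rng.uniform(size=(10, 1)))
        with pytest.raises(CellageError, match="absent from the null"):
            empirical_pq(pd.Series({"Txx": 0.5}), null)

    def test_loo_variant_close_to_plugin(self, rng):
        null = null_from_matrix(rng.normal(0.5, 0.05, size=(400, 4)))
        observed = pd.Series({f"T{j}": 0.6 for j in range(4)})
        plug = empirical_pq(observed, null, variant="plugin")
        loo = empirical_pq(observed, null, variant="loo")
        assert np.allclose(plug["p"], loo["p"])  # p itself is unaffected
        assert np.all(loo["q"] <= plug["q"] + 0.05)


class TestFixedSetTest:
    def test_bonferroni_arithmetic(self, rng):
        rk = make_ranking(300, rng)
        genes = list(rk.genes)
        sets = {f"s{j}": set(rng.choice(genes, 20, replace=False)) for j in range(6)}
        out = fixed_set_test(sets, rk).set_index("name")
        assert len(out) == 6
        for name in out.index:
            assert out.loc[name, "p_adj"] == pytest.approx(
                min(1.0, 6 * out.loc[name, "p"])
            )

    def test_empty_intersection_skipped_and_family_shrinks(self, rng):
        rk = make_ranking(50, rng)
        sets = {
            "real": set(list(rk.genes)[:10]),
            "ghost": {"nope1", "nope2"},
            "real2": set(list(rk.genes)[20:30]),
        }
        out = fixed_set_test(sets, rk)
        assert set(out["name"]) == {"real", "real2"}
        # m = 2, not 3
        assert np.allclose(out["p_adj"], np.minimum(1, 2 * out["p"]))

    def test_planted_downshifted_set_detected(self):
        # housekeeping-like set planted with a 0.5 SD down-shift
        rng = np.random.default_rng(123)
        n, k = 10_000, 200
        stats_ = rng.standard_normal(n)
        stats_[:k] -= 0.5
        genes = [f"g{i}" for i in range(n)]
        order = np.argsort(-stats_)
        rk = AgeRanking(tuple(np.array(genes)[order]), stats_[order])
        out = fixed_set_test({"housekeeping": set(genes[:k])}, rk)
        assert out["auroc"].iloc[0] < 0.5
        assert out["p_adj"].iloc[0] < 0.05

    def test_no_overlapping_sets_rejected(self, rng):
        rk = make_ranking(10, rng)
        with pytest.raises(CellageError, match="no gene set overlaps"):
            fixed_set_test({"ghost": {"zzz"}}, rk)


class TestEnrichmentAnalysis:
    def test_table_contract(self, small_dataset):
        cfg, expr, labels, truth = small_dataset
        z = standardize(filter_zero_genes(expr))
        table, _ = cellage.simulate_age_table(truth, cfg)
        rk = cellage.build_signed_ranking(table)
        out, null = cellage.enrichment_analysis(z, labels, rk, B=50, seed=3)
        assert set(out.columns) == {
            "cell_count", "gene_count", "permuted_auroc", "auroc", "p", "q"
        }
        assert "nonspecific" in out.index
        valid = out.dropna(subset=["p"])
        assert ((valid["p"] >= 1 / 50 - 1e-12) & (valid["p"] <= 1)).all()
        srt = valid.sort_values("p")
        assert srt["q"].is_monotonic_increasing
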
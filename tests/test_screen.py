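"""Screen scoring: normalization, R-score, rank product, Z-factor, hit picks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radscreen import (
    mean_abs_deviation, normalize_sf, r_score, rank_product,
    rank_product_pvalues, select_top_hits, z_factor,
)


def _sf_table(sample_sf, nt_sf, run="run1"):
    rows = [{"run_id": run, "gene_id": f"G{i}", "role": "sample", "sf": s}
            for i, s in enumerate(sample_sf)]
    rows += [{"run_id": run, "gene_id": "NT", "role": "nt_control", "sf": s}
             for s in nt_sf]
    return pd.DataFrame(rows)


class TestNormalizeSf:
    def test_nt_wells_map_to_unity(self):
        norm = normalize_sf(_sf_table([0.05], [0.1, 0.1, 0.1]))
        nt = norm[norm["role"] == "nt_control"]
        assert (nt["normalized_sf"] == 1.0).all()

    def test_sample_divided_by_nt_median(self):
        norm = normalize_sf(_sf_table([0.05], [0.08, 0.10, 0.12]))
        assert norm.loc[norm["role"] == "sample", "normalized_sf"].iloc[0] == pytest.approx(0.5)

    def test_scale_invariance_within_run(self):
        base = _sf_table([0.05, 0.2], [0.08, 0.10, 0.12])
        scaled = base.copy()
        scaled["sf"] *= 3.7
        a = normalize_sf(base)["normalized_sf"]
        b = normalize_sf(scaled)["normalized_sf"]
        assert np.allclose(a, b)

    def test_run_without_nt_rejected(self):
        df = _sf_table([0.05], [0.1])
        df = df[df["role"] == "sample"]
        with pytest.raises(ValueError, match="non-targeting"):
            normalize_sf(df)


class TestRScore:
    def test_unit_normalized_sf_scores_zero(self):
        scored = r_score(normalize_sf(_sf_table([0.1], [0.1, 0.09, 0.11])))
        # sample sf equals NT median -> normalized 1 -> R = 0
        assert scored.loc[scored["role"] == "sample", "r_score"].iloc[0] == pytest.approx(0.0)

    def test_printed_formula_hand_value(self):
        # NT normalized {0.9, 1.0, 1.1}, gene normalized 0.8:
        # meanAD = (0.1 + 0 + 0.1)/3; R = -0.2 / 0.0667 = -3.0
        df = _sf_table([0.08], [0.09, 0.10, 0.11])
        scored = r_score(normalize_sf(df))
        assert scored.loc[scored["role"] == "sample", "r_score"].iloc[0] == pytest.approx(-3.0)

    def test_most_negative_score_ranks_first(self):
        df = _sf_table([0.02, 0.15, 0.08], [0.09, 0.10, 0.11])
        scored = r_score(normalize_sf(df))
        samples = scored[scored["role"] == "sample"].set_index("gene_id")
        assert samples.loc["G0", "rank"] == 1.0
        assert list(samples["rank"].sort_values().index) == ["G0", "G2", "G1"]

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValueError, match="zero deviation"):
            r_score(normalize_sf(_sf_table([0.05], [0.1, 0.1, 0.1])))

    def test_single_nt_well_rejected(self):
        with pytest.raises(ValueError, match=">= 2 NT"):
            r_score(normalize_sf(_sf_table([0.05], [0.1])))

    def test_median_mad_switch(self):
        df = normalize_sf(_sf_table([0.08], [0.09, 0.10, 0.13]))
        mean_based = r_score(df, mad_center="mean")
        median_based = r_score(df, mad_center="median")
        s = lambda t: t.loc[t["role"] == "sample", "r_score"].iloc[0]
        assert s(mean_based) != pytest.approx(s(median_based))

    @settings(max_examples=200)
    @given(st.lists(st.floats(0.01, 2.0), min_size=1, max_size=20),
           st.lists(st.floats(0.01, 2.0), min_size=2, max_size=10))
    def test_matches_one_line_oracle(self, sample_norm, nt_norm):
        """R equals (normalized SF - 1)/meanAD(NT normalized SF), independently coded."""
        nt = np.asarray(nt_norm)
        mad = np.mean(np.abs(nt - nt.mean()))
        if mad < 1e-12:
            return
        rows = [{"run_id": "r", "gene_id": f"G{i}", "role": "sample",
                 "sf": v, "normalized_sf": v} for i, v in enumerate(sample_norm)]
        rows += [{"run_id": "r", "gene_id": "NT", "role": "nt_control",
                  "sf": v, "normalized_sf": v} for v in nt_norm]
        scored = r_score(pd.DataFrame(rows))
        got = scored.loc[scored["role"] == "sample", "r_score"].to_numpy()
        expected = (np.asarray(sample_norm) - 1.0) / mad
        assert np.allclose(got, expected)


def _rank_tables(rank_lists):
    """rank_lists: per run, dict gene -> rank."""
    return [pd.DataFrame({"gene_id": list(d), "rank": list(d.values())})
            for d in rank_lists]


class TestRankProduct:
    def test_three_gene_example(self):
        rp = rank_product(_rank_tables([{"A": 1, "B": 2, "C": 3},
                                        {"A": 2, "B": 1, "C": 3}]))
        by_gene = rp.set_index("gene_id")["rp"]
        assert by_gene["A"] == pytest.approx(math.sqrt(2))
        assert by_gene["B"] == pytest.approx(math.sqrt(2))
        assert by_gene["C"] == pytest.approx(3.0)

    def test_first_in_every_run_gives_one(self):
        rp = rank_product(_rank_tables([{"A": 1, "B": 2}, {"A": 1, "B": 2}]))
        assert rp.set_index("gene_id")["rp"]["A"] == pytest.approx(1.0)

    def test_invariant_to_run_order(self):
        t = [{"A": 1, "B": 3, "C": 2}, {"A": 2, "B": 1, "C": 3}]
        a = rank_product(_rank_tables(t)).set_index("gene_id")["rp"]
        b = rank_product(_rank_tables(t[::-1])).set_index("gene_id")["rp"]
        assert np.allclose(a.sort_index(), b.sort_index())

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError, match="gene set"):
            rank_product(_rank_tables([{"A": 1, "B": 2}, {"A": 1, "C": 2}]))

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            rank_product(_rank_tables([{"A": 1}]))

    @settings(max_examples=100)
    @given(st.integers(2, 6), st.integers(2, 3), st.integers(0, 10_000))
    def test_equals_brute_force_geometric_mean(self, n, k, seed):
        rng = np.random.default_rng(seed)
        tables = [{f"G{i}": r for i, r in enumerate(rng.permutation(n) + 1)}
                  for _ in range(k)]
        rp = rank_product(_rank_tables(tables)).set_index("gene_id")["rp"]
        for gene in tables[0]:
            brute = math.prod(t[gene] for t in tables) ** (1.0 / k)
            assert rp[gene] == pytest.approx(brute)


class TestRankProductPValues:
    def test_exhaustive_three_gene_enumeration(self):
        # rp = sqrt(2): products over {1..3}^2 with prod <= 2 are
        # (1,1),(1,2),(2,1) -> exact tail p = 3/9 = 1/3
        rp = rank_product(_rank_tables([{"A": 1, "B": 2, "C": 3},
                                        {"A": 2, "B": 1, "C": 3}]))
        res = rank_product_pvalues(rp, method="exhaustive").set_index("gene_id")
        assert res.loc["A", "p_perm"] == pytest.approx(1 / 3)
        assert res.loc["B", "p_perm"] == pytest.approx(1 / 3)

    def test_worst_in_all_runs_has_p_one(self):
        rp = rank_product(_rank_tables([{"A": 1, "B": 2}, {"A": 1, "B": 2}]))
        res = rank_product_pvalues(rp, method="exhaustive").set_index("gene_id")
        assert res.loc["B", "p_perm"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n, k", [(3, 2), (4, 2), (5, 3)])
    def test_permutation_converges_to_exhaustive(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        tables = [{f"G{i}": r for i, r in enumerate(rng.permutation(n) + 1)}
                  for _ in range(k)]
        rp = rank_product(_rank_tables(tables))
        exact = rank_product_pvalues(rp, method="exhaustive").set_index("gene_id")["p_perm"]
        mc = rank_product_pvalues(rp, method="permutation", n_permutations=20_000,
                                  seed=7).set_index("gene_id")["p_perm"]
        # MC standard error <= 0.5/sqrt(B) ~ 0.0035; allow 4 s.e.
        assert np.allclose(mc.sort_index(), exact.sort_index(), atol=0.02)

    def test_auto_switches_on_feasibility(self):
        rp = rank_product(_rank_tables([{"A": 1, "B": 2, "C": 3},
                                        {"A": 2, "B": 1, "C": 3}]))
        auto = rank_product_pvalues(rp, method="auto").set_index("gene_id")["p_perm"]
        exact = rank_product_pvalues(rp, method="exhaustive").set_index("gene_id")["p_perm"]
        assert np.allclose(auto, exact)

    def test_too_few_permutations_rejected(self):
        rp = rank_product(_rank_tables([{"A": 1, "B": 2}, {"A": 2, "B": 1}]))
        with pytest.raises(ValueError, match="n_permutations"):
            rank_product_pvalues(rp, method="permutation", n_permutations=10)


class TestZFactor:
    def test_zero_variance_is_perfect_assay(self):
        rep = z_factor([1.0, 1.0, 1.0], [0.4, 0.4, 0.4])
        assert rep.z_factor == pytest.approx(1.0)

    def test_closed_form_example(self):
        neg = np.array([0.95, 1.05, 0.95, 1.05])   # mu 1.0; |mu_n - mu_p| = 0.6
        pos = np.array([0.35, 0.45, 0.35, 0.45])
        rep = z_factor(neg, pos)
        sd = np.std(neg, ddof=1)
        expected = 1 - 3 * (sd + sd) / 0.6
        assert rep.z_factor == pytest.approx(expected)

    def test_swapping_groups_symmetric(self):
        neg = [0.9, 1.0, 1.1]
        pos = [0.3, 0.4, 0.5]
        assert z_factor(neg, pos).z_factor == pytest.approx(z_factor(pos, neg).z_factor)

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            z_factor([1.0, 1.2], [1.2, 1.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            z_factor([1.0], [0.4, 0.5])


class TestSelectTopHits:
    def _ranking(self):
        return pd.DataFrame({
            "gene_id": ["G3", "G1", "G2", "G4"],
            "r_score": [-3.0, -2.0, -2.0, 1.0],
            "rank": [1.0, 2.5, 2.5, 4.0],
        })

    def test_all_and_none(self):
        df = self._ranking()
        assert select_top_hits(df, n=4) == ["G3", "G1", "G2", "G4"]
        assert select_top_hits(df, n=0) == []

    def test_ties_broken_deterministically_by_gene_id(self):
        assert select_top_hits(self._ranking(), n=3) == ["G3", "G1", "G2"]

    def test_rank_product_column_preferred(self):
        rp = rank_product(_rank_tables([{"A": 1, "B": 2, "C": 3},
                                        {"A": 2, "B": 1, "C": 3}]))
        assert select_top_hits(rp, n=2) == ["A", "B"]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="top"):
            select_top_hits(self._ranking(), n=5)


class TestMeanAbsDeviation:
    def test_mean_and_median_centers(self):
        x = [0.9, 1.0, 1.1]
        assert mean_abs_deviation(x, "mean") == pytest.approx(0.2 / 3)
        assert mean_abs_deviation(x, "median") == pytest.approx(0.1)

    def test_unknown_center_rejected(self):
        with pytest.raises(ValueError):
            mean_abs_deviation([1, 2], "mode")
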
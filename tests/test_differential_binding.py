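"""SILAC ratios, one-sample testing with BH, set algebra, clustering, PTM shifts."""
import numpy as np
import pandas as pd
import pytest

from chromabench import synthetic as syn
from chromabench._errors import AnalysisError, DesignError
from chromabench.differential_binding import (
    RatioTable,
    cluster_ratio_matrix,
    compute_ratios,
    ptm_shift,
    subtract_control_and_intersect,
)
from chromabench.differential_binding import test_differential as silac_differential
from conftest import make_quant_table


def bh_oracle(p):
    """From-definition BH: sort, p*n/rank, cumulative min from the largest."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestComputeRatios:
    def test_log2_of_heavy_over_light(self):
        table = make_quant_table(
            {"h1": [8.0, 2.0], "l1": [2.0, 2.0]}, ids=["A", "B"], roles=["bait", "bait"]
        )
        rt = compute_ratios(table, [("h1", "l1")], median_center=False)
        assert rt.ratios.loc["A", "r1"] == 2.0
        assert rt.ratios.loc["B", "r1"] == 0.0

    def test_missing_channel_yields_no_ratio(self):
        table = make_quant_table(
            {"h1": [0.0, 4.0], "l1": [2.0, 2.0]}, ids=["A", "B"], roles=["bait", "bait"]
        )
        rt = compute_ratios(table, [("h1", "l1")], median_center=False)
        assert np.isnan(rt.ratios.loc["A", "r1"])

    def test_matches_division_oracle_and_centering(self):
        rng = np.random.default_rng(4)
        h = rng.uniform(1, 100, 50)
        l = rng.uniform(1, 100, 50)
        table = make_quant_table(
            {"h1": list(h), "l1": list(l)}, ids=[f"P{i:02d}" for i in range(50)],
            roles=["bait", "bait"],
        )
        raw = compute_ratios(table, [("h1", "l1")], median_center=False).ratios["r1"]
        np.testing.assert_allclose(raw.to_numpy(), np.log2(h / l))
        centered = compute_ratios(table, [("h1", "l1")]).ratios["r1"]
        np.testing.assert_allclose(centered.to_numpy(), np.log2(h / l) - np.median(np.log2(h / l)))
        assert abs(np.median(centered)) < 1e-12

    def test_all_missing_is_an_error(self):
        table = make_quant_table(
            {"h1": [0.0], "l1": [2.0]}, ids=["A"], roles=["bait", "bait"]
        )
        with pytest.raises(AnalysisError):
            compute_ratios(table, [("h1", "l1")])


class TestTestDifferential:
    @staticmethod
    def from_matrix(mat, ids=None):
        ids = ids or [f"P{i}" for i in range(len(mat))]
        return RatioTable(
            ratios=pd.DataFrame(mat, index=pd.Index(ids, name="protein_id"),
                                columns=[f"r{j+1}" for j in range(len(mat[0]))])
        )

    def test_all_zero_ratios(self):
        res = silac_differential(self.from_matrix([[0.0, 0.0, 0.0]]))
        row = res.table.iloc[0]
        assert (row["t"], row["p"]) == (0.0, 1.0)

    def test_single_protein_bh_identity(self):
        res = silac_differential(self.from_matrix([[0.5, 0.7, 0.4]]))
        row = res.table.iloc[0]
        assert row["p_adj"] == row["p"]

    def test_zero_variance_nonzero_mean_flagged(self):
        res = silac_differential(self.from_matrix([[1.0, 1.0, 1.0], [0.1, -0.2, 0.3]]))
        row = res.table.iloc[0]
        assert row["zero_variance"] and row["p"] > 0
        assert row["p"] < 1e-300 and bool(res.table.iloc[1]["zero_variance"]) is False

    def test_too_few_replicates_untested(self):
        res = silac_differential(self.from_matrix([[0.5, np.nan, np.nan], [0.1, 0.2, 0.3]]))
        assert not res.table.iloc[0]["tested"] and res.table.iloc[1]["tested"]
        assert np.isnan(res.table.iloc[0]["p_adj"])

    def test_bh_matches_from_definition_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            mat = rng.normal(rng.choice([0, 2], n)[:, None], 0.5, (n, 3))
            res = silac_differential(self.from_matrix(mat.tolist()))
            np.testing.assert_allclose(
                res.table["p_adj"].to_numpy(), bh_oracle(res.table["p"].to_numpy())
            )
            # adjusted p never below raw p; significance contract
            assert (res.table["p_adj"] >= res.table["p"] - 1e-15).all()
            sig = res.table["significant"]
            assert (res.table.loc[sig, "p_adj"] <= 0.1).all()

    def test_planted_sensitivity_with_moderation(self):
        rt, truth = syn.simulate_silac_ratios(500, 50, (2.0, 4.0), 0.3, 3, seed=123)
        res = silac_differential(rt, alpha=0.1, moderate_variance=True)
        planted = {p for p, e in truth.differential_effects.items() if e != 0}
        assert len(res.significant_ids & planted) / len(planted) >= 0.9

    def test_null_significant_fraction_controlled(self):
        # planted-null: across 50 seeds the significant fraction stays near alpha
        fracs = []
        for seed in range(50):
            rt, _ = syn.simulate_silac_ratios(200, 0, sigma_rep=0.3, n_replicates=3, seed=seed)
            res = silac_differential(rt, alpha=0.1, moderate_variance=True)
            fracs.append(len(res.significant_ids) / 200)
        assert float(np.mean(fracs)) <= 0.12


class TestSetAlgebra:
    def test_intersection_minus_control(self):
        got = subtract_control_and_intersect(
            [{"A", "B", "C"}, {"B", "C"}, {"B", "C", "D"}], {"C"}
        )
        assert got == {"B"}

    def test_empty_control_is_plain_intersection(self):
        assert subtract_control_and_intersect([{"A", "B"}, {"B"}]) == {"B"}

    def test_single_set_rejected(self):
        with pytest.raises(DesignError):
            subtract_control_and_intersect([{"A"}])

    def test_matches_brute_force_set_algebra(self):
        rng = np.random.default_rng(2)
        universe = [f"P{i}" for i in range(30)]
        for _ in range(30):
            sets = [set(rng.choice(universe, size=rng.integers(0, 25), replace=False))
                    for _ in range(int(rng.integers(2, 5)))]
            control = set(rng.choice(universe, size=rng.integers(0, 10), replace=False))
            expected = {x for x in universe if all(x in s for s in sets) and x not in control}
            assert subtract_control_and_intersect(sets, control) == expected


def average_linkage_oracle(points, metric):
    """Naive agglomerative average linkage over raw observation distances."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(points, metric=metric))
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or avg < best[0]:
                    best = (avg, i, j)
        avg, i, j = best
        heights.append(avg)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestClustering:
    def test_identical_baits_merge_at_zero(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 1, 10)
        mat = pd.DataFrame(
            {"b1": col, "b2": col, "b3": rng.normal(0, 1, 10)},
            index=[f"P{i}" for i in range(10)],
        )
        res = cluster_ratio_matrix(mat)
        assert res.col_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {res.col_order.index("b1"), res.col_order.index("b2")}
        assert merged in ({0, 1}, {1, 2})

    def test_outgroup_bait_is_last_merged(self):
        # three correlated pluripotency-factor-like columns, one unrelated bait
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 40)
        mat = pd.DataFrame(
            {
                "Oct4": base + rng.normal(0, 0.2, 40),
                "Sox2": base + rng.normal(0, 0.2, 40),
                "Nanog": base + rng.normal(0, 0.2, 40),
                "Cdh1": rng.normal(0, 1, 40),
            },
            index=[f"P{i}" for i in range(40)],
        )
        res = cluster_ratio_matrix(mat)
        last_merge = res.col_linkage[-1]
        # the final merge joins the outgroup singleton with the OSN cluster
        singleton = [int(x) for x in last_merge[:2] if x < 4]
        assert singleton == [3]  # Cdh1's original column index

    def test_merge_heights_match_brute_force(self):
        rng = np.random.default_rng(11)
        for metric in ("euclidean", "correlation"):
            mat = pd.DataFrame(rng.normal(0, 1, (6, 4)),
                               index=[f"P{i}" for i in range(6)],
                               columns=[f"b{j}" for j in range(4)])
            res = cluster_ratio_matrix(mat, distance=metric)
            expected = average_linkage_oracle(mat.to_numpy(), metric)
            np.testing.assert_allclose(np.sort(res.row_linkage[:, 2]), np.sort(expected))

    def test_row_permutation_leaves_leaf_sets(self):
        rng = np.random.default_rng(14)
        mat = pd.DataFrame(rng.normal(0, 1, (12, 3)),
                           index=[f"P{i:02d}" for i in range(12)],
                           columns=["b1", "b2", "b3"])
        res1 = cluster_ratio_matrix(mat)
        perm = mat.sample(frac=1.0, random_state=0)
        res2 = cluster_ratio_matrix(perm)
        assert set(res1.row_order) == set(res2.row_order)
        np.testing.assert_allclose(
            np.sort(res1.row_linkage[:, 2]), np.sort(res2.row_linkage[:, 2])
        )

    def test_constant_column_falls_back_to_euclidean(self):
        mat = pd.DataFrame(
            {"b1": [0.0, 0.0, 0.0], "b2": [1.0, 2.0, 3.0]}, index=["P1", "P2", "P3"]
        )
        res = cluster_ratio_matrix(mat, distance="correlation")
        assert res.col_distance_used == "euclidean"

    def test_missing_cells_imputed_with_mask(self):
        mat = pd.DataFrame(
            {"b1": [1.0, np.nan, 2.0], "b2": [0.5, 1.0, np.nan]},
            index=["P1", "P2", "P3"],
        )
        res = cluster_ratio_matrix(mat, distance="euclidean")
        assert res.matrix.loc["P2", "b1"] == 0.0
        assert bool(res.imputed_mask.loc["P2", "b1"])
        assert int(res.imputed_mask.to_numpy().sum()) == 2


class TestPtmShift:
    def test_delta_and_flagging(self):
        ptm = pd.DataFrame(
            {"site_id": ["s1", "s2"], "protein_id": ["A", "B"], "log2_ratio": [2.0, 3.0]}
        )
        prot = pd.Series({"A": 2.0, "B": 0.5})
        shifts = ptm_shift(ptm, prot)
        assert (shifts[0].delta, shifts[0].flagged) == (0.0, False)
        assert (shifts[1].delta, shifts[1].flagged) == (2.5, True)

    def test_orphan_site_skipped_with_warning(self):
        ptm = pd.DataFrame({"site_id": ["s1"], "protein_id": ["NOPE"], "log2_ratio": [1.0]})
        with pytest.warns(UserWarning, match="orphan"):
            assert ptm_shift(ptm, pd.Series(dtype=float)) == []

    def test_matches_subtraction_oracle(self):
        rng = np.random.default_rng(5)
        prot = pd.Series(rng.normal(0, 2, 20), index=[f"P{i:02d}" for i in range(20)])
        ptm = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(40)],
                "protein_id": rng.choice(prot.index, 40),
                "log2_ratio": rng.normal(0, 2, 40),
            }
        )
        shifts = ptm_shift(ptm, prot)
        for row, s in zip(ptm.itertuples(index=False), shifts):
            assert s.delta == row.log2_ratio - prot[row.protein_id]
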
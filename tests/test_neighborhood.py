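"""Delaunay graphs vs an empty-circumcircle oracle; interaction matrices."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glandmap import (
    InteractionModel,
    build_delaunay,
    interaction_matrix,
    normalize_and_fold_change,
    prune_edges,
)
from glandmap.neighborhood import column_normalize


def cells_frame(points, types=None, tissue="t0"):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x": points[:, 0],
            "y": points[:, 1],
            "cell_type": types if types is not None else ["A"] * n,
            "tissue_id": tissue,
        }
    )


def delaunay_oracle_edges(points):
    """All edges of triangles whose circumcircle is empty of other points.

    Brute-force over point triples; robust only for small general-position
    instances, which is exactly what it is used for.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue  # collinear triple
        ux = (
            (ax**2 + ay**2) * (by - cy)
            + (bx**2 + by**2) * (cy - ay)
            + (cx**2 + cy**2) * (ay - by)
        ) / d
        uy = (
            (ax**2 + ay**2) * (cx - bx)
            + (bx**2 + by**2) * (ax - cx)
            + (cx**2 + cy**2) * (bx - ax)
        ) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        empty = all(
            (pts[m, 0] - ux) ** 2 + (pts[m, 1] - uy) ** 2 > r2 - 1e-9
            for m in range(n)
            if m not in (i, j, k)
        )
        if empty:
            edges.update({(i, j), (j, k), (i, k)})
    return edges


class TestDelaunay:
    def test_triangle_has_three_edges(self):
        g = build_delaunay(cells_frame([(0, 0), (1, 0), (0, 1)]))
        assert g.n_edges == 3

    def test_unit_square_has_five_edges(self):
        g = build_delaunay(cells_frame([(0, 0), (1, 0), (1, 1), (0, 1)]))
        assert g.n_edges == 5  # 4 sides + 1 diagonal

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_circumcircle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(rng.integers(4, 13), 2))
        g = build_delaunay(cells_frame(pts))
        got = {tuple(sorted(e)) for e in g.edges[["i", "j"]].to_numpy()}
        assert got == delaunay_oracle_edges(pts)

    def test_unknown_cells_excluded(self):
        df = cells_frame(
            [(0, 0), (1, 0), (0, 1), (0.4, 0.4)],
            types=["A", "A", "A", "Unknown"],
        )
        g = build_delaunay(df)
        assert len(g.cells) == 3 and g.n_edges == 3

    def test_duplicates_deduplicated_with_warning(self):
        df = cells_frame([(0, 0), (0, 0), (1, 0), (0, 1)])
        with pytest.warns(UserWarning, match="duplicate"):
            g = build_delaunay(df)
        assert len(g.cells) == 3

    def test_degenerate_tissues_skipped(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert build_delaunay(cells_frame([(0, 0), (1, 1)])) is None
        with pytest.warns(UserWarning, match="collinear"):
            assert build_delaunay(cells_frame([(0, 0), (1, 1), (2, 2)])) is None


class TestPruning:
    def test_equal_lengths_nothing_removed(self):
        pts = [(float(i), 0.0) for i in range(5)] + [(float(i) + 0.5, 1.0) for i in range(4)]
        g = build_delaunay(cells_frame(pts))
        assert prune_edges(g, 99).n_edges == g.n_edges - int(
            (g.edges["length"] > np.percentile(g.edges["length"], 99)).sum()
        )

    def test_single_long_edge_removed(self):
        # chain of near-unit edges plus one far outlier
        pts = [(float(i), (-1.0) ** i * 0.1) for i in range(100)] + [(250.0, 0.0)]
        g = build_delaunay(cells_frame(pts))
        pruned = prune_edges(g, 99)
        assert pruned.edges["length"].max() < 100
        assert g.edges["length"].max() > 100

    def test_percentile_100_is_identity(self):
        g = build_delaunay(cells_frame([(0, 0), (3, 0), (1, 4), (5, 5)]))
        assert prune_edges(g, 100).n_edges == g.n_edges

    def test_lowering_percentile_never_adds_edges(self):
        rng = np.random.default_rng(3)
        g = build_delaunay(cells_frame(rng.uniform(0, 5, size=(30, 2))))
        counts = [prune_edges(g, p).n_edges for p in (100, 99, 90, 50)]
        assert counts == sorted(counts, reverse=True)


class TestInteractionMatrix:
    def test_same_type_edge_fills_diagonal(self):
        g = build_delaunay(cells_frame([(0, 0), (1, 0), (0, 1)], ["A", "A", "B"]))
        M = interaction_matrix([g])
        assert M.loc["A", "A"] == 1
        assert M.loc["A", "B"] == M.loc["B", "A"] == 2

    def test_hand_counted_six_cell_toy(self):
        # two unit triangles far apart: one AAB, one BBC
        pts = [(0, 0), (1, 0), (0, 1), (100, 0), (101, 0), (100, 1)]
        types = ["A", "A", "B", "B", "B", "C"]
        g = build_delaunay(cells_frame(pts, types))
        g = prune_edges(g, 99)  # removes the single long bridge edges
        M = interaction_matrix([g], cell_types=["A", "B", "C"])
        # within triangle 1: A-A, A-B, A-B; triangle 2: B-B, B-C, B-C
        assert M.loc["A", "A"] == 1
        assert M.loc["B", "B"] >= 1
        assert M.loc["A", "B"] >= 2
        assert (M.to_numpy() == M.to_numpy().T).all()

    def test_additive_over_tissues(self):
        g1 = build_delaunay(cells_frame([(0, 0), (1, 0), (0, 1)], ["A", "B", "B"]))
        g2 = build_delaunay(cells_frame([(0, 0), (2, 0), (0, 2)], ["A", "A", "B"]))
        M12 = interaction_matrix([g1, g2], cell_types=["A", "B"])
        M1 = interaction_matrix([g1], cell_types=["A", "B"])
        M2 = interaction_matrix([g2], cell_types=["A", "B"])
        pd.testing.assert_frame_equal(M12, M1 + M2)


class TestFoldChange:
    def test_column_normalization_sums(self):
        M = pd.DataFrame([[2.0, 0.0], [2.0, 0.0]], index=list("AB"),
                         columns=list("AB"))
        N = column_normalize(M)
        assert N["A"].sum() == pytest.approx(1.0)
        assert (N["B"] == 0).all()  # zero column stays zero

    def test_identical_matrices_give_unit_fc(self):
        M = pd.DataFrame([[4.0, 2.0], [2.0, 6.0]], index=list("AB"),
                         columns=list("AB"))
        fc = normalize_and_fold_change(M, M.copy())
        np.testing.assert_allclose(fc.to_numpy(), 1.0)

    def test_doubled_interaction_raises_fc(self):
        H = pd.DataFrame([[4.0, 2.0], [2.0, 6.0]], index=list("AB"),
                         columns=list("AB"))
        D = H.copy()
        D.loc["A", "B"] *= 2
        D.loc["B", "A"] *= 2
        fc = normalize_and_fold_change(H, D)
        assert fc.loc["A", "B"] > 1.0

    def test_zero_denominator_reported_missing(self):
        H = pd.DataFrame([[1.0, 0.0], [0.0, 0.0]], index=list("AB"),
                         columns=list("AB"))
        D = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("AB"),
                         columns=list("AB"))
        fc = normalize_and_fold_change(H, D)
        assert fc["B"].isna().all()
        assert not np.isinf(fc.to_numpy()).any()

    def test_pseudocount_yields_dense_output(self):
        H = pd.DataFrame([[1.0, 0.0], [0.0, 0.0]], index=list("AB"),
                         columns=list("AB"))
        D = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("AB"),
                         columns=list("AB"))
        fc = normalize_and_fold_change(H, D, pseudocount=0.5)
        assert np.isfinite(fc.to_numpy()).all()

    def test_type_universe_union(self):
        H = pd.DataFrame([[1.0]], index=["A"], columns=["A"])
        D = pd.DataFrame([[1.0]], index=["B"], columns=["B"])
        fc = normalize_and_fold_change(H, D)
        assert list(fc.index) == ["A", "B"]


class TestModel:
    def test_end_to_end_two_conditions(self, rng):
        rows = []
        for tissue, cond in [("t1", "disease"), ("t2", "healthy")]:
            pts = rng.uniform(0, 20, size=(120, 2))
            types = rng.choice(["A", "B", "C"], size=120)
            df = cells_frame(pts, types, tissue=tissue)
            df["condition"] = cond
            rows.append(df)
        cells = pd.concat(rows, ignore_index=True)
        res = InteractionModel(cells, ("disease", "healthy")).fit(percentile=99)
        for M in res.normalized.values():
            sums = M.sum(axis=0)
            np.testing.assert_allclose(sums[sums > 0], 1.0, atol=1e-9)
        assert res.fold_change.shape == (3, 3)
        assert res.cluster_order is not None

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            InteractionModel(pd.DataFrame({"x": [1]}), ("d", "h"))
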
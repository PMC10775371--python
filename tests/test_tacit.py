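"""TACIT stages: CTR algebra, cutoff search, AND gating, KNN resolution."""

import numpy as np
import pandas as pd
import pytest

from glandmap import (
    SignatureMatrix,
    SynthConfig,
    TACITModel,
    assign_primary,
    compute_ctr,
    find_cutoff,
    seed_cluster,
    synth_marker_table,
    znormalize_intensities,
)
from glandmap.tacit import UNKNOWN_LABEL, classify_lrg_hrg, fit_breakpoints


def brute_force_cutoff(values, is_hrg):
    """Scan all midpoint candidates with an explicit loop."""
    values = np.asarray(values, float)
    is_hrg = np.asarray(is_hrg, bool)
    distinct = np.unique(values)
    best = (np.inf, None)
    for c in 0.5 * (distinct[:-1] + distinct[1:]):
        err = (
            np.sum(is_hrg & (values < c)) + np.sum(~is_hrg & (values >= c))
        ) / values.size
        if err < best[0] - 1e-15:
            best = (err, c)
    return best[1]


class TestZNormalize:
    def test_two_cell_convention(self):
        t = pd.DataFrame({"m": [0.0, 2.0]})
        np.testing.assert_allclose(znormalize_intensities(t)["m"], [-1, 1])

    def test_constant_marker_zeroed_with_warning(self):
        t = pd.DataFrame({"m": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = znormalize_intensities(t)
        assert (out["m"] == 0).all()

    def test_non_numeric_column_named_in_error(self):
        t = pd.DataFrame({"m": [1.0, 2.0], "bad": ["x", "y"]})
        with pytest.raises(ValueError, match="bad"):
            znormalize_intensities(t)

    def test_columns_standardized(self, rng):
        t = pd.DataFrame(rng.normal(3, 2, size=(100, 4)))
        Z = znormalize_intensities(t)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)


class TestCTR:
    def test_identity_signature_returns_z(self, rng):
        Z = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        sig = SignatureMatrix(
            pd.DataFrame(np.eye(3, dtype=int), index=["a", "b", "c"],
                         columns=["A", "B", "C"])
        )
        ctr = compute_ctr(Z, sig)
        np.testing.assert_allclose(ctr.to_numpy(), Z.to_numpy())

    def test_two_marker_sum_and_level_binarization(self):
        Z = pd.DataFrame({"m1": [1.0], "m2": [2.0]})
        sig = SignatureMatrix(
            pd.DataFrame({"T": [1, 2]}, index=["m1", "m2"])  # level-2 marker
        )
        assert compute_ctr(Z, sig).iloc[0, 0] == pytest.approx(3.0)

    def test_linearity_in_single_marker(self, rng):
        Z = pd.DataFrame(rng.normal(size=(5, 2)), columns=["m1", "m2"])
        sig = SignatureMatrix(pd.DataFrame({"T": [1, 1]}, index=["m1", "m2"]))
        base = compute_ctr(Z, sig)
        Z2 = Z.copy()
        Z2["m1"] += 0.7
        np.testing.assert_allclose(
            compute_ctr(Z2, sig)["T"], base["T"] + 0.7, atol=1e-12
        )

    def test_marker_order_irrelevant(self, rng):
        Z = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        sig = SignatureMatrix(
            pd.DataFrame({"T": [1, 0, 1], "U": [0, 1, 0]},
                         index=["a", "b", "c"])
        )
        pd.testing.assert_frame_equal(
            compute_ctr(Z, sig), compute_ctr(Z[["c", "a", "b"]], sig)
        )

    def test_no_shared_markers_errors(self, rng):
        Z = pd.DataFrame(rng.normal(size=(4, 1)), columns=["x"])
        sig = SignatureMatrix(pd.DataFrame({"T": [1]}, index=["y"]))
        with pytest.raises(ValueError, match="no markers shared"):
            compute_ctr(Z, sig)

    def test_signature_validation(self):
        with pytest.raises(ValueError, match="without any defining"):
            SignatureMatrix(pd.DataFrame({"T": [0, 0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="integers"):
            SignatureMatrix(pd.DataFrame({"T": [0.5]}, index=["a"]))


class TestSeedClustering:
    def test_cluster_count_and_mean_size(self, rng):
        Z = pd.DataFrame(rng.normal(size=(5000, 4)))
        labels, k = seed_cluster(Z, target_fraction=0.005, seed=0)
        assert k == 200
        sizes = pd.Series(labels).value_counts()
        assert sizes.mean() == pytest.approx(25.0)

    def test_determinism(self, rng):
        Z = pd.DataFrame(rng.normal(size=(500, 3)))
        l1, _ = seed_cluster(Z, 0.01, seed=7)
        l2, _ = seed_cluster(Z, 0.01, seed=7)
        np.testing.assert_array_equal(l1, l2)

    def test_k_reduced_when_exceeding_cells(self, rng):
        Z = pd.DataFrame(rng.normal(size=(50, 2)))
        with pytest.warns(UserWarning, match="reducing"):
            labels, k = seed_cluster(Z, 0.005, seed=0)  # k=200 > 50
        assert k == 50
        assert len(np.unique(labels)) == 50  # singleton clusters

    def test_invalid_fraction_rejected(self, rng):
        Z = pd.DataFrame(rng.normal(size=(100, 2)))
        with pytest.raises(ValueError):
            seed_cluster(Z, 0.0, seed=0)


class TestCutoff:
    def test_separable_midpoint(self):
        values = np.array([1.0, 2.0, 5.0, 6.0])
        is_hrg = np.array([False, False, True, True])
        assert find_cutoff(values, is_hrg) == pytest.approx(3.5)

    def test_single_lrg_below_all_hrg(self):
        values = np.array([0.0, 4.0, 5.0, 6.0])
        is_hrg = np.array([False, True, True, True])
        c = find_cutoff(values, is_hrg)
        assert 0.0 < c <= 4.0
        assert ((values >= c) == is_hrg).all()

    def test_interleaved_matches_bruteforce_lowest_tie(self, rng):
        for _ in range(20):
            values = rng.normal(size=30)
            is_hrg = rng.random(30) < 0.5
            if is_hrg.all() or not is_hrg.any():
                continue
            assert find_cutoff(values, is_hrg) == pytest.approx(
                brute_force_cutoff(values, is_hrg)
            )

    def test_one_sided_groups_rejected(self):
        with pytest.raises(ValueError):
            find_cutoff(np.array([1.0, 2.0]), np.array([True, True]))


class TestLrgHrg:
    def test_breakpoint_partition_semantics(self):
        from glandmap.segmented import SegmentedRegressionResults

        fit = SegmentedRegressionResults(
            n_breakpoints=2,
            breakpoints=np.array([5.0, 12.0]),
            params=np.zeros(4),
            aic=0.0,
            aic_by_count={2: 0.0},
            rss=0.0,
            nobs=20,
        )
        clusters = np.arange(20)
        lrg, hrg = classify_lrg_hrg(fit, clusters)
        # ranks 1..5 (ids 0..4) below/at lowest bp; ranks 13.. (ids 12..) above
        np.testing.assert_array_equal(lrg, np.arange(5))
        np.testing.assert_array_equal(hrg, np.arange(12, 20))

    def test_zero_breakpoints_refused(self):
        fit = fit_breakpoints(np.linspace(0, 1, 30), max_bp=2, min_seg=3)
        assert fit.n_breakpoints == 0
        with pytest.raises(ValueError, match="non-separable"):
            classify_lrg_hrg(fit, np.arange(30))


class TestAssignment:
    def test_ctm_thresholding_inclusive(self):
        ctr = pd.DataFrame({"A": [0.9, 1.0, 1.1], "B": [5.0, 0.0, 5.0]})
        ctm = assign_primary(ctr, {"A": 1.0, "B": 2.0})
        assert ctm["A"].tolist() == [0, 1, 1]  # inclusive >= at the cutoff
        assert ctm["B"].tolist() == [1, 0, 1]

    def test_types_without_cutoff_zeroed(self):
        ctr = pd.DataFrame({"A": [3.0], "B": [3.0]})
        ctm = assign_primary(ctr, {"A": 1.0, "B": None})
        assert ctm["B"].tolist() == [0]

    def test_unknown_count_monotone_in_cutoffs(self, rng):
        ctr = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("ABC"))
        base = {"A": 0.0, "B": 0.0, "C": 0.0}
        raised = {t: c + 1.0 for t, c in base.items()}
        unknown = lambda cut: int(
            (assign_primary(ctr, cut).sum(axis=1) == 0).sum()
        )
        assert unknown(raised) >= unknown(base)


class TestResolveMixed:
    @pytest.fixture
    def two_type_model(self):
        sig = SignatureMatrix(
            pd.DataFrame({"A": [1, 0], "B": [0, 1]}, index=["mA", "mB"])
        )
        # clean A cells near mA high, clean B cells near mB high, one mixed
        Z = pd.DataFrame(
            {
                "mA": [3.0, 3.1, 2.9, 0.0, 0.1, -0.1, 2.5],
                "mB": [0.0, 0.1, -0.1, 3.0, 3.1, 2.9, 2.4],
            },
            index=[f"c{i}" for i in range(7)],
        )
        model = TACITModel(Z, sig, knn_k=3)
        return model, Z

    def test_majority_of_clean_neighbors_wins(self, two_type_model):
        model, Z = two_type_model
        ctm = pd.DataFrame(
            {"A": [1, 1, 1, 0, 0, 0, 1], "B": [0, 0, 0, 1, 1, 1, 1]},
            index=Z.index,
        )
        labels = model._resolve_mixed(ctm, Z)
        assert labels["c6"] == "A"  # nearer the A cloud
        assert (labels[:3] == "A").all() and (labels[3:6] == "B").all()

    def test_all_zero_rows_labeled_unknown(self, two_type_model):
        model, Z = two_type_model
        ctm = pd.DataFrame(0, index=Z.index, columns=["A", "B"])
        labels = model._resolve_mixed(ctm, Z)
        assert (labels == UNKNOWN_LABEL).all()

    def test_tie_goes_to_nearest_neighbor(self):
        sig = SignatureMatrix(
            pd.DataFrame({"A": [1, 0], "B": [0, 1]}, index=["mA", "mB"])
        )
        Z = pd.DataFrame(
            {"mA": [0.0, 10.0, 1.0], "mB": [0.0, 10.0, 0.0]},
            index=["cleanA", "cleanB", "mixed"],
        )
        model = TACITModel(Z, sig, knn_k=2)
        ctm = pd.DataFrame(
            {"A": [1, 0, 1], "B": [0, 1, 1]}, index=Z.index
        )
        labels = model._resolve_mixed(ctm, Z)
        assert labels["mixed"] == "A"  # one vote each; nearest is cleanA


class TestEndToEnd:
    def test_recovers_planted_types_with_hierarchy(self, signature):
        cfg = SynthConfig(seed=21)
        table, truth = synth_marker_table(cfg, signature, n_cells=2000)
        res = TACITModel(table, signature, target_fraction=0.02).fit(seed=21)
        acc = (res.labels == truth.cell_types).mean()
        assert acc >= 0.85
        # AND gate: refined subtype membership implies primary membership
        for t in signature.subtype_columns:
            assert (res.ctm[t] <= res.ctm_primary[t]).all()

    def test_subtype_gate_uses_level2_marker(self, signature):
        cfg = SynthConfig(seed=22)
        table, truth = synth_marker_table(cfg, signature, n_cells=2000)
        res = TACITModel(table, signature, target_fraction=0.02).fit(seed=22)
        Z = znormalize_intensities(table.drop(columns=["x", "y"]))
        cd8_cut = res.marker_cutoffs.get("CD8")
        assert cd8_cut is not None
        tex_pos = res.ctm["Tex"].astype(bool)
        assert (Z.loc[tex_pos.to_numpy(), "CD8"] >= cd8_cut).all()

    def test_full_fit_deterministic(self, signature):
        cfg = SynthConfig(seed=23)
        table, _ = synth_marker_table(cfg, signature, n_cells=1200)
        r1 = TACITModel(table, signature, target_fraction=0.02).fit(seed=5)
        r2 = TACITModel(table, signature, target_fraction=0.02).fit(seed=5)
        pd.testing.assert_series_equal(r1.labels, r2.labels)
        assert r1.cutoffs == r2.cutoffs

    def test_summary_reports_cutoffs(self, signature):
        cfg = SynthConfig(seed=24)
        table, _ = synth_marker_table(cfg, signature, n_cells=1000)
        res = TACITModel(table, signature, target_fraction=0.02).fit(seed=0)
        text = res.summary()
        assert "cutoff" in text and "Tex" in text
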
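import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methtraj.io import BetaMatrix
from methtraj.preprocess import (
    average_dname,
    filter_probes,
    group_cv,
    impute_missing,
    intersect_platforms,
    normalize_beta,
)
from methtraj.simulate import SimConfig, simulate_dataset

from conftest import make_beta, make_sheet


class TestFilterProbes:
    def test_boundary_of_the_twenty_percent_rule(self):
        # 10 samples: 3 missing (30%) goes, exactly 2 missing (20%) stays
        vals = np.full((3, 10), 0.5)
        vals[0, :3] = np.nan
        vals[1, :2] = np.nan
        bm = make_beta(vals, probe_ids=["drop", "keep", "full"])
        out = filter_probes(bm, max_missing_frac=0.2)
        assert list(out.probe_ids) == ["keep", "full"]
        assert list(out.sample_ids) == list(bm.sample_ids)

    def test_fully_observed_identity(self):
        bm = make_beta(np.full((5, 4), 0.3))
        out = filter_probes(bm)
        pd.testing.assert_frame_equal(out.values, bm.values)

    def test_empty_result_warns_not_raises(self):
        vals = np.full((2, 4), np.nan)
        vals[:, 0] = 0.5  # 75% missing everywhere
        with pytest.warns(UserWarning):
            out = filter_probes(make_beta(vals), 0.2)
        assert out.shape == (0, 4)


class TestImpute:
    def test_row_mean_arithmetic(self):
        bm = make_beta([[0.2, np.nan, 0.4]])
        out = impute_missing(bm, "row_mean")
        assert out.values.iloc[0].tolist() == [0.2, pytest.approx(0.3), 0.4]

    def test_no_missing_is_identity(self):
        bm = make_beta(np.full((3, 3), 0.7))
        assert impute_missing(bm, "row_mean") is bm

    def test_knn_k1_matches_brute_force(self):
        # 4 probes x 3 samples; s1 is missing probe p0
        vals = np.array(
            [
                [0.2, np.nan, 0.7],
                [0.1, 0.12, 0.9],
                [0.2, 0.22, 0.8],
                [0.3, 0.28, 0.7],
            ]
        )
        bm = make_beta(vals)
        # brute-force nearest neighbour of s1 among donors of p0, by
        # mean squared difference over mutually observed probes
        d_to_s0 = np.nanmean((vals[1:, 1] - vals[1:, 0]) ** 2)
        d_to_s2 = np.nanmean((vals[1:, 1] - vals[1:, 2]) ** 2)
        expected = vals[0, 0] if d_to_s0 < d_to_s2 else vals[0, 2]
        out = impute_missing(bm, "knn", k=1)
        assert out.values.iloc[0, 1] == pytest.approx(expected)
        assert expected == 0.2  # s0 is the near neighbour in this toy

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_imputation_never_alters_observed_cells(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1, size=(6, 5))
        mask = rng.random((6, 5)) < 0.25
        mask[:, 0] = False  # keep every probe observed at least once
        vals[mask] = np.nan
        bm = make_beta(vals.copy())
        for method in ("row_mean", "knn"):
            out = impute_missing(bm, method, k=2)
            assert out.n_missing() == 0
            obs = ~mask
            np.testing.assert_array_equal(
                out.values.to_numpy()[obs], np.nan_to_num(vals)[obs]
            )
            assert ((out.values.to_numpy() >= 0) & (out.values.to_numpy() <= 1)).all()


class TestIntersect:
    def test_pairwise_intersection(self):
        a = make_beta(np.full((3, 2), 0.5), probe_ids=["a", "b", "c"])
        b = make_beta(np.full((3, 2), 0.5), probe_ids=["b", "c", "d"])
        out = intersect_platforms([a, b])
        assert [list(x.probe_ids) for x in out] == [["b", "c"], ["b", "c"]]

    def test_single_input_unchanged(self):
        a = make_beta(np.full((2, 2), 0.5), probe_ids=["b", "a"])
        (out,) = intersect_platforms([a])
        assert list(out.probe_ids) == ["a", "b"]  # sorted per contract

    def test_disjoint_sets_error(self):
        a = make_beta(np.full((1, 2), 0.5), probe_ids=["a"])
        b = make_beta(np.full((1, 2), 0.5), probe_ids=["b"])
        with pytest.raises(ValueError):
            intersect_platforms([a, b])


class TestNormalize:
    def test_none_is_identity(self):
        bm = make_beta([[0.1, 0.9]])
        assert normalize_beta(bm, "none") is bm

    def test_quantile_mean_order_statistics(self):
        bm = make_beta(np.array([[0.1, 0.2], [0.3, 0.4]]))
        out = normalize_beta(bm, "quantile")
        np.testing.assert_allclose(out.values.to_numpy(), [[0.15, 0.15], [0.35, 0.35]])

    def test_constant_matrix_is_fixed_point(self):
        bm = make_beta(np.full((4, 3), 0.42))
        out = normalize_beta(bm, "quantile")
        np.testing.assert_allclose(out.values.to_numpy(), 0.42)

    def test_quantile_idempotent(self):
        rng = np.random.default_rng(7)
        bm = make_beta(rng.uniform(0, 1, size=(50, 6)))
        once = normalize_beta(bm, "quantile")
        twice = normalize_beta(once, "quantile")
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )


class TestSummaries:
    def test_adname_is_column_mean(self):
        bm = make_beta(np.array([[0.2, 0.5], [0.6, 0.5]]))
        out = average_dname(bm)
        assert out["adname"].tolist() == [pytest.approx(0.4), pytest.approx(0.5)]

    def test_adname_invariant_to_orderings(self):
        rng = np.random.default_rng(5)
        bm = make_beta(rng.uniform(0, 1, size=(20, 6)))
        base = average_dname(bm)
        shuffled = BetaMatrix(
            bm.values.sample(frac=1, axis=0, random_state=1).sample(
                frac=1, axis=1, random_state=2
            )
        )
        out = average_dname(shuffled)
        pd.testing.assert_frame_equal(out.sort_index(), base.sort_index())

    def test_cervix_like_baseline_recovered(self):
        cfg = SimConfig(seed=2, n_probes=2000, baseline_mean=0.18)
        bm, *_ = simulate_dataset(cfg)
        out = average_dname(bm)
        assert abs(out["adname"].mean() - 0.18) < 0.02

    def test_group_cv_hand_values(self):
        sheet = make_sheet(3, 2, 0)
        summaries = pd.DataFrame(
            {"adname": [0.4, 0.4, 0.4, 0.4, 0.6]},
            index=pd.Index(["N0", "N1", "N2", "P0", "P1"], name="sample_id"),
        )
        out = group_cv(summaries, sheet).set_index("stage")
        assert out.loc["N", "cv"] == pytest.approx(0.0)
        # population sd of (0.4, 0.6) is 0.1; mean 0.5 -> cv 0.2
        assert out.loc["P", "cv"] == pytest.approx(0.2)

    def test_group_cv_scale_invariant(self):
        sheet = make_sheet(3, 0, 0)
        a = pd.DataFrame(
            {"adname": [0.2, 0.3, 0.4]},
            index=pd.Index(["N0", "N1", "N2"], name="sample_id"),
        )
        cv1 = group_cv(a, sheet)["cv"].iloc[0]
        cv2 = group_cv(a * 2, sheet)["cv"].iloc[0]
        assert cv1 == pytest.approx(cv2)

    def test_single_sample_group_error_names_group(self):
        sheet = make_sheet(2, 1, 0)
        summaries = pd.DataFrame(
            {"adname": [0.4, 0.5, 0.6]},
            index=pd.Index(["N0", "N1", "P0"], name="sample_id"),
        )
        with pytest.raises(ValueError, match="P"):
            group_cv(summaries, sheet)


def test_filter_then_impute_completes_matrix():
    rng = np.random.default_rng(9)
    vals = rng.uniform(0, 1, size=(100, 10))
    vals[rng.random((100, 10)) < 0.15] = np.nan
    bm = make_beta(vals)
    out = impute_missing(filter_probes(bm, 0.2), "row_mean")
    assert out.n_missing() == 0
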
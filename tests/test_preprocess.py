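import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import farmbiome as fb
from farmbiome.preprocess import clr_transform, procrustes_correlation


class TestSparsityFilter:
    def test_hand_enumerated_zero_fractions(self, toy_counts):
        counts, meta = toy_counts
        out = fb.filter_sparse_genera(counts, meta)
        # g_clean 0% zeros -> kept; g_half_lhs 50% in LHS -> dropped;
        # g_third 33.3% in HHS -> dropped; g_sixth 16.7% in both -> kept.
        assert list(out.columns) == ["g_clean", "g_sixth"]
        assert out.index.equals(counts.index)

    def test_idempotent(self, toy_counts):
        counts, meta = toy_counts
        once = fb.filter_sparse_genera(counts, meta)
        twice = fb.filter_sparse_genera(once, meta)
        pd.testing.assert_frame_equal(once, twice)

    def test_boundary_is_exclusive(self, toy_counts):
        """Exactly 25% zeros within a status excludes the genus."""
        counts, meta = toy_counts
        counts = counts.copy()
        counts["g_boundary"] = [0, 0, 1, 1, 2, 2, 1, 1, 1, 1, 1, 1]
        out = fb.filter_sparse_genera(counts, meta, max_zero_fraction=2 / 6)
        assert "g_boundary" not in out.columns  # 2/6 zeros == threshold -> out
        assert "g_sixth" in out.columns  # 1/6 < threshold -> kept

    def test_all_excluded_raises_with_diagnostic(self, toy_counts):
        counts, meta = toy_counts
        with pytest.raises(ValueError, match="zero fraction"):
            fb.filter_sparse_genera(
                counts[["g_half_lhs", "g_third"]], meta
            )


class TestZeroReplacement:
    def test_no_zeros_identity_both_modes(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        for mode in ("pseudocount_one", "half_minimum"):
            pd.testing.assert_frame_equal(fb.replace_zeros(df, mode), df)

    def test_half_minimum_closed_form(self):
        df = pd.DataFrame({"g": [0.0, 4.0, 8.0]})
        out = fb.replace_zeros(df, "half_minimum")
        assert list(out["g"]) == [2.0, 4.0, 8.0]

    def test_pseudocount_one_closed_form(self):
        df = pd.DataFrame({"g": [0.0, 3.0, 0.0, 5.0]})
        out = fb.replace_zeros(df, "pseudocount_one")
        assert list(out["g"]) == [1.0, 3.0, 1.0, 5.0]

    def test_all_zero_genus_rejected(self):
        df = pd.DataFrame({"g": [0.0, 0.0], "h": [1.0, 2.0]})
        with pytest.raises(ValueError, match="all-zero"):
            fb.replace_zeros(df)


class TestReferenceSelection:
    def test_constant_relative_abundance_wins(self):
        # g_const is a fixed 10% of every sample -> CV 0.
        df = pd.DataFrame(
            {
                "g_const": [1.0, 2.0, 3.0],
                "g_a": [5.0, 11.0, 6.0],
                "g_b": [4.0, 7.0, 21.0],
            }
        )
        assert fb.select_alr_reference(df) == "g_const"

    def test_hand_computed_cv_ordering(self):
        # Relative abundances: col a = (.5,.55,.45): mean .5, sd .05 -> CV .1
        # col b = (.5,.45,.55) complements -> same CV; instead build explicit:
        df = pd.DataFrame(
            {
                "a": [50.0, 55.0, 45.0],
                "b": [50.0, 45.0, 55.0],
            }
        )
        # two-column table: rel abundances mirror; CVs equal -> tie-break 'a'
        assert fb.select_alr_reference(df) == "a"
        df3 = pd.DataFrame(
            {
                "low_cv": [10.0, 10.5, 9.5],
                "high_cv": [10.0, 16.0, 5.0],
                "rest": [80.0, 73.5, 85.5],
            }
        )
        rel = df3.div(df3.sum(axis=1), axis=0)
        cv = rel.std(ddof=1) / rel.mean()
        assert cv["low_cv"] < cv["high_cv"]
        assert fb.select_alr_reference(df3) == "low_cv"

    def test_requires_two_genera(self):
        with pytest.raises(ValueError):
            fb.select_alr_reference(pd.DataFrame({"only": [1.0, 2.0]}))


class TestAlr:
    def test_closed_form_row(self):
        df = pd.DataFrame([[2.0, 4.0, 1.0]], columns=["a", "b", "r"])
        alr = fb.alr_transform(df, "r")
        np.testing.assert_allclose(
            alr.values.to_numpy()[0], [np.log(2), np.log(4)], atol=1e-12
        )

    def test_reference_equal_gives_zero_column(self):
        df = pd.DataFrame({"a": [3.0, 5.0], "r": [3.0, 5.0]})
        alr = fb.alr_transform(df, "r")
        np.testing.assert_allclose(alr.values["a"], 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e4),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.uniform(0.5, 20.0, size=(4, 5)), columns=list("abcde")
        )
        alr1 = fb.alr_transform(df, "c").values
        scaled = df.copy()
        scaled.iloc[1] *= scale
        alr2 = fb.alr_transform(scaled, "c").values
        np.testing.assert_allclose(alr1, alr2, rtol=1e-9, atol=1e-9)

    def test_rejects_nonpositive(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "r": [1.0, 1.0]})
        with pytest.raises(ValueError):
            fb.alr_transform(df, "r")


def _procrustes_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force Procrustes correlation via the full-SVD sum-of-squares form.

    Centre both, scale to unit Frobenius norm, then the minimised residual
    is 1 - (sum of singular values of A'B)^2, so the correlation is the
    singular-value sum itself.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a /= np.linalg.norm(a)
    b /= np.linalg.norm(b)
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(s.sum())


class TestProcrustes:
    def test_self_comparison_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        assert procrustes_correlation(x, x) == pytest.approx(1.0, abs=1e-10)

    def test_similarity_transform_invisible(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        y = 3.5 * x @ rot + np.array([2.0, -1.0])
        assert procrustes_correlation(x, y) == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle_on_random_configurations(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(size=(20, 5))
            b = rng.normal(size=(20, 5))
            assert procrustes_correlation(a, b) == pytest.approx(
                _procrustes_oracle(a, b), abs=1e-8
            )

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(15, 4)), rng.normal(size=(15, 4))
        assert procrustes_correlation(a, b) == pytest.approx(
            procrustes_correlation(b, a), abs=1e-10
        )

    def test_isometry_check_uses_clr_partner(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            rng.uniform(1.0, 50.0, size=(8, 6)), columns=list("abcdef")
        )
        alr = fb.alr_transform(df, "f")
        corr = fb.procrustes_isometry_check(alr, df)
        expected = _procrustes_oracle(
            np.pad(alr.values.to_numpy(), ((0, 0), (0, 1))),
            clr_transform(df).to_numpy(),
        )
        assert 0.0 < corr <= 1.0
        assert corr == pytest.approx(expected, abs=1e-8)


class TestAutoscale:
    def test_closed_form_sample_sd(self):
        alr = fb.AlrMatrix(
            values=pd.DataFrame({"g": [1.0, 2.0, 3.0]}), reference="r"
        )
        scaled, record = fb.autoscale(alr)
        np.testing.assert_allclose(scaled["g"], [-1.0, 0.0, 1.0], atol=1e-12)
        assert record.means["g"] == pytest.approx(2.0)
        assert record.sds["g"] == pytest.approx(1.0)

    def test_postconditions_on_random_input(self):
        rng = np.random.default_rng(9)
        alr = fb.AlrMatrix(
            values=pd.DataFrame(rng.normal(2, 3, size=(20, 6))), reference="r"
        )
        scaled, _ = fb.autoscale(alr)
        assert scaled.mean().abs().max() < 1e-10
        assert (scaled.std(ddof=1) - 1).abs().max() < 1e-10

    def test_zero_variance_column_named_in_error(self):
        alr = fb.AlrMatrix(
            values=pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 4.0]}),
            reference="r",
        )
        with pytest.raises(ValueError, match="flat"):
            fb.autoscale(alr)


def test_retained_genera_equals_plsda_columns_plus_reference(wall_dataset):
    counts, meta, _ = wall_dataset
    filtered = fb.filter_sparse_genera(counts, meta)
    replaced = fb.replace_zeros(filtered)
    alr = fb.alr_transform(replaced, fb.select_alr_reference(replaced))
    scaled, _ = fb.autoscale(alr)
    assert filtered.shape[1] == scaled.shape[1] + 1
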
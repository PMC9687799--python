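import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcburden import (
    ConsistencyError,
    DegenerateRangeError,
    DomainError,
    ExpressionMatrix,
    abacus_order,
    compute_gene_shift,
    compute_tcb,
    log2_transform,
    median_shift,
    median_shift_per_gene,
)
from tests.conftest import random_log2_matrix

finite_vectors = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2, max_size=50
).filter(lambda v: max(v) - min(v) > 1e-3)  # keep away from float-underflow ties


class TestMedianShift:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([2, 4, 6], [0.0, 0.5, 1.0]),
            ([10, 0, 5, 7.5], [1.0, 0.0, 0.5, 0.75]),
            ([5, 3], [1.0, 0.0]),
        ],
    )
    def test_formula(self, values, expected):
        assert np.allclose(median_shift(values), expected, atol=1e-15)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateRangeError):
            median_shift([5, 5, 5])

    def test_degenerate_zeros_fallback(self):
        assert np.array_equal(median_shift([5, 5, 5], degenerate="zeros"), [0.0, 0.0, 0.0])

    def test_too_short(self):
        with pytest.raises(DomainError):
            median_shift([1.0])

    @given(finite_vectors)
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_formula(self, v):
        arr = np.array(v)
        expected = (arr - arr.min()) / (arr.max() - arr.min())
        assert np.allclose(median_shift(arr), expected, atol=1e-12)

    @given(
        finite_vectors,
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=-1e3, max_value=1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_affine_invariance(self, v, a, b):
        arr = np.array(v)
        assert np.allclose(median_shift(a * arr + b), median_shift(arr), atol=1e-9)

    @given(finite_vectors)
    @settings(max_examples=100, deadline=None)
    def test_endpoints_and_order(self, v):
        out = median_shift(np.array(v))
        assert out.min() == 0.0 and out.max() == 1.0
        order = np.argsort(v, kind="stable")
        assert (np.diff(out[order]) >= 0).all()  # weakly order-preserving


class TestLog2Transform:
    def test_values(self):
        m = ExpressionMatrix(
            values=pd.DataFrame([[3.0, 0.0], [1.0, 7.0]], index=["A", "B"], columns=["S1", "S2"]),
            scale="raw",
        )
        out = log2_transform(m, pseudocount=1.0)
        assert out.scale == "log2"
        assert out.values.loc["A", "S1"] == 2.0  # log2(3+1)
        assert out.values.loc["A", "S2"] == 0.0  # log2(0+1)
        assert out.values.loc["B", "S2"] == 3.0

    def test_zero_without_pseudocount_is_domain_error(self):
        m = ExpressionMatrix(
            values=pd.DataFrame([[0.0, 1.0], [1.0, 1.0]], index=["A", "B"], columns=["S1", "S2"]),
            scale="raw",
        )
        with pytest.raises(DomainError, match="A"):
            log2_transform(m, pseudocount=0.0)

    def test_already_log2_is_noop_with_warning(self, tiny_matrix):
        with pytest.warns(UserWarning, match="no-op"):
            out = log2_transform(tiny_matrix)
        pd.testing.assert_frame_equal(out.values, tiny_matrix.values)


class TestComputeTcb:
    def test_three_sample_sums(self):
        # sums 50 / 75 / 100 per sample -> tcb 0 / 0.5 / 1
        values = pd.DataFrame(
            {"S1": [20.0, 30.0], "S2": [35.0, 40.0], "S3": [55.0, 45.0]}, index=["A", "B"]
        )
        tcb = compute_tcb(ExpressionMatrix(values=values, scale="log2"))
        assert np.allclose(tcb["raw_sum"], [50, 75, 100])
        assert np.allclose(tcb["tcb"], [0.0, 0.5, 1.0])

    def test_gene_permutation_invariance(self, rng):
        m = random_log2_matrix(rng, n_genes=12, n_samples=7)
        perm = m.values.sample(frac=1, random_state=0)
        t1 = compute_tcb(m)
        t2 = compute_tcb(ExpressionMatrix(values=perm, scale="log2"))
        assert np.allclose(t1["tcb"], t2["tcb"])

    def test_requires_log2_scale(self):
        values = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["A", "B"], columns=["S1", "S2"])
        with pytest.raises(DomainError):
            compute_tcb(ExpressionMatrix(values=values, scale="raw"))

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(20):
            n_g, n_s = rng.integers(2, 20, size=2)
            m = random_log2_matrix(rng, n_genes=int(n_g), n_samples=int(n_s))
            sums = m.values.to_numpy().sum(axis=0)
            expected = (sums - sums.min()) / (sums.max() - sums.min())
            assert np.allclose(compute_tcb(m)["tcb"], expected, atol=1e-12)


class TestGeneShift:
    def test_median_summary_formula(self):
        # per-gene medians 0 / 2 / 6 / 8 -> shifts 0 / 0.25 / 0.75 / 1
        values = pd.DataFrame(
            [[0.0, 0.0, 0.0], [2.0, 2.0, 2.0], [6.0, 6.0, 6.0], [8.0, 8.0, 8.0]],
            index=list("ABCD"),
            columns=["S1", "S2", "S3"],
        )
        gs = compute_gene_shift(ExpressionMatrix(values=values, scale="log2"))
        assert np.allclose(gs["shift"], [0.0, 0.25, 0.75, 1.0])

    def test_translation_invariance(self, rng):
        m = random_log2_matrix(rng, n_genes=10, n_samples=5)
        shifted = ExpressionMatrix(values=m.values + 17.3, scale="log2")
        assert np.allclose(
            compute_gene_shift(m)["shift"], compute_gene_shift(shifted)["shift"], atol=1e-9
        )

    def test_per_value_mode_scales_each_gene_to_unit_interval(self, rng):
        m = random_log2_matrix(rng, n_genes=10, n_samples=8)
        out = median_shift_per_gene(m)
        arr = out.values.to_numpy()
        assert out.scale == "shift"
        assert np.allclose(arr.min(axis=1), 0) and np.allclose(arr.max(axis=1), 1)

    def test_per_value_constant_gene_raises_or_zeroes(self):
        values = pd.DataFrame(
            [[2.0, 2.0], [1.0, 3.0]], index=["A", "B"], columns=["S1", "S2"]
        )
        m = ExpressionMatrix(values=values, scale="log2")
        with pytest.raises(DegenerateRangeError):
            median_shift_per_gene(m)
        out = median_shift_per_gene(m, degenerate="zeros")
        assert np.array_equal(out.values.loc["A"].to_numpy(), [0.0, 0.0])


class TestAbacusOrder:
    def _ordered(self, m):
        return abacus_order(m, compute_tcb(m), compute_gene_shift(m))

    def test_sorts_by_tcb_and_gene_shift(self, rng):
        m = random_log2_matrix(rng, n_genes=9, n_samples=7)
        out = self._ordered(m)
        tcb = compute_tcb(out)
        gs = compute_gene_shift(out)
        assert (np.diff(tcb["tcb"]) >= 0).all()
        assert (np.diff(gs["shift"]) >= 0).all()

    def test_idempotent(self, rng):
        m = random_log2_matrix(rng, n_genes=9, n_samples=7)
        once = self._ordered(m)
        twice = self._ordered(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_pure_permutation(self, rng):
        m = random_log2_matrix(rng, n_genes=9, n_samples=7)
        out = self._ordered(m)
        assert sorted(out.gene_ids) == sorted(m.gene_ids)
        assert sorted(out.sample_ids) == sorted(m.sample_ids)
        assert np.allclose(np.sort(out.values.to_numpy().ravel()),
                           np.sort(m.values.to_numpy().ravel()))

    def test_reversal_is_undone(self, rng):
        m = random_log2_matrix(rng, n_genes=6, n_samples=6)
        sorted_m = self._ordered(m)
        reversed_m = ExpressionMatrix(
            values=sorted_m.values.iloc[:, ::-1], scale="log2"
        )
        back = self._ordered(reversed_m)
        pd.testing.assert_frame_equal(back.values, sorted_m.values)

    def test_ties_broken_by_id(self):
        values = pd.DataFrame(
            [[1.0, 1.0, 4.0], [2.0, 2.0, 6.0]], index=["B", "A"], columns=["Sz", "Sa", "Sb"]
        )
        m = ExpressionMatrix(values=values, scale="log2")
        out = self._ordered(m)
        # Sz and Sa have identical sums -> lexicographic by sample id
        assert out.sample_ids[:2] == ["Sa", "Sz"]

    def test_missing_profile_is_consistency_error(self, rng):
        m = random_log2_matrix(rng, n_genes=5, n_samples=5)
        tcb = compute_tcb(m).iloc[1:]
        with pytest.raises(ConsistencyError):
            abacus_order(m, tcb, compute_gene_shift(m))
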
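"""Single-layer mathematics: masks, gather/scatter, linear maps, update."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coarsefine import (
    ConfigurationError,
    LayerConfig,
    NumericError,
    ShapeError,
    apply_update,
    build_inhibition_mask,
    forward,
    im2row,
    inhibition_buffer,
    row2im,
    topdown,
    weight_delta,
    window_geometry,
)
from coarsefine.layer import naive_inhibition_buffer, naive_weight_delta

RTOL, ATOL = 1e-9, 1e-12


# --- inhibition topology -------------------------------------------------


class TestInhibitionMask:
    @pytest.mark.parametrize(
        "shape,variant,expected",
        [
            ((1, 1), "printed", [[1.0]]),
            ((2, 1), "printed", [[1, 1], [0, 1]]),
            ((2, 1), "strict_raster", [[1, 1], [0, 1]]),
        ],
    )
    def test_small_masks(self, shape, variant, expected):
        assert build_inhibition_mask(shape, variant).tolist() == np.asarray(
            expected, dtype=float
        ).tolist()

    def test_printed_2x2_rowwise(self):
        # direct enumeration of the row-comparison predicate
        m = build_inhibition_mask((2, 2), "printed")
        assert m[:2].tolist() == [[1, 1, 1, 1], [1, 1, 1, 1]]
        assert m[2:].tolist() == [[0, 0, 1, 1], [0, 0, 1, 1]]

    def test_matches_predicate_enumeration(self):
        j_r, j_c = 3, 4
        m = build_inhibition_mask((j_r, j_c), "printed")
        for a in range(j_r * j_c):
            for b in range(j_r * j_c):
                assert m[a, b] == (1.0 if a // j_c <= b // j_c else 0.0)

    @pytest.mark.parametrize("variant", ["printed", "strict_raster"])
    def test_diagonal_self_inhibition(self, variant):
        m = build_inhibition_mask((3, 5), variant)
        assert np.all(np.diag(m) == 1.0)

    @given(
        j_r=st.integers(1, 6),
        j_c=st.integers(1, 6),
        variant=st.sampled_from(["printed", "strict_raster"]),
    )
    @settings(deadline=None, derandomize=True)
    def test_cumulativity(self, j_r, j_c, variant):
        """The inhibitor set of a later bank row contains every earlier
        row's inhibitor set."""
        m = build_inhibition_mask((j_r, j_c), variant)
        for b_early in range(j_r * j_c):
            for b_late in range(j_r * j_c):
                if b_early // j_c <= b_late // j_c and (
                    variant == "printed" or b_early <= b_late
                ):
                    inhibitors_early = set(np.flatnonzero(m[:, b_early]))
                    inhibitors_late = set(np.flatnonzero(m[:, b_late]))
                    assert inhibitors_early <= inhibitors_late

    def test_bad_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            build_inhibition_mask((0, 3))
        with pytest.raises(ConfigurationError):
            build_inhibition_mask((2, 2), "circular")


# --- im2row / row2im -----------------------------------------------------


def _geom(grid, field, **kw):
    return window_geometry(grid, field, **kw)


class TestGatherScatter:
    def test_layer1_default_patch_count(self):
        g = _geom((36, 36), (3, 3))
        assert g.grid == (34, 34)
        patches = im2row(np.random.default_rng(0).random((36, 36)), g)
        assert patches.shape == (1156, 9)

    def test_window_sized_image_single_row(self):
        img = np.arange(9.0).reshape(3, 3)
        g = _geom((3, 3), (3, 3))
        patches = im2row(img, g)
        assert patches.shape == (1, 9)
        np.testing.assert_array_equal(patches[0], img.ravel())

    def test_gather_matches_bruteforce_loop(self, rng):
        img = rng.random((3, 3))
        g = _geom((3, 3), (2, 2))
        patches = im2row(img, g)
        expected = [
            [img[r, c], img[r, c + 1], img[r + 1, c], img[r + 1, c + 1]]
            for r in range(2)
            for c in range(2)
        ]
        np.testing.assert_allclose(patches, expected)

    def test_dilated_gather_offsets(self, rng):
        # gap 1 between cells: window gathers elements 0 and 2 along each axis
        img = rng.random((5, 5))
        g = _geom((5, 5), (2, 2), gap=(1, 1))
        patches = im2row(img, g)
        assert g.grid == (3, 3)
        np.testing.assert_allclose(
            patches[0], [img[0, 0], img[0, 2], img[2, 0], img[2, 2]]
        )

    def test_cell_block_flatten_order(self, rng):
        # 2 cells, block 1x2: patch order is (cell, within-cell)
        img = rng.random((1, 4))  # 2 cells of 1x2 along columns
        g = _geom((1, 2), (1, 2), cell_block=(1, 2))
        patches = im2row(img, g)
        np.testing.assert_array_equal(patches[0], img.ravel())

    def test_overlap_counts_3x3_with_2x2_windows(self):
        g = _geom((3, 3), (2, 2))
        _, counts = row2im(np.zeros((4, 4)), g)
        np.testing.assert_array_equal(
            counts, [[1, 2, 1], [2, 4, 2], [1, 2, 1]]
        )

    def test_zero_rows_scatter_to_zero_grid(self):
        g = _geom((4, 4), (2, 2))
        grid, _ = row2im(np.zeros((9, 4)), g)
        assert not grid.any()

    @given(
        h=st.integers(3, 7),
        w=st.integers(3, 7),
        f=st.integers(1, 3),
        gap=st.integers(0, 1),
    )
    @settings(deadline=None, derandomize=True)
    def test_scatter_is_adjoint_of_gather(self, h, w, f, gap):
        """row2im(im2row(x)) equals x weighted by per-pixel overlap counts."""
        span = (f - 1) * (gap + 1) + 1
        if span > min(h, w):
            return
        rng = np.random.default_rng(h * 100 + w * 10 + f)
        img = rng.random((h, w))
        g = _geom((h, w), (f, f), gap=(gap, gap))
        grid, counts = row2im(im2row(img, g), g)
        np.testing.assert_allclose(grid, img * counts, rtol=1e-12)

    def test_window_too_large_raises(self):
        from coarsefine import GeometryError

        with pytest.raises(GeometryError):
            _geom((3, 3), (4, 4))

    def test_shape_mismatch_raises(self):
        g = _geom((4, 4), (2, 2))
        with pytest.raises(ShapeError):
            im2row(np.zeros((5, 5)), g)
        with pytest.raises(ShapeError):
            row2im(np.zeros((2, 2)), g)


# --- forward / topdown ---------------------------------------------------


class TestLinearMaps:
    def test_zero_patches_zero_activation(self):
        assert not forward(np.zeros((4, 6)), np.ones((3, 6))).any()

    def test_layer1_default_activation_shape(self, rng):
        g = _geom((36, 36), (3, 3))
        patches = im2row(rng.random((36, 36)), g)
        acts = forward(patches, rng.normal(size=(36, 9)))
        assert acts.shape == (1156, 36)

    def test_hand_dot_products(self):
        acts = forward(
            np.array([[1.0, 2, 3, 4]]),
            np.array([[1.0, 0, 0, 0], [0, 0, 0, 2.0]]),
        )
        np.testing.assert_array_equal(acts, [[1.0, 8.0]])

    def test_topdown_one_hot_returns_kernel(self, rng):
        W = rng.normal(size=(5, 7))
        onehot = np.zeros((1, 5))
        onehot[0, 3] = 1.0
        np.testing.assert_array_equal(topdown(onehot, W)[0], W[3])

    def test_topdown_scalar_combination(self):
        np.testing.assert_array_equal(
            topdown(np.array([[1.0, 2.0]]), np.array([[2.0], [5.0]])), [[12.0]]
        )

    def test_forward_linearity(self, rng):
        W = rng.normal(size=(4, 6))
        x, y = rng.normal(size=(3, 6)), rng.normal(size=(3, 6))
        np.testing.assert_allclose(
            forward(2.0 * x - 3.0 * y, W),
            2.0 * forward(x, W) - 3.0 * forward(y, W),
            rtol=1e-12,
            atol=1e-12,
        )

    def test_orthonormal_bank_roundtrip(self, rng):
        """With a complete orthonormal bank, topdown(forward(x)) == x."""
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        x = rng.normal(size=(2, 6))
        np.testing.assert_allclose(topdown(forward(x, Q), Q), x, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ShapeError):
            forward(np.zeros((2, 5)), np.zeros((3, 6)))
        with pytest.raises(ShapeError):
            topdown(np.zeros((2, 5)), np.zeros((3, 6)))


# --- inhibition buffer & weight delta ------------------------------------


class TestCumulativeInhibitionUpdate:
    def test_buffer_worked_example(self):
        """n=1, bank 2x1, i=1: target 0 sees only kernel 0, target 1 both."""
        W = np.array([[2.0], [5.0]])
        A = np.array([[1.0, 3.0]])
        M = build_inhibition_mask((2, 1), "printed")
        np.testing.assert_allclose(inhibition_buffer(A, W, M), [[2.0, 17.0]])

    def test_delta_worked_example(self):
        W = np.array([[2.0], [5.0]])
        A = np.array([[1.0, 3.0]])
        I = np.array([[4.0]])
        M = build_inhibition_mask((2, 1), "printed")
        np.testing.assert_allclose(
            weight_delta(I, A, W, M, 0.1), [[0.2], [-3.9]], rtol=1e-12
        )

    def test_zero_activation_zero_buffer_and_delta(self, rng):
        W = rng.normal(size=(4, 3))
        M = build_inhibition_mask((2, 2))
        A = np.zeros((5, 4))
        assert not inhibition_buffer(A, W, M).any()
        assert not weight_delta(rng.normal(size=(5, 3)), A, W, M, 0.5).any()

    def test_zero_learning_rate_zero_delta(self, rng):
        W = rng.normal(size=(4, 3))
        M = build_inhibition_mask((2, 2))
        A = rng.normal(size=(5, 4))
        assert not weight_delta(rng.normal(size=(5, 3)), A, W, M, 0.0).any()

    def test_diagonal_mask_self_term_only(self, rng):
        W = rng.normal(size=(3, 4))
        A = rng.normal(size=(2, 3))
        buf = inhibition_buffer(A, W, np.eye(3))
        for p in range(2):
            for t in range(3):
                np.testing.assert_allclose(
                    buf[p, t * 4 : (t + 1) * 4], A[p, t] * W[t], rtol=1e-12
                )

    def test_oracle_equivalence_random_instances(self):
        """Vectorized buffer and delta match the triple-loop oracles on 100
        seeded random small instances."""
        rng = np.random.default_rng(1234)
        for trial in range(100):
            n = int(rng.integers(1, 6))
            j_r = int(rng.integers(1, 4))
            j_c = int(rng.integers(1, 3))
            i = int(rng.integers(1, 9))
            variant = ["printed", "strict_raster"][trial % 2]
            j = j_r * j_c
            W = rng.normal(size=(j, i))
            A = rng.normal(size=(n, j))
            I = rng.normal(size=(n, i))
            M = build_inhibition_mask((j_r, j_c), variant)
            lr = float(rng.uniform(0.01, 1.0))
            np.testing.assert_allclose(
                inhibition_buffer(A, W, M),
                naive_inhibition_buffer(A, W, M),
                rtol=RTOL,
                atol=ATOL,
            )
            np.testing.assert_allclose(
                weight_delta(I, A, W, M, lr),
                naive_weight_delta(I, A, W, M, lr),
                rtol=RTOL,
                atol=ATOL,
            )

    def test_single_kernel_fixed_point(self):
        """A self-inhibiting unit kernel reproducing its input exactly has
        zero update (the Oja-like fixed point)."""
        W = np.array([[1.0]])
        x = np.array([[1.0]])
        a = forward(x, W)
        d = weight_delta(x, a, W, np.eye(1), 0.3)
        np.testing.assert_allclose(d, [[0.0]], atol=1e-15)

    def test_repeated_update_converges_single_kernel(self):
        """Iterating the update on one fixed patch drives the delta norm to
        zero (scalar recurrence w <- w + a*w(x - w x w) contracts)."""
        W = np.array([[0.3, 0.1]])
        x = np.array([[0.8, 0.6]])
        M = np.eye(1)
        for _ in range(2000):
            a = forward(x, W)
            W = apply_update(W, weight_delta(x, a, W, M, 0.2))
        final_delta = weight_delta(x, forward(x, W), W, M, 0.2)
        assert np.linalg.norm(final_delta) < 1e-10
        # fixed point: unit response along the patch direction
        np.testing.assert_allclose(float(forward(x, W)[0, 0]), 1.0, rtol=1e-6)


class TestSangerReduction:
    def test_single_column_strict_raster_is_deflation(self, rng):
        """With a one-column bank in strict raster order, the delta equals
        Sanger's generalized Hebbian update computed independently."""
        j, i, n = 4, 6, 3
        W = rng.normal(size=(j, i))
        X = rng.normal(size=(n, i))
        A = forward(X, W)
        M = build_inhibition_mask((j, 1), "strict_raster")
        got = weight_delta(X, A, W, M, 0.1)
        # independent GHA: dw_t = lr * sum_p a_pt (x_p - sum_{s<=t} a_ps w_s)
        expected = np.zeros_like(W)
        for t in range(j):
            for p in range(n):
                recon = sum(A[p, s] * W[s] for s in range(t + 1))
                expected[t] += A[p, t] * (X[p] - recon)
        np.testing.assert_allclose(got, 0.1 * expected, rtol=1e-9)

    def test_leading_kernel_finds_top_eigenvector(self):
        """Online training on correlated Gaussians recovers the top
        principal component (|cosine| > 0.95)."""
        rng = np.random.default_rng(42)
        i, j = 8, 3
        Q, _ = np.linalg.qr(rng.normal(size=(i, i)))
        evals = np.array([5.0, 3.0, 1.5, 0.8, 0.5, 0.3, 0.2, 0.1])
        chol = np.linalg.cholesky(Q @ np.diag(evals) @ Q.T)
        M = build_inhibition_mask((j, 1), "strict_raster")
        W = np.random.default_rng(7).uniform(-0.01, 0.01, size=(j, i))
        for t in range(10_000):
            lr = 0.02 / (1.0 + t / 2000.0)  # decaying step: no jitter floor
            x = (chol @ rng.normal(size=i))[None, :]
            a = forward(x, W)
            W = apply_update(W, weight_delta(x, a, W, M, lr))
        cos = abs(W[0] @ Q[:, 0]) / np.linalg.norm(W[0])
        assert cos > 0.95


# --- apply_update --------------------------------------------------------


class TestApplyUpdate:
    def test_zero_delta_identity(self, rng):
        W = rng.normal(size=(3, 4))
        np.testing.assert_array_equal(apply_update(W, np.zeros_like(W)), W)

    def test_elementwise_addition(self):
        np.testing.assert_array_equal(
            apply_update(np.array([[1.0, 1.0]]), np.array([[0.5, -0.5]])),
            [[1.5, 0.5]],
        )

    def test_nonfinite_result_raises(self):
        with pytest.raises(NumericError):
            apply_update(np.array([[1.0]]), np.array([[np.inf]]))

    def test_optional_clip(self):
        out = apply_update(np.array([[1.0]]), np.array([[5.0]]), clip=2.0)
        assert out[0, 0] == 2.0

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            apply_update(np.zeros((2, 2)), np.zeros((2, 3)))


class TestLayerConfig:
    def test_defaults_match_standard_table(self):
        from coarsefine import default_layer_configs

        cfgs = default_layer_configs()
        assert [c.receptive_field for c in cfgs] == [(3, 3), (3, 3), (2, 2), (2, 2)]
        assert [c.bank_shape for c in cfgs] == [(3, 12), (10, 20), (12, 24), (8, 16)]
        assert all(c.learning_rate == 0.0005 for c in cfgs)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            LayerConfig((0, 3), (2, 2))
        with pytest.raises(ConfigurationError):
            LayerConfig((2, 2), (2, 2), learning_rate=-1.0)
        with pytest.raises(ConfigurationError):
            LayerConfig((2, 2), (2, 2), topology_variant="ring")
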
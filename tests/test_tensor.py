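"""Structure-tensor pipeline: gradients, NLM filtering, eigen-structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import _oracles as oracle
from patchfuse import (
    NLMParams,
    TensorField,
    coherence,
    compute_gradient,
    eigen_decompose,
    gaussian_structure_tensor,
    initial_structure_tensor,
    make_test_pattern,
    nlm_filter_plane,
    nlm_weights,
    patch_distance,
    patch_structure_tensor,
)

SMALL = NLMParams(search_radius=3, patch_radius=1, h=0.2)

small_images = arrays(
    np.float64,
    st.tuples(st.integers(4, 12), st.integers(4, 12)),
    elements=st.floats(0, 1, width=32),
)


class TestGradient:
    def test_constant_image_has_zero_gradient(self):
        g = compute_gradient(make_test_pattern("constant", 8))
        assert np.all(g.gx == 0) and np.all(g.gy == 0)

    def test_column_ramp_has_unit_gx_in_interior(self):
        img = np.tile(np.arange(7, dtype=float), (5, 1))
        g = compute_gradient(img)
        assert g.gx[:, 1:-1] == pytest.approx(1.0)
        assert g.gy == pytest.approx(0.0)

    def test_matches_loop_oracle(self, rng):
        img = rng.uniform(size=(5, 5))
        g = compute_gradient(img)
        gx, gy = oracle.gradient(img)
        np.testing.assert_allclose(g.gx, gx, atol=1e-12)
        np.testing.assert_allclose(g.gy, gy, atol=1e-12)

    def test_rejects_degenerate_images(self):
        with pytest.raises(ValueError):
            compute_gradient(np.zeros((1, 5)))
        with pytest.raises(ValueError):
            compute_gradient(np.array([[np.nan, 1.0], [0.0, 1.0]]))


class TestInitialTensor:
    def test_outer_product_entries(self):
        from patchfuse.tensor import GradientField

        g = GradientField(gx=np.full((2, 2), 3.0), gy=np.full((2, 2), 4.0))
        t = initial_structure_tensor(g)
        assert t.j11[0, 0] == 9 and t.j12[0, 0] == 12 and t.j22[0, 0] == 16

    def test_zero_gradient_gives_zero_tensor(self):
        t = initial_structure_tensor(compute_gradient(make_test_pattern("constant", 8)))
        assert np.all(t.j11 == 0) and np.all(t.j12 == 0) and np.all(t.j22 == 0)

    def test_rank_one_eigenvalues_are_gradnorm_and_zero(self, rng):
        """Eigenvalues of the unfiltered tensor are |grad I|^2 and 0."""
        img = rng.uniform(size=(12, 12))
        g = compute_gradient(img)
        e = eigen_decompose(initial_structure_tensor(g))
        np.testing.assert_allclose(e.mu1, g.gx**2 + g.gy**2, atol=1e-12)
        np.testing.assert_allclose(e.mu2, 0.0, atol=1e-10)


class TestGaussianTensor:
    def test_tiny_rho_approaches_identity(self, rng):
        t = initial_structure_tensor(compute_gradient(rng.uniform(size=(10, 10))))
        out = gaussian_structure_tensor(t, rho=1e-4)
        np.testing.assert_allclose(out.j11, t.j11, atol=1e-8)

    def test_constant_field_unchanged(self):
        t = TensorField(j11=np.full((9, 9), 2.0), j12=np.zeros((9, 9)), j22=np.ones((9, 9)))
        out = gaussian_structure_tensor(t, rho=1.5)
        np.testing.assert_allclose(out.j11, 2.0, atol=1e-12)
        np.testing.assert_allclose(out.j22, 1.0, atol=1e-12)

    def test_impulse_reproduces_sampled_kernel(self):
        """A delta in j11 comes back as the normalized truncated Gaussian."""
        rho = 1.0
        n = 33
        t = TensorField(j11=np.zeros((n, n)), j12=np.zeros((n, n)), j22=np.zeros((n, n)))
        t.j11[n // 2, n // 2] = 1.0
        out = gaussian_structure_tensor(t, rho=rho)
        radius = int(4.0 * rho + 0.5)  # default truncation of the discrete kernel
        k1d = np.exp(-np.arange(-radius, radius + 1) ** 2 / (2 * rho**2))
        k1d /= k1d.sum()
        expected = np.outer(k1d, k1d)
        got = out.j11[n // 2 - radius : n // 2 + radius + 1, n // 2 - radius : n // 2 + radius + 1]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_rejects_nonpositive_rho(self):
        t = TensorField(j11=np.zeros((4, 4)), j12=np.zeros((4, 4)), j22=np.zeros((4, 4)))
        with pytest.raises(ValueError):
            gaussian_structure_tensor(t, rho=0.0)


class TestPatchDistance:
    def test_identical_patches_give_zero(self, rng):
        img = rng.uniform(size=(9, 9))
        assert patch_distance(img, (4, 4), (4, 4), SMALL) == 0.0

    def test_single_center_difference(self):
        img = np.full((9, 9), 0.3)
        delta = 0.2
        img[6, 6] += delta
        p = NLMParams(search_radius=3, patch_radius=2, h=0.1)
        from patchfuse.tensor import _patch_kernel

        g = _patch_kernel(2, p.effective_rho)
        assert patch_distance(img, (2, 2), (6, 6), p) == pytest.approx(g[2, 2] * delta**2)

    def test_symmetry_and_oracle(self, rng):
        img = rng.uniform(size=(9, 9))
        p = NLMParams(search_radius=4, patch_radius=2, h=0.1)
        for X, Y in [((0, 0), (4, 6)), ((4, 4), (8, 1)), ((2, 7), (6, 3))]:
            d = patch_distance(img, X, Y, p)
            assert d == pytest.approx(patch_distance(img, Y, X, p))
            assert d == pytest.approx(
                oracle.patch_distance(img, X, Y, 2, p.effective_rho), abs=1e-12
            )


class TestNLMWeights:
    def test_constant_image_gives_uniform_weights(self):
        img = make_test_pattern("constant", 15)
        w = nlm_weights(img, (7, 7), NLMParams(search_radius=3, patch_radius=1))
        nz = w[w > 0]
        assert nz.size == 49
        np.testing.assert_allclose(nz, 1.0 / 49, atol=1e-12)

    def test_window_clipped_at_border(self):
        img = make_test_pattern("constant", 15)
        w = nlm_weights(img, (0, 0), NLMParams(search_radius=3, patch_radius=1))
        assert np.count_nonzero(w) == 16  # 4x4 corner window
        assert w.sum() == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self, rng):
        img = rng.uniform(size=(11, 11))
        p = NLMParams(search_radius=5, patch_radius=2, h=0.1)
        for X in [(5, 5), (0, 3), (10, 10)]:
            got = nlm_weights(img, X, p)
            want = oracle.nlm_weights(img, X, 5, 2, 0.1, p.effective_rho)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_rejects_nonpositive_h(self):
        with pytest.raises(ValueError):
            NLMParams(h=0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(small_images)
    def test_weights_normalized_on_arbitrary_images(self, img):
        w = nlm_weights(img, (img.shape[0] // 2, img.shape[1] // 2), SMALL)
        assert np.all(w >= 0) and np.all(w <= 1)
        assert w.sum() == pytest.approx(1.0, abs=1e-8)


class TestNLMFilter:
    def test_constant_plane_is_fixed_point(self):
        img = make_test_pattern("constant", 12)
        out = nlm_filter_plane(img, img, SMALL)
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    def test_huge_h_limit_is_clipped_box_mean(self, rng):
        plane = rng.uniform(size=(10, 10))
        guide = rng.uniform(size=(10, 10))
        p = NLMParams(search_radius=2, patch_radius=1, h=1e8)
        out = nlm_filter_plane(plane, guide, p)
        H, W = plane.shape
        want = np.empty((H, W))
        for i in range(H):
            for j in range(W):
                win = plane[max(0, i - 2) : i + 3, max(0, j - 2) : j + 3]
                want[i, j] = win.mean()
        np.testing.assert_allclose(out, want, atol=1e-8)

    def test_matches_loop_oracle(self, rng):
        plane = rng.uniform(size=(9, 9))
        guide = rng.uniform(size=(9, 9))
        p = NLMParams(search_radius=3, patch_radius=1, h=0.25)
        out = nlm_filter_plane(plane, guide, p)
        want = oracle.nlm_filter(plane, guide, 3, 1, 0.25, p.effective_rho)
        np.testing.assert_allclose(out, want, atol=1e-10)

    def test_rejects_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            nlm_filter_plane(rng.uniform(size=(5, 5)), rng.uniform(size=(6, 5)), SMALL)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(small_images)
    def test_output_stays_in_input_envelope(self, img):
        out = nlm_filter_plane(img, img, SMALL)
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12


class TestPatchTensor:
    def test_constant_image_gives_zero_tensor(self):
        t = patch_structure_tensor(make_test_pattern("constant", 16), SMALL)
        assert np.allclose(t.j11, 0) and np.allclose(t.j12, 0) and np.allclose(t.j22, 0)

    def test_positive_semidefinite(self, rng):
        t = patch_structure_tensor(rng.uniform(size=(16, 16)), SMALL)
        assert np.all(t.j11 >= -1e-12) and np.all(t.j22 >= -1e-12)
        assert np.all(t.j11 * t.j22 - t.j12**2 >= -1e-10)

    def test_step_edge_dominant_eigenvector_is_edge_normal(self):
        """Near a vertical step the leading eigenvector points along x."""
        e = eigen_decompose(patch_structure_tensor(make_test_pattern("step", 24), SMALL))
        col = 24 // 2  # column of peak gradient
        for row in (8, 12, 16):
            vx, vy = e.v1[row, col]
            assert abs(vx) > 0.999 and abs(vy) < 0.05

    def test_equals_composition_of_stage_oracles(self, rng):
        img = rng.uniform(size=(9, 9))
        p = NLMParams(search_radius=3, patch_radius=1, h=0.2)
        t = patch_structure_tensor(img, p)
        gx, gy = oracle.gradient(img)
        for got, plane in ((t.j11, gx * gx), (t.j12, gx * gy), (t.j22, gy * gy)):
            want = oracle.nlm_filter(plane, img, 3, 1, 0.2, p.effective_rho)
            np.testing.assert_allclose(got, want, atol=1e-10)


class TestEigenDecompose:
    def test_diagonal_tensor(self):
        t = TensorField(
            j11=np.full((2, 2), 5.0), j12=np.zeros((2, 2)), j22=np.full((2, 2), 2.0)
        )
        e = eigen_decompose(t)
        assert np.all(e.mu1 == 5.0) and np.all(e.mu2 == 2.0)
        np.testing.assert_allclose(e.v1[..., 0], 1.0)
        np.testing.assert_allclose(e.v1[..., 1], 0.0)

    def test_closed_form_matches_generic_eigensolver(self, rng):
        j11 = rng.uniform(size=(8, 8))
        j12 = rng.uniform(-1, 1, size=(8, 8))
        j22 = rng.uniform(size=(8, 8))
        e = eigen_decompose(TensorField(j11=j11, j12=j12, j22=j22))
        mu1, mu2 = oracle.eigen(j11, j12, j22)
        np.testing.assert_allclose(e.mu1, mu1, atol=1e-10)
        np.testing.assert_allclose(e.mu2, mu2, atol=1e-10)

    def test_eigenvectors_unit_orthogonal_and_satisfy_eigen_equation(self, rng):
        j11 = rng.uniform(size=(6, 6))
        j12 = rng.uniform(-1, 1, size=(6, 6))
        j22 = rng.uniform(size=(6, 6))
        e = eigen_decompose(TensorField(j11=j11, j12=j12, j22=j22))
        np.testing.assert_allclose(np.sum(e.v1**2, axis=-1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.sum(e.v1 * e.v2, axis=-1), 0.0, atol=1e-12)
        jv_x = j11 * e.v1[..., 0] + j12 * e.v1[..., 1]
        jv_y = j12 * e.v1[..., 0] + j22 * e.v1[..., 1]
        np.testing.assert_allclose(jv_x, e.mu1 * e.v1[..., 0], atol=1e-9)
        np.testing.assert_allclose(jv_y, e.mu1 * e.v1[..., 1], atol=1e-9)

    def test_isotropic_tie_break_pins_axes(self):
        t = TensorField(j11=np.ones((3, 3)), j12=np.zeros((3, 3)), j22=np.ones((3, 3)))
        e = eigen_decompose(t)
        np.testing.assert_array_equal(e.v1[..., 0], 1.0)
        np.testing.assert_array_equal(e.v2[..., 1], 1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        arrays(np.float64, (5, 5), elements=st.floats(0, 10, width=32)),
        arrays(np.float64, (5, 5), elements=st.floats(-5, 5, width=32)),
        arrays(np.float64, (5, 5), elements=st.floats(0, 10, width=32)),
    )
    def test_trace_and_determinant_conserved(self, j11, j12, j22):
        e = eigen_decompose(TensorField(j11=j11, j12=j12, j22=j22))
        assert np.all(e.mu1 >= e.mu2 - 1e-12)
        np.testing.assert_allclose(e.mu1 + e.mu2, j11 + j22, atol=1e-8)
        np.testing.assert_allclose(e.mu1 * e.mu2, j11 * j22 - j12**2, atol=1e-8)


class TestCoherence:
    def test_equal_eigenvalues_give_zero(self):
        from patchfuse.tensor import EigenField

        mu = np.ones((4, 4))
        v = np.zeros((4, 4, 2))
        phi = coherence(EigenField(mu1=mu, mu2=mu, v1=v, v2=v)).phi
        assert np.all(phi == 0)

    def test_squared_gap_value(self):
        from patchfuse.tensor import EigenField

        e = EigenField(
            mu1=np.full((1, 1), 3.0),
            mu2=np.full((1, 1), 1.0),
            v1=np.zeros((1, 1, 2)),
            v2=np.zeros((1, 1, 2)),
        )
        assert coherence(e).phi[0, 0] == 4.0

    def test_monotone_in_gap(self):
        from patchfuse.tensor import EigenField

        gaps = np.array([[0.5, 1.0, 2.0, 3.5]])
        e = EigenField(mu1=1.0 + gaps, mu2=np.ones_like(gaps), v1=None, v2=None)
        phi = coherence(e).phi[0]
        assert np.all(np.diff(phi) > 0)


def test_transpose_symmetry(rng):
    """Transposing the image swaps the j11/j22 planes and transposes phi."""
    img = rng.uniform(size=(12, 10))
    p = NLMParams(search_radius=2, patch_radius=1, h=0.2)
    t = patch_structure_tensor(img, p)
    tT = patch_structure_tensor(img.T, p)
    np.testing.assert_allclose(tT.j11, t.j22.T, atol=1e-12)
    np.testing.assert_allclose(tT.j22, t.j11.T, atol=1e-12)
    phi = coherence(eigen_decompose(t)).phi
    phiT = coherence(eigen_decompose(tT)).phi
    np.testing.assert_allclose(phiT, phi.T, atol=1e-10)
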
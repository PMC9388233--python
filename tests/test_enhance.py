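"""Wavelet transform, deflation PCA, and covariance matched filter."""

import numpy as np
import pytest

from gliomaseg import (
    CovarianceModel,
    EnhanceConfig,
    MultiModalVolume,
    enhance_volume,
    estimate_covariance,
    generalized_snr,
    matched_filter_energy,
    pca_covariance_check,
    pca_fit,
    pca_project,
    wavelet_decompose,
    wavelet_reconstruct,
)
from gliomaseg.enhance import EnhanceError


# -- wavelets ---------------------------------------------------------------


def test_constant_slice_has_zero_details():
    pyr = wavelet_decompose(np.full((16, 16), 3.7), levels=1)
    for band in pyr.details[0]:
        np.testing.assert_array_equal(band, 0.0)


def test_haar_matches_block_filter_bank_oracle(rng):
    """One Haar level equals the 2x2 sum/difference filter bank."""
    x = rng.standard_normal((8, 8))
    pyr = wavelet_decompose(x, levels=1, wavelet_name="haar")
    a = x[0::2, 0::2]
    b = x[0::2, 1::2]
    c = x[1::2, 0::2]
    d = x[1::2, 1::2]
    np.testing.assert_allclose(pyr.approx, (a + b + c + d) / 2, atol=1e-12)
    ch, cv, cd = pyr.details[0]
    # separable Haar pair: H = high-pass along rows, V = along columns,
    # D = along both
    np.testing.assert_allclose(ch, (a + b - c - d) / 2, atol=1e-12)
    np.testing.assert_allclose(cv, (a - b + c - d) / 2, atol=1e-12)
    np.testing.assert_allclose(cd, (a - b - c + d) / 2, atol=1e-12)


def test_orthonormal_energy_conservation(rng):
    x = rng.standard_normal((16, 16))
    pyr = wavelet_decompose(x, levels=2, wavelet_name="db2")
    assert abs(pyr.total_energy() - np.sum(x**2)) < 1e-8


@pytest.mark.parametrize("shape,levels,wavelet", [
    ((32, 32), 1, "haar"),
    ((32, 32), 3, "haar"),
    ((24, 40), 2, "db2"),
    ((17, 33), 1, "haar"),
])
def test_perfect_reconstruction(rng, shape, levels, wavelet):
    x = rng.standard_normal(shape)
    pyr = wavelet_decompose(x, levels=levels, wavelet_name=wavelet)
    np.testing.assert_allclose(wavelet_reconstruct(pyr), x, atol=1e-10)


def test_zeroed_details_give_block_average():
    rng = np.random.default_rng(5)
    x = np.indices((8, 8)).sum(axis=0) % 2 * 1.0  # checkerboard
    pyr = wavelet_decompose(x, levels=1, wavelet_name="haar")
    zeroed = pyr.with_detail_vector(np.zeros(pyr.detail_vector().size))
    rec = wavelet_reconstruct(zeroed)
    block_means = x.reshape(4, 2, 4, 2).mean(axis=(1, 3))
    np.testing.assert_allclose(rec, np.repeat(np.repeat(block_means, 2, 0), 2, 1),
                               atol=1e-12)


def test_all_zero_pyramid_reconstructs_to_zero():
    pyr = wavelet_decompose(np.zeros((8, 8)), levels=2)
    np.testing.assert_array_equal(wavelet_reconstruct(pyr), 0.0)


def test_decompose_rejects_too_small_slice():
    with pytest.raises(EnhanceError):
        wavelet_decompose(np.zeros((4, 4)), levels=3)


# -- deflation PCA ----------------------------------------------------------


def _eig_oracle(x):
    xc = x - x.mean(axis=0)
    evals, evecs = np.linalg.eigh(xc.T @ xc)
    return evals[::-1], evecs[:, ::-1]


def test_rank_one_data_recovers_direction(rng):
    u = np.array([3.0, 0.0, 4.0]) / 5.0
    x = np.outer(rng.standard_normal(30), u)
    basis = pca_fit(x, 2)
    assert min(np.abs(basis.components[:, 0] - u).max(),
               np.abs(basis.components[:, 0] + u).max()) < 1e-8
    assert basis.eigenvalues[1] < 1e-10


@pytest.mark.parametrize("seed", range(5))
def test_deflation_matches_dense_eigendecomposition(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((20, 5))
    basis = pca_fit(x, 5)
    evals, evecs = _eig_oracle(x)
    np.testing.assert_allclose(basis.eigenvalues, evals, atol=1e-8)
    for i in range(5):
        dev = min(np.abs(basis.components[:, i] - evecs[:, i]).max(),
                  np.abs(basis.components[:, i] + evecs[:, i]).max())
        assert dev < 1e-8


def test_basis_is_orthonormal_and_eigenvalues_sorted(rng):
    x = rng.standard_normal((40, 8))
    basis = pca_fit(x, 6)
    gram = basis.components.T @ basis.components
    np.testing.assert_allclose(gram, np.eye(6), atol=1e-10)
    assert np.all(np.diff(basis.eigenvalues) <= 1e-10)


def test_cluster_separation_dominates_first_component(rng):
    n = 40
    x = rng.standard_normal((n, 4)) * 0.5
    x[: n // 2, 1] += 5.0  # separation 10x the noise scale on axis 1
    basis = pca_fit(x, 2)
    assert np.argmax(np.abs(basis.components[:, 0])) == 1


def test_score_covariance_is_diagonal_with_eigenvalues(rng):
    x = rng.standard_normal((25, 6))
    basis = pca_fit(x, 6)
    q = pca_covariance_check(basis, x)
    evals, _ = _eig_oracle(x)
    off = q - np.diag(np.diag(q))
    assert np.abs(off).max() / evals.max() < 1e-6
    np.testing.assert_allclose(np.diag(q), evals, atol=1e-8)


def test_identity_covariance_gives_isotropic_scores():
    rng = np.random.default_rng(11)
    # exactly whitened data -> score covariance proportional to identity
    x = rng.standard_normal((50, 4))
    xc = x - x.mean(0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    xw = u @ vt  # X^T X = I
    basis = pca_fit(xw, 4)
    q = pca_covariance_check(basis, xw)
    np.testing.assert_allclose(q, np.eye(4), atol=1e-8)


def test_full_rank_projection_is_isometry(rng):
    x = rng.standard_normal((15, 5))
    basis = pca_fit(x, 5)
    scores = pca_project(x, basis)
    from scipy.spatial.distance import pdist

    np.testing.assert_allclose(pdist(scores), pdist(x), atol=1e-8)


def test_truncated_reconstruction_error_is_eigenvalue_tail(rng):
    x = rng.standard_normal((30, 6))
    basis = pca_fit(x, 6)
    scores = pca_project(x, basis, 2)
    recon = scores @ basis.components[:, :2].T + basis.mean
    err = np.sum((x - recon) ** 2)
    np.testing.assert_allclose(err, basis.eigenvalues[2:].sum(), rtol=1e-6)


def test_zero_variance_data_warns():
    with pytest.warns(UserWarning, match="zero-variance"):
        basis = pca_fit(np.ones((5, 3)), 2)
    np.testing.assert_array_equal(basis.eigenvalues, 0.0)


def test_k_too_large_rejected(rng):
    with pytest.raises(EnhanceError):
        pca_fit(rng.standard_normal((4, 3)), 4)


# -- covariance estimation --------------------------------------------------


def test_covariance_matches_direct_outer_product_average(rng):
    vecs = rng.standard_normal((200, 27))
    model = estimate_covariance(None, (3, 3, 3), vectors=vecs, ridge=0.0)
    vbar = vecs.mean(axis=0)
    expected = sum(np.outer(v - vbar, v - vbar) for v in vecs) / len(vecs)
    np.testing.assert_allclose(model.r_v, expected, atol=1e-12)
    np.testing.assert_allclose(model.mean, vbar, atol=1e-14)


def test_white_noise_covariance_approaches_scaled_identity():
    rng = np.random.default_rng(0)
    sigma = 2.0
    channel = rng.normal(0, sigma, (20, 20, 20))
    model = estimate_covariance(channel, (3, 3, 3))
    n = model.n_vectors
    tol = 5 * sigma**2 / np.sqrt(n)
    diag = np.diag(model.r_v)
    assert np.abs(diag - sigma**2).max() < tol
    off = model.r_v - np.diag(diag)
    assert np.abs(off).max() < tol


def test_constant_channel_gives_zero_covariance_with_pd_ridge():
    model = estimate_covariance(np.full((8, 8, 8), 4.0), (3, 3, 3))
    np.testing.assert_allclose(model.r_v, 0.0, atol=1e-20)
    np.linalg.cholesky(model.loaded)  # must succeed


def test_too_few_vectors_rejected(rng):
    with pytest.raises(EnhanceError):
        estimate_covariance(None, (3, 3, 3), vectors=rng.standard_normal((10, 27)))


# -- matched filter ---------------------------------------------------------


def test_identity_covariance_energy_is_squared_norm(rng):
    channel = rng.standard_normal((6, 6, 6))
    model = CovarianceModel(np.eye(27), 0.0, (3, 3, 3), 0)
    out = matched_filter_energy(channel, model)
    # interior voxel: energy equals the squared norm of its neighborhood
    s = channel[1:4, 2:5, 2:5].ravel()
    np.testing.assert_allclose(out.energy[2, 3, 3], s @ s, rtol=1e-12)


def test_energy_scales_quadratically(rng):
    channel = rng.standard_normal((8, 8, 8))
    model = estimate_covariance(channel, (3, 3, 3))
    model = CovarianceModel(model.r_v, model.ridge, model.patch_shape,
                            model.n_vectors, mean=np.zeros(27))
    e1 = matched_filter_energy(channel, model).energy
    e3 = matched_filter_energy(3.0 * channel, model).energy
    np.testing.assert_allclose(e3, 9.0 * e1, rtol=1e-10)


def test_energy_invariant_to_constant_offset(rng):
    channel = rng.standard_normal((8, 8, 8))
    e1 = matched_filter_energy(
        channel, estimate_covariance(channel, (3, 3, 3))
    ).energy
    shifted = channel + 17.0
    e2 = matched_filter_energy(
        shifted, estimate_covariance(shifted, (3, 3, 3))
    ).energy
    np.testing.assert_allclose(e2, e1, atol=1e-8)


def test_energy_nonnegative_everywhere(rng):
    channel = rng.standard_normal((10, 10, 10))
    model = estimate_covariance(channel, (3, 3, 3))
    out = matched_filter_energy(channel, model)
    assert np.all(out.energy >= 0)
    assert out.candidate_mask.mean() == pytest.approx(0.05, abs=0.01)


def test_matched_filter_snr_bound_and_equality(rng):
    """No filter h beats s^T R^{-1} s; h = R^{-1} s attains it."""
    p = 8
    a = rng.standard_normal((p, p))
    r = a @ a.T + 0.5 * np.eye(p)
    s = rng.standard_normal(p)
    bound = s @ np.linalg.solve(r, s)
    for _ in range(50):
        h = rng.standard_normal(p)
        h /= np.linalg.norm(h)
        assert generalized_snr(h, r, s) <= bound + 1e-10
    h_opt = np.linalg.solve(r, s)
    assert abs(generalized_snr(h_opt, r, s) - bound) < 1e-8 * bound
    # scaling the optimal filter does not change its SNR
    assert abs(generalized_snr(2.5 * h_opt, r, s) - bound) < 1e-8 * bound


def test_template_mode_scores_matching_pattern_highest(rng):
    channel = rng.normal(0, 1.0, (10, 10, 10))
    template = np.zeros((3, 3, 3))
    template[1, 1, 1] = 1.0
    channel[5, 5, 5] += 8.0  # impulse matching the template
    model = estimate_covariance(channel, (3, 3, 3))
    out = matched_filter_energy(channel, model, template_mode="template",
                                template=template)
    assert np.unravel_index(out.energy.argmax(), out.energy.shape) == (5, 5, 5)


# -- pipeline ---------------------------------------------------------------


def _uniform_lesion_volume(rng, sigma=1.0, contrast=3.0, shape=(48, 48, 48)):
    g = np.ogrid[[slice(0, s) for s in shape]]
    lesion = sum(((gi - s / 2) / r) ** 2
                 for gi, s, r in zip(g, shape, (8, 7, 9))) <= 1.0
    chans = []
    for _ in range(4):
        img = rng.normal(0, sigma, shape)
        img[lesion] += contrast * sigma
        chans.append(img)
    return MultiModalVolume(np.stack(chans), (1, 1, 1), np.eye(4)), lesion


def test_identity_config_preserves_volume(small_phantom):
    volume, _ = small_phantom
    out, energy = enhance_volume(volume, EnhanceConfig(covariance="identity"))
    np.testing.assert_allclose(out.data, volume.data, atol=1e-8)
    assert energy.energy.shape == volume.shape


def test_lesion_energy_contrast_at_three_sigma():
    rng = np.random.default_rng(0)
    volume, lesion = _uniform_lesion_volume(rng)
    _, energy = enhance_volume(volume, EnhanceConfig())
    ratio = energy.energy[lesion].mean() / energy.energy[~lesion].mean()
    assert ratio >= 2.0


def test_enhance_volume_deterministic(small_phantom):
    volume, _ = small_phantom
    out1, e1 = enhance_volume(volume, EnhanceConfig())
    out2, e2 = enhance_volume(volume, EnhanceConfig())
    np.testing.assert_array_equal(out1.data, out2.data)
    np.testing.assert_array_equal(e1.energy, e2.energy)


def test_pca_compression_is_lossy_but_close(small_phantom):
    volume, _ = small_phantom
    full, _ = enhance_volume(volume, EnhanceConfig(covariance="identity"))
    comp, _ = enhance_volume(
        volume, EnhanceConfig(pca_k=8, covariance="identity")
    )
    err = np.abs(comp.data - volume.data).max()
    assert err > 1e-8  # actually compressed
    rel = np.linalg.norm(comp.data - volume.data) / np.linalg.norm(volume.data)
    assert rel < 0.5  # but retains most energy


def test_inconsistent_pyramid_rejected(rng):
    pyr = wavelet_decompose(rng.standard_normal((16, 16)), levels=2)
    pyr.details = pyr.details[:1]  # drop a level
    with pytest.raises(EnhanceError):
        wavelet_reconstruct(pyr)
    pyr2 = wavelet_decompose(rng.standard_normal((16, 16)), levels=1)
    with pytest.raises(EnhanceError, match="length"):
        pyr2.with_detail_vector(np.zeros(7))


def test_singular_covariance_without_ridge_instructs_ridge(rng):
    model = CovarianceModel(np.zeros((27, 27)), 0.0, (3, 3, 3), 0)
    with pytest.raises(EnhanceError, match="ridge"):
        matched_filter_energy(rng.standard_normal((6, 6, 6)), model)
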
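"""Slice enhancement: wavelets, deflation PCA, covariance matched filter.

The enhancement stage runs per axial slice of each modality:

1. a 2D discrete wavelet transform splits the slice into an
   approximation band ``W_phi`` and detail bands ``W_psi^i``,
   ``i in {H, V, D}``, per scale;
2. optionally, the detail coefficients of the whole slice stack are
   compressed to ``k`` principal components found by *deflation* PCA —
   each component maximizes the explained norm of the residual matrix
   left after subtracting the previously found components;
3. the reconstructed channel is scored voxel-by-voxel by a matched
   filter: with ``R_v`` the covariance of local neighborhood vectors
   ``v`` and ``s`` the (mean-removed) neighborhood at a voxel, the
   optimal linear filter ``h ∝ R_v^{-1} s`` attains the energy
   ``E_p = s^T R_v^{-1} s``, the quantity mapped here.  High ``E_p``
   flags voxels whose neighborhood is anomalous under the background
   covariance — candidate tumor voxels.

MRI magnitude images are real, so conjugate transposition degenerates
to transposition throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.linalg import cho_factor, cho_solve

from .volume_io import MultiModalVolume

__all__ = [
    "WaveletPyramid",
    "PCABasis",
    "CovarianceModel",
    "EnhancedVolume",
    "EnhanceConfig",
    "wavelet_decompose",
    "wavelet_reconstruct",
    "pca_fit",
    "pca_covariance_check",
    "pca_project",
    "estimate_covariance",
    "matched_filter_energy",
    "generalized_snr",
    "enhance_volume",
]


class EnhanceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Wavelet pyramid (forward / inverse 2D DWT per slice)
# ---------------------------------------------------------------------------

_DWT_MODE = "periodization"  # keeps dyadic sizes; orthonormal filters stay an isometry


@dataclass
class WaveletPyramid:
    """Approximation + detail coefficients of one 2D slice.

    ``approx`` holds ``W_phi`` at the coarsest retained scale ``j0``;
    ``details[j]`` is the ``(H, V, D)`` detail triple at level ``j``
    (level 0 = coarsest retained).  For an orthonormal wavelet the total
    coefficient energy equals the slice energy.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    levels: int
    wavelet_name: str
    slice_shape: tuple[int, int]

    def total_energy(self) -> float:
        e = float(np.sum(self.approx.astype(np.float64) ** 2))
        for triple in self.details:
            for band in triple:
                e += float(np.sum(band.astype(np.float64) ** 2))
        return e

    def detail_vector(self) -> np.ndarray:
        """All detail bands flattened into one vector (fixed order)."""
        return np.concatenate(
            [band.ravel() for triple in self.details for band in triple]
        )

    def with_detail_vector(self, vec: np.ndarray) -> "WaveletPyramid":
        """Rebuild the pyramid with detail bands taken from ``vec``."""
        expected = sum(b.size for t in self.details for b in t)
        if vec.size != expected:
            raise EnhanceError(
                f"detail vector length {vec.size} != expected {expected}"
            )
        out, pos = [], 0
        for triple in self.details:
            new_triple = []
            for band in triple:
                n = band.size
                new_triple.append(vec[pos : pos + n].reshape(band.shape))
                pos += n
            out.append(tuple(new_triple))
        if pos != vec.size:
            raise EnhanceError("detail vector length mismatch")
        return replace(self, details=out)


def wavelet_decompose(
    slice2d: np.ndarray, levels: int = 1, wavelet_name: str = "haar"
) -> WaveletPyramid:
    """Forward 2D DWT of one slice down to ``levels`` scales."""
    x = np.asarray(slice2d, dtype=np.float64)
    if x.ndim != 2:
        raise EnhanceError("wavelet_decompose expects a 2D slice")
    m, n = x.shape
    if levels < 1:
        raise EnhanceError("levels must be >= 1")
    if min(m, n) < 2**levels:
        raise EnhanceError(
            f"slice {x.shape} too small for {levels} decomposition levels"
        )
    coeffs = pywt.wavedec2(x, wavelet_name, mode=_DWT_MODE, level=levels)
    approx = coeffs[0]
    details = [tuple(np.asarray(b) for b in triple) for triple in coeffs[1:]]
    return WaveletPyramid(
        approx=np.asarray(approx),
        details=details,
        levels=levels,
        wavelet_name=wavelet_name,
        slice_shape=(m, n),
    )


def wavelet_reconstruct(pyramid: WaveletPyramid) -> np.ndarray:
    """Inverse of :func:`wavelet_decompose`."""
    if len(pyramid.details) != pyramid.levels:
        raise EnhanceError("pyramid level count inconsistent with details")
    coeffs = [pyramid.approx] + [tuple(t) for t in pyramid.details]
    try:
        rec = pywt.waverec2(coeffs, pyramid.wavelet_name, mode=_DWT_MODE)
    except ValueError as exc:  # band shapes inconsistent
        raise EnhanceError(f"cannot reconstruct pyramid: {exc}") from exc
    m, n = pyramid.slice_shape
    if rec.shape != (m, n):
        # periodization pads odd extents to even; crop back (exact)
        if rec.shape[0] < m or rec.shape[1] < n:
            raise EnhanceError(
                f"reconstruction shape {rec.shape} < slice shape {(m, n)}"
            )
        rec = rec[:m, :n]
    return rec


# ---------------------------------------------------------------------------
# Deflation PCA
# ---------------------------------------------------------------------------


@dataclass
class PCABasis:
    """Ordered principal directions found by deflation.

    ``components`` is ``(d, k)`` with orthonormal columns ``w_1..w_k``;
    ``eigenvalues`` are the matching eigenvalues of ``X_c^T X_c``
    (``X_c`` mean-centered), non-increasing.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    mean: np.ndarray
    n_samples: int


def _leading_direction(
    c: np.ndarray, rng: np.random.Generator, max_iter: int = 5000, tol: float = 1e-14
) -> np.ndarray:
    """Leading eigenvector of a small symmetric PSD matrix.

    Power iteration with a Rayleigh-quotient polish; deterministic given
    ``rng``.
    """
    d = c.shape[0]
    w = rng.standard_normal(d)
    w /= np.linalg.norm(w)
    for _ in range(max_iter):
        w_new = c @ w
        nrm = np.linalg.norm(w_new)
        if nrm == 0.0:  # c is (numerically) zero on this subspace
            return w
        w_new /= nrm
        if min(np.linalg.norm(w_new - w), np.linalg.norm(w_new + w)) < tol:
            w = w_new
            break
        w = w_new
    # Rayleigh-quotient polish: cubic convergence near the fixed point.
    for _ in range(3):
        mu = float(w @ c @ w)
        try:
            z = np.linalg.solve(c - (mu + 1e-12 * (1.0 + abs(mu))) * np.eye(d), w)
        except np.linalg.LinAlgError:
            break
        nz = np.linalg.norm(z)
        if not np.isfinite(nz) or nz == 0.0:
            break
        w = z / nz
    return w


def pca_fit(x: np.ndarray, k: int, seed: int = 0) -> PCABasis:
    """Fit ``k`` principal components by sequential deflation.

    The ``i``-th direction maximizes ``||X̂_i w||^2`` over unit ``w``,
    where ``X̂_i = X_c − Σ_{s<i} X_c w_s w_s^T`` is the data matrix
    with the earlier components' contributions subtracted.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise EnhanceError("pca_fit expects a 2D data matrix")
    n, d = x.shape
    if n < 2:
        raise EnhanceError("need at least 2 samples")
    if not 1 <= k <= min(n, d):
        raise EnhanceError(f"k={k} must satisfy 1 <= k <= min(n={n}, d={d})")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc

    if float(np.trace(cov)) <= 1e-300:
        warnings.warn(
            "zero-variance data: returning an arbitrary orthonormal basis",
            stacklevel=2,
        )
        return PCABasis(np.eye(d)[:, :k], np.zeros(k), mean, n)

    rng = np.random.default_rng(seed)
    comps = np.empty((d, 0))
    eigvals = []
    for _ in range(k):
        xhat = xc - (xc @ comps) @ comps.T  # deflated data matrix
        w = _leading_direction(xhat.T @ xhat, rng)
        if comps.shape[1]:  # re-orthogonalize against found components
            w = w - comps @ (comps.T @ w)
            nrm = np.linalg.norm(w)
            if nrm < 1e-12:  # exhausted rank: complete with any orthonormal dir
                w = _complete_direction(comps, rng)
            else:
                w = w / nrm
        eigvals.append(float(w @ cov @ w))
        comps = np.hstack([comps, w[:, None]])

    order = np.argsort(eigvals)[::-1]
    return PCABasis(comps[:, order], np.asarray(eigvals)[order], mean, n)


def _complete_direction(comps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    d = comps.shape[0]
    for _ in range(50):
        w = rng.standard_normal(d)
        w -= comps @ (comps.T @ w)
        nrm = np.linalg.norm(w)
        if nrm > 1e-8:
            return w / nrm
    raise EnhanceError("could not complete an orthonormal basis")


def pca_covariance_check(basis: PCABasis, x: np.ndarray) -> np.ndarray:
    """Covariance matrix of the component scores.

    For an exact fit this is diagonal with the eigenvalues on the
    diagonal: ``Q[j, k] = (X_c w_j)^T (X_c w_k) = λ_k w_j^T w_k``.
    Returned in full so callers can assert the off-diagonal decay.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[1] != basis.components.shape[0]:
        raise EnhanceError("data dimension does not match basis")
    scores = (x - basis.mean) @ basis.components
    return scores.T @ scores


def pca_project(x: np.ndarray, basis: PCABasis, k: int | None = None) -> np.ndarray:
    """Project centered data onto the first ``k`` components."""
    x = np.asarray(x, dtype=np.float64)
    k = basis.components.shape[1] if k is None else k
    if k > basis.components.shape[1]:
        raise EnhanceError(f"k={k} exceeds fitted components")
    if x.shape[1] != basis.components.shape[0]:
        raise EnhanceError("data dimension does not match basis")
    return (x - basis.mean) @ basis.components[:, :k]


# ---------------------------------------------------------------------------
# Covariance matched filter
# ---------------------------------------------------------------------------


@dataclass
class CovarianceModel:
    """Sample covariance ``R_v`` of local neighborhood vectors.

    ``mean`` is the average neighborhood vector ``v̄`` of the source
    region; the matched filter scores deviations ``s = v − v̄`` from
    it, so a flat lesion interior still registers as anomalous while a
    constant intensity offset of the whole channel cancels.  ``ridge``
    is the diagonal-loading constant that guarantees ``R_v + ridge*I``
    admits a Cholesky factorization.
    """

    r_v: np.ndarray
    ridge: float
    patch_shape: tuple[int, int, int]
    n_vectors: int
    mean: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean is None:
            self.mean = np.zeros(self.r_v.shape[0])

    @property
    def loaded(self) -> np.ndarray:
        return self.r_v + self.ridge * np.eye(self.r_v.shape[0])


def _neighborhood_vectors(
    channel: np.ndarray, patch_shape: tuple[int, int, int]
) -> np.ndarray:
    """All full-neighborhood vectors of a channel, shape (n, p)."""
    win = np.lib.stride_tricks.sliding_window_view(channel, patch_shape)
    return win.reshape(-1, int(np.prod(patch_shape)))


def estimate_covariance(
    channel: np.ndarray,
    patch_shape: tuple[int, int, int] = (3, 3, 3),
    source_region: np.ndarray | None = None,
    ridge: float | None = None,
    vectors: np.ndarray | None = None,
) -> CovarianceModel:
    """Estimate ``R_v = E[(v − v̄)(v − v̄)^T]`` from neighborhood vectors.

    ``source_region`` (optional boolean volume over patch *corner*
    positions, i.e. the valid sliding-window grid) restricts which
    neighborhoods contribute.  ``vectors`` bypasses extraction and uses
    the given ``(n, p)`` rows directly.  The returned ridge defaults to
    ``1e-6 * trace(R_v)/p`` and is escalated tenfold until Cholesky
    succeeds.
    """
    p = int(np.prod(patch_shape))
    if vectors is None:
        channel = np.asarray(channel, dtype=np.float64)
        if not np.all(np.isfinite(channel)):
            raise EnhanceError("non-finite values in channel")
        if any(s < ps for s, ps in zip(channel.shape, patch_shape)):
            raise EnhanceError("channel smaller than patch_shape")
        vecs = _neighborhood_vectors(channel, patch_shape)
        if source_region is not None:
            vecs = vecs[np.asarray(source_region, dtype=bool).ravel()]
    else:
        vecs = np.asarray(vectors, dtype=np.float64)
        if vecs.ndim != 2 or vecs.shape[1] != p:
            raise EnhanceError(f"vectors must be (n, {p})")
    n = vecs.shape[0]
    if n < p:
        raise EnhanceError(f"need at least p={p} neighborhood vectors, got {n}")
    vbar = vecs.mean(axis=0)
    centered = vecs - vbar
    r_v = (centered.T @ centered) / n

    if ridge is None:
        ridge = 1e-6 * float(np.trace(r_v)) / p
        if ridge <= 0.0:  # zero-variance data still needs a PD load
            ridge = 1e-12
    eye = np.eye(p)
    for _ in range(20):
        try:
            np.linalg.cholesky(r_v + ridge * eye if ridge else r_v)
            break
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-12)
    else:
        raise EnhanceError("could not regularize covariance to positive definite")
    return CovarianceModel(
        r_v, float(max(ridge, 0.0)), tuple(patch_shape), n, mean=vbar
    )


@dataclass
class EnhancedVolume:
    """Per-voxel matched-filter energy map with a candidate gate."""

    energy: np.ndarray
    threshold: float
    candidate_mask: np.ndarray


def generalized_snr(h: np.ndarray, r: np.ndarray, s: np.ndarray) -> float:
    """Output SNR of filter ``h`` against signal ``s`` in noise cov ``R``.

    ``(h^T s)^2 / (h^T R h)``; bounded above by ``s^T R^{-1} s`` with
    equality iff ``h ∝ R^{-1} s`` (Cauchy–Schwarz in the whitened
    domain).
    """
    h = np.asarray(h, dtype=np.float64)
    num = float(h @ s) ** 2
    den = float(h @ r @ h)
    return num / den


def _energy_from_vectors(vecs: np.ndarray, model: CovarianceModel) -> np.ndarray:
    """``E_p = s^T (R_v + εI)^{-1} s`` with ``s = v − v̄`` per row."""
    s = vecs - model.mean
    a = model.loaded
    try:
        factor = cho_factor(a, lower=True)
    except np.linalg.LinAlgError as exc:
        raise EnhanceError(
            "covariance not positive definite; use ridge > 0"
        ) from exc
    sol = cho_solve(factor, s.T)
    e = np.einsum("ij,ji->i", s, sol)
    return np.maximum(e, 0.0)  # clip tiny negative round-off


def matched_filter_energy(
    channel: np.ndarray,
    model: CovarianceModel,
    template_mode: str = "self",
    template: np.ndarray | None = None,
    threshold_percentile: float = 95.0,
) -> EnhancedVolume:
    """Matched-filter energy at every voxel of a channel.

    ``template_mode="self"`` scores each voxel's own (mean-removed)
    neighborhood: ``E_p = s^T (R_v + εI)^{-1} s``.  With ``"template"``
    a fixed signal template ``t`` is matched instead:
    ``E_p = (t^T (R+εI)^{-1} s)^2 / (t^T (R+εI)^{-1} t)``, the output
    SNR of the optimal filter ``h ∝ (R+εI)^{-1} t``.  Borders use
    reflection padding so the energy map matches the input shape.
    """
    channel = np.asarray(channel, dtype=np.float64)
    ps = model.patch_shape
    if any(s < p for s, p in zip(channel.shape, ps)):
        raise EnhanceError("volume too small for patch_shape")
    pads = [(p // 2, p - 1 - p // 2) for p in ps]
    padded = np.pad(channel, pads, mode="reflect")
    vecs = _neighborhood_vectors(padded, ps)

    if template_mode == "self":
        energy = _energy_from_vectors(vecs, model)
    elif template_mode == "template":
        if template is None:
            raise EnhanceError("template_mode='template' requires a template")
        t = np.asarray(template, dtype=np.float64).ravel()
        if t.size != vecs.shape[1]:
            raise EnhanceError("template size does not match patch_shape")
        factor = cho_factor(model.loaded, lower=True)
        h = cho_solve(factor, t)  # optimal filter direction
        s = vecs - model.mean
        energy = (s @ h) ** 2 / float(t @ h)
        energy = np.maximum(energy, 0.0)
    else:
        raise EnhanceError(f"unknown template_mode {template_mode!r}")

    energy = energy.reshape(channel.shape)
    threshold = float(np.percentile(energy, threshold_percentile))
    return EnhancedVolume(energy, threshold, energy >= threshold)


# ---------------------------------------------------------------------------
# Volume enhancement pipeline
# ---------------------------------------------------------------------------


@dataclass
class EnhanceConfig:
    """Tunable parameters of the slice-enhancement stage.

    ``pca_k=None`` disables detail-coefficient compression.
    ``covariance="identity"`` replaces the estimated ``R_v`` with the
    identity (useful as a null model).  By default the reference
    covariance and mean are estimated once from a volume-wide subsample
    of neighborhoods (anomaly scoring against the global background);
    ``per_slab_covariance=True`` instead re-estimates them from the
    axial slab preceding each scored slice, which adapts to slow trends
    but treats any structure extended across slices as background.
    """

    wavelet: str = "haar"
    levels: int = 1
    pca_k: int | None = None
    patch_shape: tuple[int, int, int] = (3, 3, 3)
    ridge: float | None = None
    threshold_percentile: float = 95.0
    template_mode: str = "self"
    covariance: str = "estimate"  # or "identity"
    per_slab_covariance: bool = False
    max_covariance_samples: int = 4096
    energy_channels: tuple[str, ...] = ("flair", "t1", "t1ce", "t2")
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "EnhanceConfig":
        kwargs = dict(d)
        for key in ("patch_shape", "energy_channels"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _enhance_channel_slices(
    channel: np.ndarray, cfg: EnhanceConfig
) -> np.ndarray:
    """Wavelet-decompose every axial slice, optionally PCA-compress the
    detail coefficients across the slice stack, and reconstruct."""
    nz = channel.shape[2]
    pyramids = [
        wavelet_decompose(channel[:, :, z], cfg.levels, cfg.wavelet)
        for z in range(nz)
    ]
    if cfg.pca_k is not None:
        detail_matrix = np.stack([p.detail_vector() for p in pyramids])
        k = min(cfg.pca_k, min(detail_matrix.shape))
        basis = pca_fit(detail_matrix, k, seed=cfg.seed)
        scores = pca_project(detail_matrix, basis, k)
        compressed = scores @ basis.components[:, :k].T + basis.mean
        pyramids = [
            p.with_detail_vector(compressed[z]) for z, p in enumerate(pyramids)
        ]
    out = np.empty_like(channel, dtype=np.float64)
    for z in range(nz):
        out[:, :, z] = wavelet_reconstruct(pyramids[z])
    return out


def _slab_energy(channel: np.ndarray, cfg: EnhanceConfig) -> np.ndarray:
    """Per-slice matched-filter energy with slab-local covariance.

    Scoring vectors come from a reflect-padded volume so the energy map
    keeps the input shape; covariance is always estimated from
    *unpadded* neighborhoods, since padding duplicates planes and would
    make ``R_v`` exactly singular.
    """
    px, py, pz = cfg.patch_shape
    p = px * py * pz
    pads = [(q // 2, q - 1 - q // 2) for q in (px, py, pz)]
    padded = np.pad(channel, pads, mode="reflect")
    rng = np.random.default_rng(cfg.seed)
    energy = np.empty(channel.shape, dtype=np.float64)
    nz = channel.shape[2]

    identity = cfg.covariance == "identity"
    id_model = CovarianceModel(np.eye(p), 0.0, cfg.patch_shape, 0)
    fallback_model = None

    def fallback() -> CovarianceModel:
        nonlocal fallback_model
        if fallback_model is None:
            all_vecs = _neighborhood_vectors(channel, cfg.patch_shape)
            idx = np.arange(len(all_vecs))
            if len(idx) > cfg.max_covariance_samples:
                idx = np.sort(
                    rng.choice(idx, size=cfg.max_covariance_samples, replace=False)
                )
            fallback_model = estimate_covariance(
                channel, cfg.patch_shape, ridge=cfg.ridge, vectors=all_vecs[idx]
            )
        return fallback_model

    for z in range(nz):
        if identity:
            model = id_model
        elif cfg.per_slab_covariance and pz <= z:
            # preceding slab: unpadded planes z-pz .. z-1 (full windows)
            block = channel[:, :, z - pz : z]
            model = estimate_covariance(
                channel, cfg.patch_shape, ridge=cfg.ridge,
                vectors=_neighborhood_vectors(block, (px, py, pz)),
            )
        else:
            model = fallback()
        vecs = _neighborhood_vectors(
            padded[:, :, z : z + pz], (px, py, pz)
        )
        energy[:, :, z] = _energy_from_vectors(vecs, model).reshape(
            channel.shape[:2]
        )
    return energy


def enhance_volume(
    volume: MultiModalVolume, config: EnhanceConfig | None = None
) -> tuple[MultiModalVolume, EnhancedVolume]:
    """Run the full enhancement stage on a multi-modal volume.

    Returns the enhanced 4-channel volume and the matched-filter energy
    map (averaged over ``config.energy_channels``), deterministic given
    the config.
    """
    cfg = config or EnhanceConfig()
    from .volume_io import MODALITIES

    enhanced = np.stack(
        [_enhance_channel_slices(volume.data[c], cfg) for c in range(4)]
    )
    out_volume = MultiModalVolume(enhanced, volume.spacing, volume.affine)

    maps = []
    for name in cfg.energy_channels:
        ci = MODALITIES.index(name)
        maps.append(_slab_energy(enhanced[ci], cfg))
    energy = np.mean(maps, axis=0)
    threshold = float(np.percentile(energy, cfg.threshold_percentile))
    return out_volume, EnhancedVolume(energy, threshold, energy >= threshold)
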
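"""Voxel-related Gaussian mixture model for a pair of consecutive frames.

Each supervoxel ``k`` spans two consecutive frames and is represented by
two 5-D Gaussians with block-diagonal covariance: a 2-D spatial block per
frame (``mu_s``, ``Sigma_s`` for frame ``t``; ``mu_s_hat``,
``Sigma_s_hat`` for frame ``t+1``) and a single 3-D CIELAB color block
(``mu_c``, ``Sigma_c``) shared by both frames.  The shared color
parameters are the temporal-consistency mechanism: a supervoxel can move
between frames (its spatial Gaussians are free) but must keep its color.

A voxel ``i`` is modelled as drawn from the mixture of its candidate
supervoxels ``Ki`` only, with constant weights ``1/|Ki|``; restricting
the mixture to the local candidate window is what keeps supervoxels
similar in size and the per-iteration cost linear in the number of
voxels.  Parameters are fitted by a fixed number of EM iterations, with
eigenvalue flooring of every covariance to keep the model non-singular
on flat-color or degenerate regions.

All densities are evaluated in the log domain; E-step normalization uses
a max-shift (log-sum-exp), so responsibilities are exact even where the
5-D densities underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .grid import AnchorMap, GridSpec

__all__ = [
    "Hyperparams",
    "PairFeatures",
    "ParamSet",
    "Responsibilities",
    "EMTrace",
    "density_evals",
    "gaussian_logdensity",
    "regularize_covariance",
    "features_from_frames",
    "init_params",
    "e_step",
    "m_step",
    "log_likelihood",
    "run_em",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class _EvalCounter:
    """Counts 5-D density evaluations (one per voxel-candidate per frame)."""

    def __init__(self) -> None:
        self.count = 0

    def reset(self) -> None:
        self.count = 0


#: Global instrumentation counter; reset before a run to audit the
#: per-iteration evaluation budget ``2 * N * (2*eta_x+1) * (2*eta_y+1)``.
density_evals = _EvalCounter()


@dataclass(frozen=True)
class Hyperparams:
    """EM tuning constants.

    Attributes
    ----------
    lambda_s : float
        Eigenvalue floor for spatial covariances, in squared pixels.
        Default 2: keeps one-pixel-wide structures non-singular.
    lambda_c : float
        Eigenvalue floor for the color covariance, in squared CIELAB
        units.  Default 8: flat-color regions stay invertible.
    sigma_c : float
        Initial color standard deviation in CIELAB units (default 10);
        the color distance within which two voxels initially count as
        similar.
    n_iter : int
        Number of EM iterations (default 20).  A fixed count is used
        instead of a convergence test: the labelling stabilises long
        before the parameters do.
    """

    lambda_s: float = 2.0
    lambda_c: float = 8.0
    sigma_c: float = 10.0
    n_iter: int = 20

    def __post_init__(self) -> None:
        if self.lambda_s <= 0 or self.lambda_c <= 0 or self.sigma_c <= 0:
            raise ValueError("lambda_s, lambda_c and sigma_c must be positive")
        if self.n_iter < 0:
            raise ValueError("n_iter must be non-negative")


@dataclass
class PairFeatures:
    """Per-voxel features of a frame pair, flattened row-major.

    ``spatial`` holds ``(x, y)`` pixel coordinates (identical for both
    frames of a pair); ``color_t`` / ``color_t1`` hold CIELAB triples.
    """

    spatial: np.ndarray  # (N, 2) float64
    color_t: np.ndarray  # (N, 3) float64
    color_t1: np.ndarray  # (N, 3) float64

    @property
    def n_voxels(self) -> int:
        return self.spatial.shape[0]


@dataclass
class ParamSet:
    """Per-supervoxel Gaussian parameters, stacked over ``k = 0..K-1``.

    The color arrays are the single shared blocks used for both frames.
    """

    mu_s: np.ndarray  # (K, 2)
    Sigma_s: np.ndarray  # (K, 2, 2)
    mu_s_hat: np.ndarray  # (K, 2)
    Sigma_s_hat: np.ndarray  # (K, 2, 2)
    mu_c: np.ndarray  # (K, 3)
    Sigma_c: np.ndarray  # (K, 3, 3)

    @property
    def K(self) -> int:
        return self.mu_s.shape[0]

    def copy(self) -> "ParamSet":
        return ParamSet(
            self.mu_s.copy(),
            self.Sigma_s.copy(),
            self.mu_s_hat.copy(),
            self.Sigma_s_hat.copy(),
            self.mu_c.copy(),
            self.Sigma_c.copy(),
        )


@dataclass
class Responsibilities:
    """E-step posteriors, dense over the candidate-window slots.

    ``R[i, j]`` is the responsibility of voxel ``i``'s ``j``-th candidate
    slot (see :class:`~pairvox.grid.AnchorMap`); clipped slots are 0.
    Rows sum to 1 for each frame.
    """

    R: np.ndarray  # (N, n_slots) frame t
    R_hat: np.ndarray  # (N, n_slots) frame t+1


@dataclass
class EMTrace:
    """Optional per-iteration diagnostics collected by :func:`run_em`."""

    record_loglik: bool = True
    loglik: list = field(default_factory=list)
    floors_active: list = field(default_factory=list)


def gaussian_logdensity(z: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float | np.ndarray:
    """Log of the multivariate normal density, via Cholesky.

    ``z`` may be a single D-vector or a batch ``(..., D)``.  For the 5-D
    block-diagonal supervoxel covariance this equals the sum of the 2-D
    spatial and 3-D color log-densities.
    """
    z = np.asarray(z, dtype=float)
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    D = mu.shape[-1]
    L = np.linalg.cholesky(Sigma)
    diff = z - mu
    sol = np.linalg.solve(L, diff[..., None])[..., 0] if diff.ndim > 1 else np.linalg.solve(L, diff)
    quad = np.sum(sol**2, axis=-1)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L)))
    out = -0.5 * D * _LOG_2PI - 0.5 * logdet - 0.5 * quad
    return float(out) if out.ndim == 0 else out


def regularize_covariance(Sigma: np.ndarray, floor: float) -> np.ndarray:
    """Floor the eigenvalues of a (batch of) symmetric matrices.

    The matrix is symmetrized, eigendecomposed, eigenvalues below
    ``floor`` are raised to ``floor``, and the matrix is recomposed with
    the original eigenvectors.  The result is SPD with minimum
    eigenvalue ``>= floor``; matrices already above the floor are
    returned unchanged up to round-off.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if not np.all(np.isfinite(Sigma)):
        raise FloatingPointError("covariance contains non-finite entries")
    sym = 0.5 * (Sigma + np.swapaxes(Sigma, -1, -2))
    w, V = np.linalg.eigh(sym)
    w = np.maximum(w, floor)
    out = (V * w[..., None, :]) @ np.swapaxes(V, -1, -2)
    return 0.5 * (out + np.swapaxes(out, -1, -2))


def _regularize_batch(Sigma: np.ndarray, floor: float) -> tuple[np.ndarray, bool]:
    """Like :func:`regularize_covariance` but reports whether any floor fired."""
    sym = 0.5 * (Sigma + np.swapaxes(Sigma, -1, -2))
    w, V = np.linalg.eigh(sym)
    active = bool(np.any(w < floor))
    w = np.maximum(w, floor)
    out = (V * w[..., None, :]) @ np.swapaxes(V, -1, -2)
    return 0.5 * (out + np.swapaxes(out, -1, -2)), active


def features_from_frames(frame_t: np.ndarray, frame_t1: np.ndarray) -> PairFeatures:
    """Flatten a CIELAB frame pair into per-voxel feature arrays."""
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t1 = np.asarray(frame_t1, dtype=float)
    if frame_t.shape != frame_t1.shape or frame_t.ndim != 3 or frame_t.shape[2] != 3:
        raise ValueError(
            f"expected two (H, W, 3) frames of equal shape, got {frame_t.shape} and {frame_t1.shape}"
        )
    H, W = frame_t.shape[:2]
    ys, xs = np.mgrid[0:H, 0:W]
    spatial = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    return PairFeatures(
        spatial=spatial,
        color_t=frame_t.reshape(-1, 3),
        color_t1=frame_t1.reshape(-1, 3),
    )


def init_params(
    frame_t: np.ndarray, frame_t1: np.ndarray, grid: GridSpec, hp: Hyperparams
) -> ParamSet:
    """Initial parameters from the anchor grid.

    Spatial means start at the anchor-region centroids (identical for
    both frames); the color mean is the average of the two frames' color
    at the region's centre voxel; covariances start isotropic at the
    desired superpixel scale (``diag(vx^2, vy^2)`` spatial,
    ``sigma_c^2 I`` color) and are passed through the eigenvalue floors,
    a no-op at the default settings.
    """
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t1 = np.asarray(frame_t1, dtype=float)
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frame pair must have identical shapes")
    if frame_t.shape[:2] != (grid.H, grid.W):
        raise ValueError(
            f"frame shape {frame_t.shape[:2]} does not match grid {grid.H}x{grid.W}"
        )
    K = grid.K
    mu_s = np.empty((K, 2))
    mu_c = np.empty((K, 3))
    for k in range(K):
        cx, cy = k % grid.nx, k // grid.nx
        x0, x1 = grid.cell_x_bounds(cx)
        y0, y1 = grid.cell_y_bounds(cy)
        mu_s[k] = ((x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0)
        # centre voxel: floor of the (possibly fractional) centroid
        xc, yc = int(mu_s[k, 0]), int(mu_s[k, 1])
        mu_c[k] = 0.5 * (frame_t[yc, xc] + frame_t1[yc, xc])
    Sigma_s = np.broadcast_to(
        np.diag([float(grid.vx) ** 2, float(grid.vy) ** 2]), (K, 2, 2)
    ).copy()
    Sigma_c = np.broadcast_to(hp.sigma_c**2 * np.eye(3), (K, 3, 3)).copy()
    return ParamSet(
        mu_s=mu_s,
        Sigma_s=regularize_covariance(Sigma_s, hp.lambda_s),
        mu_s_hat=mu_s.copy(),
        Sigma_s_hat=regularize_covariance(Sigma_s, hp.lambda_s),
        mu_c=mu_c,
        Sigma_c=regularize_covariance(Sigma_c, hp.lambda_c),
    )


def _precompute_blocks(mu: np.ndarray, Sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched inverse and log-determinant of per-component covariances."""
    inv = np.linalg.inv(Sigma)
    _, logdet = np.linalg.slogdet(Sigma)
    return inv, logdet


def candidate_logdensities(
    features: PairFeatures, params: ParamSet, anchors: AnchorMap
) -> tuple[np.ndarray, np.ndarray]:
    """Dense per-slot 5-D log-densities for both frames, ``-inf`` where clipped.

    Returns arrays of shape ``(N, n_slots)`` aligned on the candidate
    slots of ``anchors``; this is the single evaluation kernel shared by
    the E-step, the log-likelihood and the label assignment, and the
    place where :data:`density_evals` is incremented.
    """
    N, S = anchors.n_voxels, anchors.n_slots
    inv_s, ld_s = _precompute_blocks(params.mu_s, params.Sigma_s)
    inv_sh, ld_sh = _precompute_blocks(params.mu_s_hat, params.Sigma_s_hat)
    inv_c, ld_c = _precompute_blocks(params.mu_c, params.Sigma_c)

    logp = np.full((N, S), -np.inf)
    logp_hat = np.full((N, S), -np.inf)
    cand = anchors.voxel_candidates
    for j in range(S):
        comp = cand[:, j]
        m = comp >= 0
        if not np.any(m):
            continue
        km = comp[m]
        ds = features.spatial[m] - params.mu_s[km]
        quad_s = np.einsum("ni,nij,nj->n", ds, inv_s[km], ds)
        dsh = features.spatial[m] - params.mu_s_hat[km]
        quad_sh = np.einsum("ni,nij,nj->n", dsh, inv_sh[km], dsh)
        dc = features.color_t[m] - params.mu_c[km]
        quad_c = np.einsum("ni,nij,nj->n", dc, inv_c[km], dc)
        dch = features.color_t1[m] - params.mu_c[km]
        quad_ch = np.einsum("ni,nij,nj->n", dch, inv_c[km], dch)
        logp[m, j] = -2.5 * _LOG_2PI - 0.5 * (ld_s[km] + ld_c[km] + quad_s + quad_c)
        logp_hat[m, j] = -2.5 * _LOG_2PI - 0.5 * (
            ld_sh[km] + ld_c[km] + quad_sh + quad_ch
        )
        density_evals.count += 2 * int(m.sum())
    return logp, logp_hat


def e_step(
    features: PairFeatures, params: ParamSet, anchors: AnchorMap
) -> Responsibilities:
    """Posterior responsibilities over each voxel's candidate set.

    ``R[i, k] = g(z_i; theta_k) / sum_{k' in Ki} g(z_i; theta_k')``,
    computed with a log-sum-exp max shift, so the normalization is exact
    even when all candidate densities underflow.
    """
    logp, logp_hat = candidate_logdensities(features, params, anchors)
    R = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    R_hat = np.exp(logp_hat - logsumexp(logp_hat, axis=1, keepdims=True))
    return Responsibilities(R=R, R_hat=R_hat)


def _weighted_moments(
    anchors: AnchorMap, weights: np.ndarray, values: np.ndarray, d: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scatter-add responsibility-weighted moments onto components.

    For each candidate slot, the voxels whose slot-``j`` candidate is
    ``k`` contribute weight ``weights[i, j]`` to component ``k``.
    Returns ``(sum_w, sum_wz, sum_wzz)`` of shapes (K,), (K, d), (K, d, d).
    """
    K = anchors.grid.K
    sum_w = np.zeros(K)
    sum_wz = np.zeros((K, d))
    sum_wzz = np.zeros((K, d, d))
    cand = anchors.voxel_candidates
    outer = values[:, :, None] * values[:, None, :]  # (N, d, d)
    for j in range(anchors.n_slots):
        comp = cand[:, j]
        m = comp >= 0
        if not np.any(m):
            continue
        km = comp[m]
        w = weights[m, j]
        sum_w += np.bincount(km, weights=w, minlength=K)
        for a in range(d):
            sum_wz[:, a] += np.bincount(km, weights=w * values[m, a], minlength=K)
            for b in range(a, d):
                sum_wzz[:, a, b] += np.bincount(
                    km, weights=w * outer[m, a, b], minlength=K
                )
    # fill lower triangles
    for a in range(d):
        for b in range(a + 1, d):
            sum_wzz[:, b, a] = sum_wzz[:, a, b]
    return sum_w, sum_wz, sum_wzz


_EMPTY_WEIGHT = 1e-12


def _mean_cov(
    sum_w: np.ndarray, sum_wz: np.ndarray, sum_wzz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted mean and covariance from raw moments; flags empty components."""
    empty = sum_w < _EMPTY_WEIGHT
    w = np.where(empty, 1.0, sum_w)
    mu = sum_wz / w[:, None]
    cov = sum_wzz / w[:, None, None] - mu[:, :, None] * mu[:, None, :]
    return mu, cov, empty


def _m_step(
    features: PairFeatures,
    resp: Responsibilities,
    anchors: AnchorMap,
    hp: Hyperparams,
    prev: ParamSet | None = None,
) -> tuple[ParamSet, bool]:
    """M-step returning also whether any eigenvalue floor activated."""
    sw, swz, swzz = _weighted_moments(anchors, resp.R, features.spatial, 2)
    mu_s, cov_s, empty_s = _mean_cov(sw, swz, swzz)
    swh, swzh, swzzh = _weighted_moments(anchors, resp.R_hat, features.spatial, 2)
    mu_sh, cov_sh, empty_sh = _mean_cov(swh, swzh, swzzh)

    # color: pool both frames with weights R + R_hat
    cw, cwz, cwzz = _weighted_moments(anchors, resp.R, features.color_t, 3)
    cwh, cwzh, cwzzh = _weighted_moments(anchors, resp.R_hat, features.color_t1, 3)
    mu_c, cov_c, empty_c = _mean_cov(cw + cwh, cwz + cwzh, cwzz + cwzzh)

    any_empty = bool(np.any(empty_s) or np.any(empty_sh) or np.any(empty_c))
    if any_empty and prev is None:
        raise ValueError(
            "supervoxel with near-zero responsibility mass and no previous "
            "parameters to fall back on"
        )
    if any_empty:
        mu_s[empty_s] = prev.mu_s[empty_s]
        cov_s[empty_s] = prev.Sigma_s[empty_s]
        mu_sh[empty_sh] = prev.mu_s_hat[empty_sh]
        cov_sh[empty_sh] = prev.Sigma_s_hat[empty_sh]
        mu_c[empty_c] = prev.mu_c[empty_c]
        cov_c[empty_c] = prev.Sigma_c[empty_c]

    Sigma_s, a1 = _regularize_batch(cov_s, hp.lambda_s)
    Sigma_sh, a2 = _regularize_batch(cov_sh, hp.lambda_s)
    Sigma_c, a3 = _regularize_batch(cov_c, hp.lambda_c)
    params = ParamSet(
        mu_s=mu_s,
        Sigma_s=Sigma_s,
        mu_s_hat=mu_sh,
        Sigma_s_hat=Sigma_sh,
        mu_c=mu_c,
        Sigma_c=Sigma_c,
    )
    return params, (a1 or a2 or a3)


def m_step(
    features: PairFeatures,
    resp: Responsibilities,
    anchors: AnchorMap,
    hp: Hyperparams,
    prev: ParamSet | None = None,
) -> ParamSet:
    """Responsibility-weighted parameter update over each overlap region.

    Spatial means/covariances are updated per frame from ``R`` and
    ``R_hat``; the shared color mean/covariance pools both frames with
    weights ``R + R_hat``.  Every covariance then passes through the
    eigenvalue floor.  Components whose total weight falls below 1e-12
    keep their previous parameters (``prev``).
    """
    params, _ = _m_step(features, resp, anchors, hp, prev)
    return params


def log_likelihood(
    features: PairFeatures, params: ParamSet, anchors: AnchorMap
) -> float:
    """Mixture log-likelihood of the pair, up to the constant weight term.

    ``L(theta) = sum_i [log sum_{k in Ki} g(z_i; theta_k)
    + log sum_{k in Ki} g(z_hat_i; theta_hat_k)]`` — the quantity EM
    ascends (the constant ``1/|Ki|^2`` weights only shift it).
    """
    logp, logp_hat = candidate_logdensities(features, params, anchors)
    return float(np.sum(logsumexp(logp, axis=1)) + np.sum(logsumexp(logp_hat, axis=1)))


def run_em(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    grid: GridSpec,
    hp: Hyperparams = Hyperparams(),
    anchors: AnchorMap | None = None,
    trace: EMTrace | None = None,
) -> ParamSet:
    """Fit the pair model: initialization plus ``hp.n_iter`` EM sweeps.

    Deterministic: identical inputs give identical outputs.  With
    ``trace`` given, the log-likelihood after initialization and after
    each M-step, and a per-iteration flag for eigenvalue-floor
    activation, are recorded (the likelihood evaluations show up in
    :data:`density_evals`).
    """
    if anchors is None:
        anchors = AnchorMap(grid)
    features = features_from_frames(frame_t, frame_t1)
    params = init_params(frame_t, frame_t1, grid, hp)
    if trace is not None and trace.record_loglik:
        trace.loglik.append(log_likelihood(features, params, anchors))
    for _ in range(hp.n_iter):
        resp = e_step(features, params, anchors)
        params, floors = _m_step(features, resp, anchors, hp, prev=params)
        if trace is not None:
            trace.floors_active.append(floors)
            if trace.record_loglik:
                trace.loglik.append(log_likelihood(features, params, anchors))
    return params
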
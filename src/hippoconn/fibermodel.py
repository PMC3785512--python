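"""Per-voxel ball-and-stick fiber model with a Metropolis posterior sampler.

The signal model per gradient-table entry i is

    S_i = s0 · [ (1 − f1 − f2) · exp(−b_i d)
                 + Σ_j f_j · exp(−b_i d (gᵢ·v_j)²) ]

one isotropic "ball" and up to two perfectly anisotropic "sticks".  A
maximum-likelihood point fit (nonlinear least squares, tensor-initialized)
seeds a random-walk Metropolis sampler whose per-voxel samples of
(f1, v1, f2, v2) form the substrate for probabilistic tractography.

Priors: d uniform on (0, 5e-3 mm²/s); (f1, f2) uniform on the simplex
f1 + f2 <= 1 with a Beta(1, 5) sparsity prior on f2 (an automatic-relevance
stand-in that shrinks the second stick when the data do not support it);
orientations uniform on the sphere.  The likelihood is Gaussian with a
noise scale estimated from b0 repeats — a deliberate simplification of the
Rician magnitude distribution, adequate at the SNR this package simulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from hippoconn.errors import ConfigurationError, InputError
from hippoconn.phantom import GradientScheme
from hippoconn.tensor import eigendecompose, fa_from_eigenvalues, fit_tensor_loglinear

log = logging.getLogger(__name__)

D_MAX = 5.0e-3  # upper prior bound on the ball diffusivity, mm²/s
F2_BETA_B = 5.0  # Beta(1, b) sparsity prior on the second stick fraction


@dataclass
class BallStickParams:
    """Point estimate of the ball-and-stick model in one voxel."""

    s0: float
    d: float
    f1: float
    f2: float
    v1: np.ndarray
    v2: np.ndarray

    def __post_init__(self):
        self.v1 = np.asarray(self.v1, dtype=float)
        self.v2 = np.asarray(self.v2, dtype=float)
        if self.f1 < 0 or self.f2 < 0 or self.f1 + self.f2 > 1.0 + 1e-9:
            raise ConfigurationError("stick fractions must satisfy 0 <= f2, f1, f1+f2 <= 1")
        if self.f1 < self.f2:
            raise ConfigurationError("sticks must be ordered by fraction (f1 >= f2)")
        for v in (self.v1, self.v2):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ConfigurationError("stick orientations must be unit vectors")


@dataclass
class FiberPosterior:
    """K posterior samples of (f1, v1, f2, v2) for every in-mask voxel.

    Sample arrays are ordered by ``np.flatnonzero(mask)``.
    """

    mask: np.ndarray        # boolean volume
    f1: np.ndarray          # (V, K)
    f2: np.ndarray          # (V, K)
    v1: np.ndarray          # (V, K, 3) unit vectors
    v2: np.ndarray          # (V, K, 3)

    @property
    def k(self) -> int:
        return self.f1.shape[1]

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def voxel_index_volume(self) -> np.ndarray:
        """Volume mapping voxel -> row in the sample arrays (−1 outside)."""
        idx = np.full(self.mask.shape, -1, dtype=np.int64)
        idx[self.mask] = np.arange(int(self.mask.sum()))
        return idx


def predict_signal(p: BallStickParams, scheme: GradientScheme) -> np.ndarray:
    g, b = scheme.bvecs, scheme.bvals
    ball = (1.0 - p.f1 - p.f2) * np.exp(-b * p.d)
    s1 = p.f1 * np.exp(-b * p.d * (g @ p.v1) ** 2)
    s2 = p.f2 * np.exp(-b * p.d * (g @ p.v2) ** 2)
    return p.s0 * (ball + s1 + s2)


def _sph(theta, phi):
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _tensor_init(signal: np.ndarray, scheme: GradientScheme):
    """Tensor-fit-derived starting point: v1 = principal eigenvector,
    d = MD, f1 = FA clipped to [0.05, 0.95]."""
    dwi = signal.reshape(1, 1, 1, -1)
    tf = fit_tensor_loglinear(dwi, scheme.bvals, scheme.bvecs)
    es = eigendecompose(tf)
    ev = es.eigenvalues[0]
    s0 = float(tf.s0[0])
    d = float(max(ev.mean(), 1e-5))
    f1 = float(np.clip(fa_from_eigenvalues(ev), 0.05, 0.95))
    v1 = es.principal_direction[0]
    if np.linalg.norm(v1) == 0:
        v1 = np.array([1.0, 0.0, 0.0])
    # second direction: orthogonal to v1
    v2 = np.cross(v1, [0.0, 0.0, 1.0])
    if np.linalg.norm(v2) < 1e-6:
        v2 = np.cross(v1, [0.0, 1.0, 0.0])
    v2 /= np.linalg.norm(v2)
    return s0, d, f1, v1, v2


def fit_ball_stick(signal: np.ndarray, scheme: GradientScheme) -> BallStickParams:
    """Maximum-likelihood point estimate via nonlinear least squares.

    Initialized from the tensor fit; on optimizer failure the tensor-derived
    initialization is returned with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal <= 0):
        raise InputError("ball-and-stick fit requires positive signals")
    s0, d, f1, v1, v2 = _tensor_init(signal, scheme)
    th1, ph1 = np.arccos(np.clip(v1[2], -1, 1)), np.arctan2(v1[1], v1[0])
    th2, ph2 = np.arccos(np.clip(v2[2], -1, 1)), np.arctan2(v2[1], v2[0])
    x0 = np.array([s0, d, f1, 0.02, th1, ph1, th2, ph2])

    def residuals(x):
        s0x, dx, f1x, f2x, t1, p1, t2, p2 = x
        f1x, f2x = max(f1x, 0.0), max(f2x, 0.0)
        if f1x + f2x > 1.0:  # fold back onto the simplex
            tot = f1x + f2x
            f1x, f2x = f1x / tot, f2x / tot
        p = BallStickParams(
            s0=max(s0x, 1e-12),
            d=min(max(dx, 1e-8), D_MAX),
            f1=max(f1x, f2x),
            f2=min(f1x, f2x),
            v1=_sph(t1, p1) if f1x >= f2x else _sph(t2, p2),
            v2=_sph(t2, p2) if f1x >= f2x else _sph(t1, p1),
        )
        return predict_signal(p, scheme) - signal

    try:
        sol = least_squares(residuals, x0, method="lm", max_nfev=2000)
        x = sol.x
        ok = sol.success
    except Exception:  # pragma: no cover - optimizer blow-up path
        ok = False
    if not ok:
        log.warning("ball-and-stick optimizer did not converge; using tensor init")
        x = x0
    s0x, dx, f1x, f2x, t1, p1, t2, p2 = x
    f1x, f2x = max(f1x, 0.0), max(f2x, 0.0)
    if f1x + f2x > 1.0:
        tot = f1x + f2x
        f1x, f2x = f1x / tot, f2x / tot
    va, vb = _sph(t1, p1), _sph(t2, p2)
    if f2x > f1x:
        f1x, f2x, va, vb = f2x, f1x, vb, va
    return BallStickParams(
        s0=float(max(s0x, 1e-12)),
        d=float(min(max(dx, 1e-8), D_MAX)),
        f1=float(f1x),
        f2=float(f2x),
        v1=va,
        v2=vb,
    )


# ---------------------------------------------------------------------------
# Metropolis sampler (vectorized across voxels)
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    k: int = 50           # retained samples per voxel
    burn_in: int = 200
    thin: int = 5
    prop_d: float = 2.0e-4       # proposal scales
    prop_f: float = 0.05
    prop_angle: float = 0.12     # radians-scale orientation perturbation

    def __post_init__(self):
        if self.k < 1:
            raise ConfigurationError("sample count k must be >= 1")
        if self.burn_in < 0 or self.thin < 1:
            raise ConfigurationError("invalid burn_in/thin")


class _ChainState:
    """Vectorized chain state across V voxels."""

    def __init__(self, signals, scheme, sigma):
        self.signals = signals            # (V, N)
        self.g = scheme.bvecs             # (N, 3)
        self.b = scheme.bvals
        self.sigma = sigma                # (V,)
        V = signals.shape[0]
        self.d = np.empty(V)
        self.f1 = np.empty(V)
        self.f2 = np.empty(V)
        self.v1 = np.empty((V, 3))
        self.v2 = np.empty((V, 3))
        self.s0 = np.empty(V)

    def loglike(self, d, f1, f2, v1, v2, rows=slice(None)) -> np.ndarray:
        att_ball = np.exp(-np.outer(d, self.b))                      # (V, N)
        q1 = (v1 @ self.g.T) ** 2
        q2 = (v2 @ self.g.T) ** 2
        pred = self.s0[rows, None] * (
            (1.0 - f1 - f2)[:, None] * att_ball
            + f1[:, None] * np.exp(-d[:, None] * self.b[None, :] * q1)
            + f2[:, None] * np.exp(-d[:, None] * self.b[None, :] * q2)
        )
        ssr = ((pred - self.signals[rows]) ** 2).sum(axis=1)
        return -0.5 * ssr / self.sigma[rows] ** 2

    def logprior(self, d, f1, f2) -> np.ndarray:
        ok = (d > 0) & (d < D_MAX) & (f1 >= 0) & (f2 >= 0) & (f1 + f2 <= 1.0) & (f1 >= f2)
        lp = np.where(ok, (F2_BETA_B - 1.0) * np.log1p(-np.minimum(f2, 1 - 1e-12)), -np.inf)
        return lp

    def _ll_subset(self, fin, d, f1, f2, v1, v2):
        """Likelihood restricted to prior-feasible voxels (others stay −inf)."""
        return self.loglike(d[fin], f1[fin], f2[fin], v1[fin], v2[fin], rows=fin)


def _perturb_orientation(
    v: np.ndarray, scale: float, rng: np.random.Generator, jump_prob: float = 0.1
) -> np.ndarray:
    """Local Gaussian perturbation on the sphere, mixed with an occasional
    uniform redraw (a symmetric jump proposal that lets chains escape
    spurious orientation modes, e.g. the oblate-tensor plane of a crossing)."""
    w = v + rng.normal(0.0, scale, size=v.shape)
    jump = rng.uniform(size=v.shape[0]) < jump_prob
    if jump.any():
        fresh = rng.standard_normal((int(jump.sum()), 3))
        w[jump] = fresh
    n = np.linalg.norm(w, axis=-1, keepdims=True)
    bad = (n == 0).ravel()
    if bad.any():
        w[bad] = v[bad]
        n = np.linalg.norm(w, axis=-1, keepdims=True)
    return w / n


def estimate_noise_sigma(signals: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Per-voxel noise scale from b0 repeats (floored at 1% of mean b0)."""
    b0 = signals[..., scheme.bvals == 0]
    if b0.shape[-1] >= 2:
        sigma = b0.std(axis=-1, ddof=1)
    else:
        sigma = np.zeros(signals.shape[:-1])
    floor = 0.01 * np.maximum(b0.mean(axis=-1), 1e-12)
    return np.maximum(sigma, floor)


def sample_posterior_volume(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
    cfg: SamplerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FiberPosterior:
    """Run the Metropolis chain for every in-mask voxel simultaneously.

    Each iteration cycles component-wise updates (d; f1; f2; v1; v2), each a
    vectorized accept/reject across voxels.  Chains are initialized from the
    per-voxel tensor fit.
    """
    cfg = cfg or SamplerConfig()
    rng = rng or np.random.default_rng(0)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("empty sampling mask")
    signals = np.asarray(dwi, dtype=float)[mask]  # (V, N)

    # tensor-based initialization, vectorized
    tf = fit_tensor_loglinear(dwi, scheme.bvals, scheme.bvecs, mask)
    es = eigendecompose(tf)
    st = _ChainState(signals, scheme, estimate_noise_sigma(signals, scheme))
    st.s0 = np.maximum(tf.s0, 1e-12)
    st.d = np.clip(es.eigenvalues.mean(axis=1), 1e-5, D_MAX - 1e-6)
    st.f1 = np.clip(fa_from_eigenvalues(es.eigenvalues), 0.05, 0.95)
    st.f2 = np.full(st.f1.shape, 0.02)
    st.v1 = es.principal_direction.copy()
    zero = np.linalg.norm(st.v1, axis=1) == 0
    st.v1[zero] = [1.0, 0.0, 0.0]
    # second stick starts on the tensor's second eigenvector (the crossing
    # plane of an oblate tensor), orthogonal to v1 by construction
    _, evecs = np.linalg.eigh(tf.tensors())
    v2 = evecs[:, :, 1]
    nrm = np.linalg.norm(v2, axis=1, keepdims=True)
    st.v2 = np.where(nrm > 0, v2 / np.where(nrm > 0, nrm, 1.0), [0.0, 1.0, 0.0])

    V = signals.shape[0]
    cur_lp = st.logprior(st.d, st.f1, st.f2) + st.loglike(st.d, st.f1, st.f2, st.v1, st.v2)

    keep_f1 = np.empty((V, cfg.k))
    keep_f2 = np.empty((V, cfg.k))
    keep_v1 = np.empty((V, cfg.k, 3))
    keep_v2 = np.empty((V, cfg.k, 3))
    n_accept = 0
    n_prop = 0
    kept = 0
    total_iters = cfg.burn_in + cfg.k * cfg.thin

    def metropolis(d, f1, f2, v1, v2):
        nonlocal cur_lp, n_accept, n_prop
        lp = st.logprior(d, f1, f2)
        new_lp = np.full(V, -np.inf)
        fin = np.isfinite(lp)
        if fin.any():
            new_lp[fin] = lp[fin] + st._ll_subset(fin, d, f1, f2, v1, v2)
        accept = np.log(rng.uniform(size=V)) < (new_lp - cur_lp)
        st.d[accept] = d[accept]
        st.f1[accept] = f1[accept]
        st.f2[accept] = f2[accept]
        st.v1[accept] = v1[accept]
        st.v2[accept] = v2[accept]
        cur_lp[accept] = new_lp[accept]
        n_accept += int(accept.sum())
        n_prop += V

    for it in range(total_iters):
        metropolis(st.d + rng.normal(0, cfg.prop_d, V), st.f1, st.f2, st.v1, st.v2)
        f1p = st.f1 + rng.normal(0, cfg.prop_f, V)
        metropolis(st.d, f1p, st.f2, st.v1, st.v2)
        f2p = st.f2 + rng.normal(0, cfg.prop_f, V)
        metropolis(st.d, st.f1, f2p, st.v1, st.v2)
        metropolis(st.d, st.f1, st.f2, _perturb_orientation(st.v1, cfg.prop_angle, rng), st.v2)
        metropolis(st.d, st.f1, st.f2, st.v1, _perturb_orientation(st.v2, cfg.prop_angle, rng))
        post_burn = it - cfg.burn_in + 1
        if post_burn >= 1 and post_burn % cfg.thin == 0 and kept < cfg.k:
            keep_f1[:, kept] = st.f1
            keep_f2[:, kept] = st.f2
            keep_v1[:, kept] = st.v1
            keep_v2[:, kept] = st.v2
            kept += 1

    log.info(
        "fiber posterior: %d voxels, %d samples, acceptance %.2f",
        V, cfg.k, n_accept / max(n_prop, 1),
    )
    return FiberPosterior(mask=mask, f1=keep_f1, f2=keep_f2, v1=keep_v1, v2=keep_v2)


def sample_posterior(
    signal: np.ndarray,
    scheme: GradientScheme,
    k: int = 50,
    burn_in: int = 200,
    rng: np.random.Generator | None = None,
    thin: int = 5,
) -> FiberPosterior:
    """Single-voxel convenience wrapper around the vectorized sampler."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    dwi = np.asarray(signal, dtype=float).reshape(1, 1, 1, -1)
    mask = np.ones((1, 1, 1), dtype=bool)
    return sample_posterior_volume(
        dwi, scheme, mask, SamplerConfig(k=k, burn_in=burn_in, thin=thin), rng
    )


def mean_orientation(samples: np.ndarray) -> np.ndarray:
    """Dyadic mean of axial data: principal eigenvector of mean(v vᵀ).

    The right way to average orientations that are only defined up to sign.
    """
    vs = np.asarray(samples, dtype=float).reshape(-1, 3)
    T = np.einsum("ki,kj->ij", vs, vs) / len(vs)
    return np.linalg.eigh(T)[1][:, -1]


def angle_between_axes(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two axes (sign-invariant), in [0, 90]."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


# ---------------------------------------------------------------------------
# persistence ("merged samples" layout + JSON sidecar)
# ---------------------------------------------------------------------------

def save_posterior(post: FiberPosterior, voxel_size, prefix: str, settings: dict | None = None) -> list:
    """Persist samples as NIfTI multi-volumes (merged_*samples naming)."""
    import json

    from hippoconn import io

    shp = post.shape
    vol_idx = post.voxel_index_volume()
    paths = []

    def expand(arr, extra=()):
        out = np.zeros(shp + (post.k,) + tuple(extra))
        out[post.mask] = arr
        return out

    paths.append(io.save_volume(expand(post.f1), voxel_size, f"{prefix}_merged_f1samples.nii.gz"))
    paths.append(io.save_volume(expand(post.f2), voxel_size, f"{prefix}_merged_f2samples.nii.gz"))
    for name, arr in (("v1", post.v1), ("v2", post.v2)):
        out = np.zeros(shp + (post.k, 3))
        out[post.mask] = arr
        # store as (X, Y, Z, 3K): sample-major per component
        flat = out.reshape(shp + (post.k * 3,))
        paths.append(io.save_volume(flat, voxel_size, f"{prefix}_merged_{name}samples.nii.gz"))
    io.save_volume(post.mask, voxel_size, f"{prefix}_nodif_brain_mask.nii.gz")
    with open(f"{prefix}_bedpost_sidecar.json", "w") as fh:
        json.dump({"k": post.k, **(settings or {})}, fh, indent=2)
    return paths


def load_posterior(prefix: str) -> FiberPosterior:
    from hippoconn import io

    mask, _ = io.load_volume(f"{prefix}_nodif_brain_mask.nii.gz")
    mask = mask > 0.5
    f1, _ = io.load_volume(f"{prefix}_merged_f1samples.nii.gz")
    f2, _ = io.load_volume(f"{prefix}_merged_f2samples.nii.gz")
    k = f1.shape[-1]
    v1, _ = io.load_volume(f"{prefix}_merged_v1samples.nii.gz")
    v2, _ = io.load_volume(f"{prefix}_merged_v2samples.nii.gz")
    shp = mask.shape
    return FiberPosterior(
        mask=mask,
        f1=f1[mask],
        f2=f2[mask],
        v1=v1.reshape(shp + (k, 3))[mask],
        v2=v2.reshape(shp + (k, 3))[mask],
    )
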
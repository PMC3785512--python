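"""Single-tensor fitting and FA/MD map computation.

The diffusion tensor is fit per voxel by ordinary (unweighted) log-linear
least squares over all gradient-table entries (b=0 rows included), i.e. the
baseline behaviour of classic tensor-fitting tools.  FA and MD follow the
standard eigenvalue definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hippoconn.errors import ConfigurationError

log = logging.getLogger(__name__)

# row layout of the six unique tensor components
TENSOR_COMPONENTS = ("xx", "xy", "xz", "yy", "yz", "zz")


@dataclass
class TensorField:
    """Per-voxel tensor fit inside an analysis mask.

    ``d6`` holds the six unique components (xx, xy, xz, yy, yz, zz) in mm²/s
    for each in-mask voxel, in the order given by ``np.flatnonzero(mask)``.
    """

    mask: np.ndarray            # boolean volume
    s0: np.ndarray              # (V,) baseline signal estimates
    d6: np.ndarray              # (V, 6) unique tensor components
    n_clamped_signals: int = 0  # signals clamped to the positivity floor

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def tensors(self) -> np.ndarray:
        """Dense (V, 3, 3) symmetric tensors."""
        xx, xy, xz, yy, yz, zz = self.d6.T
        t = np.empty((self.d6.shape[0], 3, 3))
        t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = xx, yy, zz
        t[:, 0, 1] = t[:, 1, 0] = xy
        t[:, 0, 2] = t[:, 2, 0] = xz
        t[:, 1, 2] = t[:, 2, 1] = yz
        return t


@dataclass
class EigenSystem:
    """Sorted tensor eigenvalues and principal directions per in-mask voxel."""

    mask: np.ndarray
    eigenvalues: np.ndarray       # (V, 3) sorted descending, clamped >= 0
    principal_direction: np.ndarray  # (V, 3) unit e1
    n_clamped_eigenvalues: int = 0

    @property
    def shape(self) -> tuple:
        return self.mask.shape


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """OLS design for ln S_i = ln s0 − b_i · gᵢᵀ D gᵢ.

    Columns: [1, −b gx², −2b gx gy, −2b gx gz, −b gy², −2b gy gz, −b gz²],
    matching the (xx, xy, xz, yy, yz, zz) component order.
    """
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -b * gy * gy,
            -2.0 * b * gy * gz,
            -b * gz * gz,
        ]
    )
    return X


def fit_tensor_loglinear(
    dwi: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    mask: np.ndarray | None = None,
    signal_floor_frac: float = 1e-6,
) -> TensorField:
    """Fit a single diffusion tensor per in-mask voxel.

    Parameters
    ----------
    dwi : (X, Y, Z, N) diffusion-weighted series.
    bvals, bvecs : gradient table, N entries (b0 rows carry b = 0).
    mask : boolean volume; default all voxels.
    signal_floor_frac : nonpositive in-mask signals are clamped to this
        fraction of the voxel's mean b0 signal before the log transform
        (the log-linear model is undefined at S <= 0).
    """
    dwi = np.asarray(dwi, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvals.shape[0] < 7:
        raise ConfigurationError(
            f"tensor fit needs >= 7 gradient-table entries, got {bvals.shape[0]}"
        )
    if mask is None:
        mask = np.ones(dwi.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    X = design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ConfigurationError("singular tensor design matrix (degenerate gradient scheme)")

    S = dwi[mask]  # (V, N)
    b0_mean = S[:, bvals == 0].mean(axis=1) if np.any(bvals == 0) else S.mean(axis=1)
    b0_mean = np.where(b0_mean > 0, b0_mean, 1.0)
    floor = signal_floor_frac * b0_mean[:, None]
    bad = S <= 0
    n_clamped = int(bad.sum())
    if n_clamped:
        log.warning("clamped %d nonpositive in-mask signals to the floor", n_clamped)
        S = np.where(bad, floor, S)

    coef, *_ = np.linalg.lstsq(X, np.log(S).T, rcond=None)  # (7, V)
    s0 = np.exp(coef[0])
    d6 = coef[1:].T
    return TensorField(mask=mask, s0=s0, d6=d6, n_clamped_signals=n_clamped)


def eigendecompose(tf: TensorField) -> EigenSystem:
    """Symmetric eigendecomposition per voxel; eigenvalues sorted descending.

    Negative eigenvalues (noise artefacts) are clamped to zero; the clamp
    count is logged for noise diagnostics.
    """
    w, v = np.linalg.eigh(tf.tensors())  # ascending
    w = w[:, ::-1]
    e1 = v[:, :, ::-1][:, :, 0]
    n_clamped = int((w < 0).sum())
    if n_clamped:
        log.info("clamped %d negative eigenvalues to zero", n_clamped)
    w = np.clip(w, 0.0, None)
    norm = np.linalg.norm(e1, axis=1, keepdims=True)
    e1 = e1 / np.where(norm > 0, norm, 1.0)
    return EigenSystem(
        mask=tf.mask,
        eigenvalues=w,
        principal_direction=e1,
        n_clamped_eigenvalues=n_clamped,
    )


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) · ‖λ − λ̄‖ / ‖λ‖ ; zero where all eigenvalues vanish."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(((evals - mean) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def md_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """MD = (λ1 + λ2 + λ3) / 3."""
    return np.asarray(evals, dtype=float).mean(axis=-1)


def compute_fa(es: EigenSystem) -> np.ndarray:
    """FA volume (zeros outside the mask)."""
    out = np.zeros(es.shape)
    out[es.mask] = fa_from_eigenvalues(es.eigenvalues)
    return out


def compute_md(es: EigenSystem) -> np.ndarray:
    """MD volume in mm²/s (zeros outside the mask)."""
    out = np.zeros(es.shape)
    out[es.mask] = md_from_eigenvalues(es.eigenvalues)
    return out


def fit_fa_md(
    dwi: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, EigenSystem]:
    """Convenience: tensor fit → eigensystem → (FA volume, MD volume)."""
    tf = fit_tensor_loglinear(dwi, bvals, bvecs, mask)
    es = eigendecompose(tf)
    return compute_fa(es), compute_md(es), es
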
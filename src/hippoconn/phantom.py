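"""Synthetic diffusion-MRI cohorts with known fiber geometry and group effects.

The generator builds a small common-grid phantom: one or more tube-shaped
white-matter bundles (cylindrically symmetric tensors along the local
centerline tangent, optionally mixed with an isotropic compartment), an
isotropic background, and a compact "hippocampus" seed blob abutting a
bundle.  Group effects are injected by scaling tensor eigenvalues inside a
chosen effect mask before signal simulation: a mean-diffusivity elevation
scales all eigenvalues (leaving FA untouched), a fractional-anisotropy
reduction raises the radial eigenvalues (demyelination-like change).
Magnitude (Rician) noise is added to the simulated signal.

All subjects share one voxel grid — there is no registration stage; the
common grid stands in for template-space alignment, which is not part of
this package's scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.optimize import brentq

from hippoconn import io
from hippoconn.errors import ConfigurationError
from hippoconn.tensor import fa_from_eigenvalues, md_from_eigenvalues

AMNESTIC_SD_CUTOFF = 1.5  # SDs below the control mean on delayed recall


# ---------------------------------------------------------------------------
# gradient scheme
# ---------------------------------------------------------------------------

@dataclass
class GradientScheme:
    """Diffusion sensitization table: b-values (s/mm²) and unit directions.

    b = 0 entries are unweighted baselines; their direction rows are zero.
    """

    bvals: np.ndarray  # (N,)
    bvecs: np.ndarray  # (N, 3)

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ConfigurationError("bvals and bvecs lengths differ")
        if self.bvals.shape[0] < 7:
            raise ConfigurationError("gradient scheme needs >= 7 entries for a tensor fit")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ConfigurationError("diffusion-weighted directions must be unit vectors")

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    def __len__(self) -> int:
        return self.bvals.shape[0]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (spherical Fibonacci spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_gradient_scheme(
    n_dirs: int, n_b0: int, b: float, rng_seed: int = 0
) -> GradientScheme:
    """Build a scheme of ``n_b0`` b=0 entries followed by ``n_dirs`` directions.

    Directions are a spherical-Fibonacci layout given a deterministic random
    rotation derived from ``rng_seed`` (so distinct seeds give distinct but
    equally uniform designs).
    """
    if n_dirs < 6:
        raise ConfigurationError("at least 6 diffusion directions are required")
    if n_b0 < 1:
        raise ConfigurationError("at least one b=0 entry is required")
    if b <= 0:
        raise ConfigurationError("b must be positive")
    dirs = _fibonacci_sphere(n_dirs)
    rng = np.random.default_rng(rng_seed)
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    dirs = dirs @ q.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# voxel-level forward model
# ---------------------------------------------------------------------------

@dataclass
class VoxelTissueModel:
    """Multi-tensor voxel model: baseline signal and (fraction, tensor) pairs."""

    s0: float
    compartments: list  # of (fraction, 3x3 symmetric PSD tensor in mm²/s)

    def __post_init__(self):
        if self.s0 <= 0:
            raise ConfigurationError("s0 must be positive")
        fracs = np.array([f for f, _ in self.compartments], dtype=float)
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("compartment fractions must sum to 1")
        for _, D in self.compartments:
            w = np.linalg.eigvalsh(np.asarray(D, dtype=float))
            if w.min() < -1e-15:
                raise ConfigurationError("compartment tensors must be PSD")


def simulate_signal(model: VoxelTissueModel, scheme: GradientScheme) -> np.ndarray:
    """S_i = s0 · Σ_c f_c · exp(−b_i · gᵢᵀ D_c gᵢ); b=0 entries return s0."""
    g = scheme.bvecs
    b = scheme.bvals
    S = np.zeros(len(scheme))
    for f, D in model.compartments:
        D = np.asarray(D, dtype=float)
        quad = np.einsum("ij,jk,ik->i", g, D, g)
        S += f * np.exp(-b * quad)
    return model.s0 * S


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((v + n1)² + n2²), n1, n2 ~ N(0, sigma²)."""
    if sigma < 0:
        raise ConfigurationError("noise sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# fiber geometry
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """Tube-shaped fiber bundle along a polyline centerline.

    ``control_points`` are in voxel coordinates; ``radius`` in voxels.  The
    anisotropic (stick-like) compartment has cylindrically symmetric
    diffusivities along the local tangent; ``stick_fraction`` of the voxel
    signal comes from it, the rest from the isotropic background compartment.
    """

    control_points: np.ndarray        # (P, 3) voxel coordinates
    radius: float = 1.6               # voxels
    stick_fraction: float = 1.0
    lambda_parallel: float = 1.7e-3   # mm²/s
    lambda_perp: float = 0.3e-3       # mm²/s

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        if not (0.0 < self.stick_fraction <= 1.0):
            raise ConfigurationError("stick_fraction must be in (0, 1]")

    def polyline(self, spacing: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
        """Densely resampled centerline points and unit tangents."""
        pts = self.control_points
        segs = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(segs, axis=1)
        out_pts, out_tan = [], []
        for p0, seg, L in zip(pts[:-1], segs, seg_len):
            n = max(int(np.ceil(L / spacing)), 1)
            t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
            out_pts.append(p0 + t * seg)
            out_tan.append(np.tile(seg / L, (n, 1)))
        out_pts.append(pts[-1:])
        out_tan.append((segs[-1] / seg_len[-1])[None, :])
        return np.vstack(out_pts), np.vstack(out_tan)


@dataclass
class FiberGeometry:
    """Phantom layout: bundles, seed blob, and isotropic background."""

    shape: tuple
    voxel_size: float
    bundles: list
    seed_mask: np.ndarray
    background_diffusivity: float = 0.7e-3  # mm²/s
    s0: float = 1.0

    def __post_init__(self):
        self.seed_mask = np.asarray(self.seed_mask, dtype=bool)
        if self.seed_mask.shape != tuple(self.shape):
            raise ConfigurationError("seed mask shape differs from grid shape")
        if not self.seed_mask.any():
            raise ConfigurationError("seed mask is empty")
        tract = self.tract_mask()
        touch = binary_dilation(tract) & self.seed_mask
        if not touch.any():
            raise ConfigurationError("seed mask must overlap or abut a bundle")

    def _voxel_centers(self) -> np.ndarray:
        idx = np.indices(self.shape).reshape(3, -1).T
        return idx.astype(float)

    def bundle_fields(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-voxel (bundle_id, distance-to-centerline, tangent).

        bundle_id is −1 outside every tube; where tubes overlap the closer
        centerline wins.
        """
        centers = self._voxel_centers()
        best_id = np.full(centers.shape[0], -1, dtype=int)
        best_dist = np.full(centers.shape[0], np.inf)
        tangents = np.zeros((centers.shape[0], 3))
        for bi, bundle in enumerate(self.bundles):
            pts, tans = bundle.polyline()
            d2 = ((centers[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            nearest = np.argmin(d2, axis=1)
            dist = np.sqrt(d2[np.arange(centers.shape[0]), nearest])
            inside = dist <= bundle.radius
            take = inside & (dist < best_dist)
            best_id[take] = bi
            best_dist[take] = dist[take]
            tangents[take] = tans[nearest[take]]
        shp = tuple(self.shape)
        return (
            best_id.reshape(shp),
            best_dist.reshape(shp),
            tangents.reshape(shp + (3,)),
        )

    def tract_mask(self) -> np.ndarray:
        bundle_id, _, _ = self.bundle_fields()
        return bundle_id >= 0

    def tracking_mask(self, margin: int = 1) -> np.ndarray:
        """Tract mask dilated by ``margin`` voxels, union the seed blob."""
        m = self.tract_mask()
        if margin > 0:
            m = binary_dilation(m, iterations=margin)
        return m | self.seed_mask


def ellipsoid_mask(shape, center, radii) -> np.ndarray:
    idx = np.indices(shape).astype(float)
    c = np.asarray(center, dtype=float)
    r = np.asarray(radii, dtype=float)
    q = sum(((idx[k] - c[k]) / r[k]) ** 2 for k in range(3))
    return q <= 1.0


def default_geometry(shape=(32, 32, 16), voxel_size: float = 2.0) -> FiberGeometry:
    """Two roughly parallel bundles along x plus a seed blob abutting one end.

    Bundle A is straight; bundle B carries a gentle arc so the skeleton is
    not a single line.  The seed blob ("hippocampus") touches bundle A's
    left end, mimicking a hippocampus sitting against its efferent tract.
    """
    shape = tuple(shape)
    nx, ny, nz = shape
    zc = nz // 2
    bundle_a = Bundle(control_points=[[4.0, 10.0, zc], [nx - 5.0, 10.0, zc]])
    bundle_b = Bundle(
        control_points=[
            [4.0, ny - 11.0, zc],
            [nx / 2.0, ny - 9.0, zc],
            [nx - 5.0, ny - 11.0, zc],
        ]
    )
    seed = ellipsoid_mask(shape, center=(5.0, 13.5, zc), radii=(2.2, 2.6, 2.2))
    return FiberGeometry(
        shape=shape,
        voxel_size=voxel_size,
        bundles=[bundle_a, bundle_b],
        seed_mask=seed,
    )


# ---------------------------------------------------------------------------
# grid-level tissue model
# ---------------------------------------------------------------------------

@dataclass
class TissueVolume:
    """Vectorized per-voxel cylinder+ball tissue model over the whole grid.

    Compartment 1: cylindrically symmetric tensor (eigenvalues
    ``lam_par`` once and ``lam_perp`` twice along/about ``tangent``) with
    fraction ``frac_stick``; compartment 2: isotropic ``d_iso`` with the
    complementary fraction.  Background voxels have ``frac_stick = 0``.
    """

    shape: tuple
    voxel_size: float
    s0: float
    frac_stick: np.ndarray  # (X, Y, Z)
    tangent: np.ndarray     # (X, Y, Z, 3) unit where frac_stick > 0
    lam_par: np.ndarray     # (X, Y, Z) mm²/s
    lam_perp: np.ndarray
    d_iso: np.ndarray

    def copy(self) -> "TissueVolume":
        return TissueVolume(
            shape=self.shape,
            voxel_size=self.voxel_size,
            s0=self.s0,
            frac_stick=self.frac_stick.copy(),
            tangent=self.tangent.copy(),
            lam_par=self.lam_par.copy(),
            lam_perp=self.lam_perp.copy(),
            d_iso=self.d_iso.copy(),
        )

    def effective_eigenvalues(self) -> np.ndarray:
        """(X, Y, Z, 3) eigenvalues of the fraction-weighted tensor, descending.

        The cylinder and ball share eigenvectors, so the mixture eigenvalues
        are f·λ + (1−f)·d analytically.
        """
        f = self.frac_stick
        l1 = f * self.lam_par + (1.0 - f) * self.d_iso
        l23 = f * self.lam_perp + (1.0 - f) * self.d_iso
        ev = np.stack([l1, l23, l23], axis=-1)
        return np.sort(ev, axis=-1)[..., ::-1]

    def ground_truth_fa_md(self) -> tuple[np.ndarray, np.ndarray]:
        ev = self.effective_eigenvalues()
        return fa_from_eigenvalues(ev), md_from_eigenvalues(ev)

    def simulate(self, scheme: GradientScheme) -> np.ndarray:
        """Noise-free 4-D DWI (X, Y, Z, N)."""
        g = scheme.bvecs  # (N, 3)
        b = scheme.bvals
        tan = self.tangent.reshape(-1, 3)
        gt = tan @ g.T  # (V, N) dot products
        quad_stick = self.lam_perp.reshape(-1, 1) + (
            self.lam_par - self.lam_perp
        ).reshape(-1, 1) * gt**2
        att_stick = np.exp(-b[None, :] * quad_stick)
        att_iso = np.exp(-b[None, :] * self.d_iso.reshape(-1, 1))
        f = self.frac_stick.reshape(-1, 1)
        S = self.s0 * (f * att_stick + (1.0 - f) * att_iso)
        return S.reshape(tuple(self.shape) + (len(scheme),))


def tissue_volume_from_geometry(geom: FiberGeometry) -> TissueVolume:
    bundle_id, _, tangent = geom.bundle_fields()
    shp = tuple(geom.shape)
    frac = np.zeros(shp)
    lam_par = np.full(shp, geom.background_diffusivity)
    lam_perp = np.full(shp, geom.background_diffusivity)
    for bi, bundle in enumerate(geom.bundles):
        sel = bundle_id == bi
        frac[sel] = bundle.stick_fraction
        lam_par[sel] = bundle.lambda_parallel
        lam_perp[sel] = bundle.lambda_perp
    return TissueVolume(
        shape=shp,
        voxel_size=geom.voxel_size,
        s0=geom.s0,
        frac_stick=frac,
        tangent=tangent,
        lam_par=lam_par,
        lam_perp=lam_perp,
        d_iso=np.full(shp, geom.background_diffusivity),
    )


def _radial_scale_for_fa_reduction(
    lam_par: float, lam_perp: float, f: float, d_iso: float, fa_reduction_pct: float
) -> float:
    """Radial-eigenvalue scale s >= 1 so the effective-tensor FA drops by the
    requested percentage.  Raising the radial eigenvalues mimics
    demyelination-like loss of directionality."""

    def fa_of(s: float) -> float:
        l1 = f * lam_par + (1.0 - f) * d_iso
        l23 = f * lam_perp * s + (1.0 - f) * d_iso
        return float(fa_from_eigenvalues(np.array([l1, l23, l23])))

    fa0 = fa_of(1.0)
    target = fa0 * (1.0 - fa_reduction_pct / 100.0)
    if fa0 <= 0:
        raise ConfigurationError("cannot reduce FA of an isotropic voxel")
    s_max = lam_par / lam_perp  # isotropy point, FA -> 0
    if fa_of(s_max) > target:
        raise ConfigurationError(
            f"requested FA reduction {fa_reduction_pct}% unreachable by radial scaling"
        )
    return brentq(lambda s: fa_of(s) - target, 1.0, s_max, xtol=1e-12)


def apply_group_effect(
    tissue: TissueVolume,
    effect_mask: np.ndarray,
    md_elevation_pct: float = 0.0,
    fa_reduction_pct: float = 0.0,
) -> TissueVolume:
    """Return a copy with eigenvalues scaled inside ``effect_mask``.

    MD elevation multiplies every eigenvalue of every compartment by
    1 + pct/100 (FA is scale-invariant, so it is untouched).  FA reduction
    then raises the anisotropic compartment's radial eigenvalues so the
    effective-tensor FA drops by the requested percentage (a secondary MD
    increase follows and is reported as such, not removed).
    """
    if md_elevation_pct < 0 or fa_reduction_pct < 0:
        raise ConfigurationError("effect percentages must be >= 0")
    effect_mask = np.asarray(effect_mask, dtype=bool)
    out = tissue.copy()
    if not effect_mask.any() or (md_elevation_pct == 0 and fa_reduction_pct == 0):
        return out
    k = 1.0 + md_elevation_pct / 100.0
    out.lam_par[effect_mask] *= k
    out.lam_perp[effect_mask] *= k
    out.d_iso[effect_mask] *= k
    if fa_reduction_pct > 0:
        cache: dict[tuple, float] = {}
        vox = np.argwhere(effect_mask & (out.frac_stick > 0))
        for x, y, z in vox:
            key = (
                round(out.lam_par[x, y, z], 12),
                round(out.lam_perp[x, y, z], 12),
                round(out.frac_stick[x, y, z], 12),
                round(out.d_iso[x, y, z], 12),
            )
            if key not in cache:
                cache[key] = _radial_scale_for_fa_reduction(
                    *key, fa_reduction_pct=fa_reduction_pct
                )
            out.lam_perp[x, y, z] *= cache[key]
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Full description of a synthetic cohort (a pure function of this spec).

    ``md_elevation_pct`` / ``fa_reduction_pct`` are applied, inside
    ``effect_mask``, to every group except ``control_group``.
    ``noise_sigma`` is the Rician scale relative to s0 (sigma = s0/SNR).
    ``behavioural`` maps each group to (avlt_mean, avlt_sd) for the delayed
    recall score used by the amnestic classification rule.
    """

    n_per_group: dict
    geometry: FiberGeometry
    effect_mask: np.ndarray
    md_elevation_pct: float = 0.0
    fa_reduction_pct: float = 0.0
    noise_sigma: float = 0.04
    rng_seed: int = 0
    behavioural: dict = field(default_factory=dict)
    control_group: str = "CN"
    scheme: GradientScheme | None = None

    def __post_init__(self):
        if self.md_elevation_pct < 0 or self.fa_reduction_pct < 0 or self.noise_sigma < 0:
            raise ConfigurationError("effect percentages and noise sigma must be >= 0")
        self.effect_mask = np.asarray(self.effect_mask, dtype=bool)
        tract = self.geometry.tract_mask()
        if np.any(self.effect_mask & ~tract):
            raise ConfigurationError("effect mask must lie within bundle (tract) voxels")
        if self.scheme is None:
            self.scheme = make_gradient_scheme(32, 4, 1000.0, rng_seed=0)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    dwi: np.ndarray       # (X, Y, Z, N)
    gt_fa: np.ndarray     # noise-free ground truth
    gt_md: np.ndarray
    avlt_score: float


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Simulate one subject per cohort slot; deterministic given the spec.

    Per-subject randomness comes from independent substreams spawned from
    ``rng_seed``, so subsetting groups leaves other subjects unchanged.
    """
    for group in spec.n_per_group:
        if group not in spec.behavioural:
            raise ConfigurationError(f"group {group!r} has no behavioural parameters")
    base = tissue_volume_from_geometry(spec.geometry)
    affected = apply_group_effect(
        base, spec.effect_mask, spec.md_elevation_pct, spec.fa_reduction_pct
    )
    gt: dict[bool, tuple[np.ndarray, np.ndarray]] = {
        False: base.ground_truth_fa_md(),
        True: affected.ground_truth_fa_md(),
    }
    clean: dict[bool, np.ndarray] = {}

    subjects = []
    for gi, (group, n) in enumerate(sorted(spec.n_per_group.items())):
        group_ss = np.random.SeedSequence(spec.rng_seed, spawn_key=(gi,))
        streams = group_ss.spawn(int(n))
        is_affected = group != spec.control_group
        tissue = affected if is_affected else base
        if is_affected not in clean:
            clean[is_affected] = tissue.simulate(spec.scheme)
        for si in range(int(n)):
            rng = np.random.default_rng(streams[si])
            dwi = add_rician_noise(clean[is_affected], spec.noise_sigma * tissue.s0, rng)
            mean, sd = spec.behavioural[group]
            avlt = float(rng.normal(mean, sd))
            fa, md = gt[is_affected]
            subjects.append(
                SyntheticSubject(
                    subject_id=f"{group}{si:03d}",
                    group=group,
                    dwi=dwi,
                    gt_fa=fa,
                    gt_md=md,
                    avlt_score=avlt,
                )
            )
    return subjects


def classify_amnestic(avlt_score: float, cn_mean: float, cn_sd: float) -> str:
    """Amnestic iff delayed recall falls strictly more than 1.5 SD below the
    control mean; a score exactly at the cutoff is non-amnestic."""
    if cn_sd <= 0:
        raise ConfigurationError("control-group SD must be positive")
    threshold = cn_mean - AMNESTIC_SD_CUTOFF * cn_sd
    return "amnestic" if avlt_score < threshold else "non_amnestic"


# ---------------------------------------------------------------------------
# effect-mask design and presets
# ---------------------------------------------------------------------------

def effect_mask_by_axis_fraction(
    geometry: FiberGeometry,
    reference_coords: np.ndarray,
    fraction: float,
    axis: int = 0,
) -> np.ndarray:
    """Tract-voxel mask covering ~``fraction`` of a reference voxel set.

    ``reference_coords`` is an (S, 3) integer array (typically skeleton
    voxels).  The mask takes every tract voxel up to the axis coordinate
    below which the requested fraction of reference voxels lies — a
    contiguous "anterior" tract segment, the shape of a localized lesion.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("fraction must be in (0, 1]")
    coords = np.asarray(reference_coords)
    vals = np.sort(coords[:, axis])
    k = max(int(round(fraction * len(vals))), 1)
    cut = vals[k - 1]
    tract = geometry.tract_mask()
    axis_grid = np.indices(geometry.shape)[axis]
    return tract & (axis_grid <= cut)


def amci_like_spec(
    geometry: FiberGeometry | None = None,
    n_per_group: dict | None = None,
    effect_fraction_along_tract: float = 0.3,
    rng_seed: int = 0,
    noise_sigma: float = 0.04,
    scheme: GradientScheme | None = None,
) -> CohortSpec:
    """MD-elevation-without-FA-change cohort (the amnestic-MCI-like pattern).

    Mean diffusivity is raised 7% in a contiguous tract segment; FA is left
    untouched.  Behavioural parameters mirror delayed-recall scores of
    elderly control (12.9 ± 1.6) and amnestic (6.7 ± 1.4) groups.
    """
    geometry = geometry or default_geometry()
    tract = np.argwhere(geometry.tract_mask())
    return CohortSpec(
        n_per_group=n_per_group or {"CN": 15, "aMCI": 15},
        geometry=geometry,
        effect_mask=effect_mask_by_axis_fraction(
            geometry, tract, effect_fraction_along_tract
        ),
        md_elevation_pct=7.0,
        fa_reduction_pct=0.0,
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
        behavioural={"CN": (12.9, 1.6), "aMCI": (6.7, 1.4)},
        scheme=scheme,
    )


def ad_like_spec(
    geometry: FiberGeometry | None = None,
    n_per_group: dict | None = None,
    effect_fraction_along_tract: float = 0.66,
    rng_seed: int = 0,
    noise_sigma: float = 0.04,
    scheme: GradientScheme | None = None,
) -> CohortSpec:
    """Joint MD elevation and FA reduction over a larger tract segment
    (the dementia-like pattern: widespread MD increase plus FA loss)."""
    geometry = geometry or default_geometry()
    tract = np.argwhere(geometry.tract_mask())
    return CohortSpec(
        n_per_group=n_per_group or {"CN": 15, "AD": 15},
        geometry=geometry,
        effect_mask=effect_mask_by_axis_fraction(
            geometry, tract, effect_fraction_along_tract
        ),
        md_elevation_pct=8.5,
        fa_reduction_pct=11.3,
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
        behavioural={"CN": (12.9, 1.6), "AD": (5.4, 4.3)},
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(
    subjects: list[SyntheticSubject],
    spec: CohortSpec,
    outdir: str,
    write_ground_truth: bool = True,
) -> str:
    """Write DWI NIfTIs, gradient tables, masks and the TSV manifest.

    Returns the manifest path.
    """
    io.ensure_dir(outdir)
    vs = spec.geometry.voxel_size
    rows = []
    for subj in subjects:
        dwi_path = os.path.join(outdir, f"{subj.subject_id}_dwi.nii.gz")
        io.save_volume(subj.dwi, vs, dwi_path)
        prefix = os.path.join(outdir, subj.subject_id)
        bval_path, bvec_path = io.save_bvals_bvecs(
            spec.scheme.bvals, spec.scheme.bvecs, prefix
        )
        if write_ground_truth:
            io.save_volume(subj.gt_fa, vs, os.path.join(outdir, f"{subj.subject_id}_gtFA.nii.gz"))
            io.save_volume(subj.gt_md, vs, os.path.join(outdir, f"{subj.subject_id}_gtMD.nii.gz"))
        rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "dwi_path": os.path.basename(dwi_path),
                "bval_path": os.path.basename(bval_path),
                "bvec_path": os.path.basename(bvec_path),
                "avlt_score": subj.avlt_score,
            }
        )
    io.save_volume(spec.geometry.seed_mask, vs, os.path.join(outdir, "seed_mask.nii.gz"))
    io.save_volume(spec.geometry.tract_mask(), vs, os.path.join(outdir, "tract_mask.nii.gz"))
    io.save_volume(spec.effect_mask, vs, os.path.join(outdir, "effect_mask.nii.gz"))
    io.save_volume(
        spec.geometry.tracking_mask(), vs, os.path.join(outdir, "tracking_mask.nii.gz")
    )
    return io.save_manifest(rows, os.path.join(outdir, "manifest.tsv"))
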
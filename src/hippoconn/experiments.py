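"""Canonical validation experiments on synthetic cohorts with known truth.

Each function here runs one self-contained study — tensor-fit accuracy,
fiber-orientation recovery, tractography geometry, familywise-error
calibration, injected-effect recovery, the amnestic classification rule —
and returns its headline numbers as a plain dict.  The test suite, the
analysis scripts and the acceptance script all call these functions, so
every reported number is recomputed from scratch.

Problem sizes are desk scale by design: a 32×32×16 voxel grid at 2 mm, a
32+4-entry gradient table for cohort work (the full 99+10 layout for
single-voxel orientation studies), 15 subjects per group for effect
recovery, and 200 null cohorts of 8 vs 8 for error calibration.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_dilation

from hippoconn import phantom, skeleton, tensor, tract
from hippoconn.fibermodel import (
    BallStickParams,
    angle_between_axes,
    mean_orientation,
    predict_signal,
    sample_posterior_volume,
)
from hippoconn.phantom import add_rician_noise, classify_amnestic, make_gradient_scheme

# behavioural parameters of the elderly control and amnestic groups the
# generator emulates (delayed-recall mean ± SD)
CN_AVLT = (12.9, 1.6)
AMCI_AVLT = (6.7, 1.4)


def _seed(base: int, offset: int) -> int:
    return int(np.random.SeedSequence(base, spawn_key=(offset,)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# tensor oracle
# ---------------------------------------------------------------------------

def tensor_oracle(seed: int = 0, n_voxels: int = 64) -> dict:
    """Noise-free single-tensor phantom: fitted FA/MD vs analytic truth.

    Random PSD tensors per voxel (uniform random rotations of random
    eigenvalues in the physiological range); the log-linear fit is exact
    without noise, so errors are at float precision.
    """
    rng = np.random.default_rng(seed)
    scheme = make_gradient_scheme(32, 4, 1000.0, rng_seed=0)
    side = int(np.ceil(n_voxels ** (1 / 3)))
    shape = (side, side, side)
    nv = int(np.prod(shape))
    evals = rng.uniform(0.2e-3, 2.0e-3, size=(nv, 3))
    q, _ = np.linalg.qr(rng.standard_normal((nv, 3, 3)))
    D = np.einsum("vij,vj,vkj->vik", q, evals, q)
    g, b = scheme.bvecs, scheme.bvals
    quad = np.einsum("ni,vij,nj->vn", g, D, g)
    dwi = np.exp(-b[None, :] * quad).reshape(shape + (len(scheme),))
    fa_fit, md_fit, _ = tensor.fit_fa_md(dwi, scheme.bvals, scheme.bvecs)
    gt_fa = tensor.fa_from_eigenvalues(evals).reshape(shape)
    gt_md = tensor.md_from_eigenvalues(evals).reshape(shape)
    fa_err = float(np.max(np.abs(fa_fit - gt_fa) / gt_fa))
    md_err = float(np.max(np.abs(md_fit - gt_md) / gt_md))
    fa_wm = float(tensor.fa_from_eigenvalues(np.array([1.7e-3, 0.3e-3, 0.3e-3])))
    return {
        "n_voxels": nv,
        "fa_max_rel_error": fa_err,
        "md_max_rel_error": md_err,
        "fa_single_fiber_tensor": fa_wm,
        "md_single_fiber_tensor_mm2_s": (1.7e-3 + 0.3e-3 + 0.3e-3) / 3.0,
    }


# ---------------------------------------------------------------------------
# fiber-orientation recovery
# ---------------------------------------------------------------------------

def fiber_recovery(seed: int = 0, n_voxels: int = 24, snr: float = 20.0) -> dict:
    """Orientation recovery at acquisition scale (99 directions + 10 b0).

    Single-fiber phantom: posterior mean orientation vs truth and the mean
    angular deviation of the sampled orientations.  90° crossing phantom
    (two sticks of fraction 0.4): per-stick posterior cluster axes vs the
    two true axes.
    """
    scheme = make_gradient_scheme(99, 10, 1000.0, rng_seed=0)
    sigma = 1.0 / snr
    rng = np.random.default_rng(seed)

    v_true = np.array([1.0, 1.0, 0.3])
    v_true /= np.linalg.norm(v_true)
    p1 = BallStickParams(s0=1.0, d=1.2e-3, f1=0.6, f2=0.0, v1=v_true, v2=[0.0, 0.0, 1.0])
    clean = predict_signal(p1, scheme)
    dwi = add_rician_noise(np.tile(clean, (n_voxels, 1, 1, 1)), sigma, rng)
    post = sample_posterior_volume(
        dwi, scheme, np.ones((n_voxels, 1, 1), dtype=bool),
        rng=np.random.default_rng(_seed(seed, 1)),
    )
    mo = mean_orientation(post.v1)
    single_angle = angle_between_axes(mo, v_true)
    cosines = np.abs(np.einsum("vkj,j->vk", post.v1, v_true)).clip(0.0, 1.0)
    mean_dev = float(np.degrees(np.arccos(cosines)).mean())

    va, vb = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    pc = BallStickParams(s0=1.0, d=1.2e-3, f1=0.4, f2=0.4, v1=va, v2=vb)
    dwi_c = add_rician_noise(
        np.tile(predict_signal(pc, scheme), (n_voxels, 1, 1, 1)), sigma,
        np.random.default_rng(_seed(seed, 2)),
    )
    post_c = sample_posterior_volume(
        dwi_c, scheme, np.ones((n_voxels, 1, 1), dtype=bool),
        rng=np.random.default_rng(_seed(seed, 3)),
    )
    # per-voxel cluster axes from the two stick chains, averaged over voxels
    worst_angles = []
    for v in range(n_voxels):
        m1 = mean_orientation(post_c.v1[v])
        m2 = mean_orientation(post_c.v2[v])
        worst_angles.append(
            max(min(angle_between_axes(m, ax) for m in (m1, m2)) for ax in (va, vb))
        )
    return {
        "n_voxels": n_voxels,
        "snr": snr,
        "single_fiber_mean_orientation_deg": single_angle,
        "single_fiber_mean_angular_deviation_deg": mean_dev,
        "crossing_cluster_axis_error_deg": float(np.mean(worst_angles)),
        "crossing_cluster_axis_error_worst_deg": float(np.max(worst_angles)),
        "f2_posterior_mean_single_fiber": float(post.f2.mean()),
    }


# ---------------------------------------------------------------------------
# tractography geometry
# ---------------------------------------------------------------------------

def tube_phantom(shape=(32, 12, 12), voxel_size: float = 2.0) -> phantom.FiberGeometry:
    """Straight single-fiber tube along x with a seed blob at one end."""
    zc = shape[2] // 2
    yc = shape[1] // 2
    bundle = phantom.Bundle(
        control_points=[[3.0, float(yc), float(zc)], [shape[0] - 4.0, float(yc), float(zc)]]
    )
    seed_mask = phantom.ellipsoid_mask(shape, (3.0, float(yc), float(zc)), (1.4, 1.4, 1.4))
    return phantom.FiberGeometry(
        shape=shape, voxel_size=voxel_size, bundles=[bundle], seed_mask=seed_mask
    )


def tube_tractography(seed: int = 0, n_samples: int = 200) -> dict:
    """Geometry-controlled tracking oracle on a noise-free straight tube.

    Seeded at one end; reports the visit probability at the tube voxel ten
    propagation steps (5 mm ≈ 2.5 voxels) down the tube, the maximum
    probability over background voxels (≥ 2 voxels off the tube), and the
    seed-voxel value.
    """
    geom = tube_phantom()
    scheme = make_gradient_scheme(32, 4, 1000.0, rng_seed=0)
    tv = phantom.tissue_volume_from_geometry(geom)
    dwi = tv.simulate(scheme)  # noise-free: geometry is the only variable
    mask = geom.tracking_mask()
    post = sample_posterior_volume(
        dwi, scheme, mask, rng=np.random.default_rng(_seed(seed, 1))
    )
    cfg = tract.StreamlineConfig(n_samples=n_samples)
    yc, zc = geom.shape[1] // 2, geom.shape[2] // 2
    seed_voxel = (4, yc, zc)
    m = tract.track_from_voxel(
        seed_voxel, post, cfg, np.random.default_rng(_seed(seed, 2)),
        voxel_size=geom.voxel_size,
    )
    # 10 steps × 0.5 mm = 5 mm = 2.5 voxels at 2 mm: the tube voxel 3 along
    ten_steps_voxel = (seed_voxel[0] + 3, yc, zc)
    tube_mask = geom.tract_mask()
    background = ~binary_dilation(tube_mask, iterations=2) & ~geom.seed_mask
    hsc = tract.run_hsc(
        post, geom.seed_mask, cfg, rng_seed=_seed(seed, 3), voxel_size=geom.voxel_size
    )
    centerline = hsc.prob[np.arange(8, geom.shape[0] - 6), yc, zc]
    return {
        "n_streamlines": n_samples,
        "seed_voxel_probability": float(m.prob[seed_voxel]),
        "prob_10_steps_along_tube": float(m.prob[ten_steps_voxel]),
        "max_background_probability": float(m.prob[background].max()),
        "hsc_centerline_median": float(np.median(centerline)),
        "hsc_equals_one_on_seed": bool(np.all(hsc.prob[geom.seed_mask & post.mask] == 1.0)),
    }


# ---------------------------------------------------------------------------
# cohort-level helpers
# ---------------------------------------------------------------------------

def fit_cohort(subjects, scheme):
    """Tensor-fit every subject; returns (fa_maps, md_maps, groups)."""
    fa_maps, md_maps, groups = [], [], []
    for s in subjects:
        fa, md, _ = tensor.fit_fa_md(s.dwi, scheme.bvals, scheme.bvecs)
        fa_maps.append(fa)
        md_maps.append(md)
        groups.append(s.group)
    return fa_maps, md_maps, np.asarray(groups)


def reference_skeleton(geometry: phantom.FiberGeometry, fa_threshold: float = 0.2):
    """Skeleton of the noise-free control phantom (for effect-mask design)."""
    tv = phantom.tissue_volume_from_geometry(geometry)
    gt_fa, _ = tv.ground_truth_fa_md()
    return skeleton.build_skeleton([gt_fa, gt_fa], fa_threshold)


# ---------------------------------------------------------------------------
# familywise-error calibration
# ---------------------------------------------------------------------------

def fwe_calibration(
    seed: int = 0,
    n_sims: int = 200,
    n_perm: int = 500,
    n_per_group: int = 8,
    alpha: float = 0.05,
    noise_sigma: float = 0.04,
) -> dict:
    """Null cohorts (identical generating distributions) through the full
    tensor → skeleton → TFCE permutation chain; reports the familywise
    false-positive rate at ``alpha`` and the smallest corrected p achievable
    with an exhaustive 3-vs-3 enumeration (C(6,3) = 20 relabelings)."""
    geom = phantom.default_geometry()
    scheme = make_gradient_scheme(32, 4, 1000.0, rng_seed=0)
    no_effect = np.zeros(geom.shape, dtype=bool)
    hits = 0
    for sim in range(n_sims):
        spec = phantom.CohortSpec(
            n_per_group={"A": n_per_group, "B": n_per_group},
            geometry=geom,
            effect_mask=no_effect,
            noise_sigma=noise_sigma,
            rng_seed=_seed(seed, 10 + sim),
            control_group="A",
            behavioural={"A": CN_AVLT, "B": CN_AVLT},
            scheme=scheme,
        )
        subjects = phantom.generate_cohort(spec)
        fa_maps, md_maps, groups = fit_cohort(subjects, scheme)
        sk = skeleton.build_skeleton(fa_maps)
        pm = skeleton.project_cohort(md_maps, fa_maps, sk, "MD", voxel_size=geom.voxel_size)
        res = skeleton.permutation_contrast(
            pm, groups, "B", "A", sk.neighbors, "A>B",
            n_perm=n_perm, alpha=alpha, rng_seed=_seed(seed, 100000 + sim),
        )
        hits += bool(res.significant.any())

    # exhaustive 3 vs 3: strong injected effect so the observed labeling is extreme
    spec3 = phantom.CohortSpec(
        n_per_group={"A": 3, "B": 3},
        geometry=geom,
        effect_mask=phantom.effect_mask_by_axis_fraction(
            geom, reference_skeleton(geom).coords, 0.5
        ),
        md_elevation_pct=20.0,
        noise_sigma=noise_sigma,
        rng_seed=_seed(seed, 7),
        control_group="A",
        behavioural={"A": CN_AVLT, "B": AMCI_AVLT},
        scheme=scheme,
    )
    subjects3 = phantom.generate_cohort(spec3)
    fa3, md3, groups3 = fit_cohort(subjects3, scheme)
    sk3 = skeleton.build_skeleton(fa3)
    pm3 = skeleton.project_cohort(md3, fa3, sk3, "MD", voxel_size=geom.voxel_size)
    res3 = skeleton.permutation_contrast(
        pm3, groups3, "B", "A", sk3.neighbors, "A>B", n_perm=n_perm,
        rng_seed=_seed(seed, 8),
    )
    return {
        "n_sims": n_sims,
        "n_perm": n_perm,
        "alpha": alpha,
        "fwe_rate": hits / n_sims,
        "exhaustive_3v3": bool(res3.exhaustive),
        "exhaustive_3v3_n_perm": int(res3.n_perm),
        "min_corrected_p_3v3": float(res3.p_corrected.min()),
    }


# ---------------------------------------------------------------------------
# injected-effect recovery (the amnestic-MCI-like dissociation)
# ---------------------------------------------------------------------------

def effect_recovery(
    seed: int = 0,
    n_per_group: int = 15,
    md_elevation_pct: float = 7.0,
    effect_skeleton_fraction: float = 0.30,
    snr: float = 25.0,
    n_perm: int = 500,
) -> dict:
    """MD elevated in a tract segment covering ~30% of the skeleton, FA left
    intact: the MD contrast should recover the injected mask (Dice, abnormal
    volume fraction) while the FA contrast stays null — the
    MD-without-FA dissociation characteristic of amnestic MCI."""
    geom = phantom.default_geometry()
    scheme = make_gradient_scheme(32, 4, 1000.0, rng_seed=0)
    ref_sk = reference_skeleton(geom)
    effect_mask = phantom.effect_mask_by_axis_fraction(
        geom, ref_sk.coords, effect_skeleton_fraction
    )
    spec = phantom.CohortSpec(
        n_per_group={"CN": n_per_group, "aMCI": n_per_group},
        geometry=geom,
        effect_mask=effect_mask,
        md_elevation_pct=md_elevation_pct,
        noise_sigma=1.0 / snr,
        rng_seed=_seed(seed, 1),
        behavioural={"CN": CN_AVLT, "aMCI": AMCI_AVLT},
        scheme=scheme,
    )
    subjects = phantom.generate_cohort(spec)
    fa_maps, md_maps, groups = fit_cohort(subjects, scheme)
    sk = skeleton.build_skeleton(fa_maps)
    pm_md = skeleton.project_cohort(md_maps, fa_maps, sk, "MD", voxel_size=geom.voxel_size)
    pm_fa = skeleton.project_cohort(fa_maps, fa_maps, sk, "FA", voxel_size=geom.voxel_size)
    stat_seed = _seed(seed, 2)
    res_md = skeleton.permutation_contrast(
        pm_md, groups, "aMCI", "CN", sk.neighbors, "A>B", n_perm=n_perm, rng_seed=stat_seed
    )
    res_fa = skeleton.permutation_contrast(
        pm_fa, groups, "aMCI", "CN", sk.neighbors, "A<B", n_perm=n_perm, rng_seed=stat_seed
    )
    injected = effect_mask[tuple(sk.coords.T)]
    sig = res_md.significant
    denom = float(sig.sum() + injected.sum())
    dice = 2.0 * float(np.sum(sig & injected)) / denom if denom else 0.0
    rep = skeleton.summary_metrics(pm_md, groups, res_md, cn_label="CN")
    gtab = rep["groups"].set_index("group")
    return {
        "n_per_group": n_per_group,
        "snr": snr,
        "n_skeleton_voxels": sk.n_voxels,
        "injected_skeleton_fraction": float(injected.mean()),
        "md_abnormal_fraction": skeleton.abnormal_fraction(res_md, sk),
        "fa_abnormal_fraction": skeleton.abnormal_fraction(res_fa, sk),
        "md_dice_vs_injected": dice,
        "md_regional_pct_diff": float(gtab.loc["aMCI", "regional_pct_diff"]),
        "md_global_pct_diff": float(gtab.loc["aMCI", "global_pct_diff"]),
        "md_p_global": float(gtab.loc["aMCI", "p_global"]),
    }


# ---------------------------------------------------------------------------
# amnestic classification rule
# ---------------------------------------------------------------------------

def amnestic_rule(cn_mean: float = CN_AVLT[0], cn_sd: float = CN_AVLT[1]) -> dict:
    """The delayed-recall cutoff (control mean − 1.5 SD) on reference scores."""
    threshold = cn_mean - 1.5 * cn_sd
    return {
        "cn_mean": cn_mean,
        "cn_sd": cn_sd,
        "threshold": threshold,
        "amci_mean_score_label": classify_amnestic(AMCI_AVLT[0], cn_mean, cn_sd),
        "cn_mean_score_label": classify_amnestic(cn_mean, cn_mean, cn_sd),
        "boundary_label": classify_amnestic(threshold, cn_mean, cn_sd),
    }
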
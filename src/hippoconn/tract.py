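"""Probabilistic streamline tractography and seed-region connectivity maps.

From every voxel of a seed region, streamlines are propagated by sampling
the per-voxel fiber-orientation posterior: at each step one posterior sample
is drawn for the voxel containing the current position, a stick is selected
with probability proportional to its volume fraction (sticks below a floor
are never followed), the orientation is folded into the hemisphere of the
current heading, and the streamline terminates on sharp bends, on leaving
the tracking mask, or at the step limit.  Each streamline is launched in
both directions from its jittered seed point, since the connectivity of a
hippocampus-like seed carries no a-priori orientation.

A per-seed map records, for each voxel, the fraction of streamlines that
entered it — the probability of connection to that seed voxel.  The
seed-region connectivity map (the hippocampal structural connectivity map,
HSC) is the voxelwise maximum over all per-seed maps: the likelihood that a
voxel is connected to *any* part of the seed region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hippoconn.errors import ConfigurationError, InputError
from hippoconn.fibermodel import FiberPosterior


@dataclass
class StreamlineConfig:
    """Propagation parameters (probtrackx-like conventions)."""

    n_samples: int = 1000          # streamlines per seed voxel (desk scale: 200)
    step: float = 0.5              # mm
    curvature_cos_min: float = 0.2  # ≈ 78° maximum bend per step
    max_steps: int = 2000
    f_min: float = 0.05            # sticks below this fraction are never followed
    termination_mask: np.ndarray | None = None

    def validate(self, voxel_size: float) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if not (0.0 < self.step <= voxel_size):
            raise ConfigurationError("step must be in (0, voxel edge] mm")
        if not (-1.0 <= self.curvature_cos_min <= 1.0):
            raise ConfigurationError("curvature_cos_min must be in [-1, 1]")
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be >= 1")


@dataclass
class SeedVoxelMap:
    """Connection-probability volume for a single seed voxel."""

    seed: tuple
    prob: np.ndarray  # values in [0, 1]; exactly 1 at the seed voxel


@dataclass
class HSCMap:
    """Seed-region structural connectivity: max over per-seed maps."""

    prob: np.ndarray
    seed_region_id: str = "hippocampus"


def track_from_voxel(
    seed: tuple,
    posterior: FiberPosterior,
    cfg: StreamlineConfig,
    rng: np.random.Generator,
    voxel_size: float = 1.0,
    _vol_idx: np.ndarray | None = None,
) -> SeedVoxelMap:
    """Launch ``cfg.n_samples`` bidirectional streamlines from one seed voxel.

    All streamlines advance in lock-step (vectorized over the sample axis);
    positions are continuous voxel coordinates, the posterior is looked up
    at the containing (rounded) voxel.
    """
    cfg.validate(voxel_size)
    shape = posterior.shape
    seed = tuple(int(c) for c in seed)
    if not posterior.mask[seed]:
        raise InputError(f"seed voxel {seed} lies outside the tracking mask")
    vol_idx = posterior.voxel_index_volume() if _vol_idx is None else _vol_idx
    term = cfg.termination_mask
    n = cfg.n_samples
    step_vox = cfg.step / voxel_size
    nvox = int(np.prod(shape))
    visited = np.zeros((n, nvox), dtype=bool)
    flat_seed = np.ravel_multi_index(seed, shape)
    visited[:, flat_seed] = True
    dims = np.array(shape)

    # one jittered start and one initial orientation per streamline; the two
    # half-tracks leave along +d0 and −d0 (seed connectivity has no a-priori
    # orientation, so both senses of the initial sample are explored)
    pos0 = np.asarray(seed, dtype=float) + rng.uniform(-0.5, 0.5, size=(n, 3))
    seed_row = int(vol_idx[seed])
    ks0 = rng.integers(0, posterior.k, size=n)
    f1_0 = posterior.f1[seed_row, ks0]
    f2_0 = posterior.f2[seed_row, ks0]
    p1_0 = np.where(f1_0 >= cfg.f_min, f1_0, 0.0)
    p2_0 = np.where(f2_0 >= cfg.f_min, f2_0, 0.0)
    tot0 = p1_0 + p2_0
    launchable = tot0 > 0
    pick2_0 = rng.uniform(size=n) * np.where(tot0 > 0, tot0, 1.0) < p2_0
    d0 = np.where(pick2_0[:, None], posterior.v2[seed_row, ks0], posterior.v1[seed_row, ks0])

    for half_sign in (1.0, -1.0):
        pos = pos0 + half_sign * step_vox * d0
        heading = half_sign * d0
        active = launchable.copy()
        for _ in range(cfg.max_steps - 1):
            if not active.any():
                break
            ai = np.flatnonzero(active)
            vox = np.rint(pos[ai]).astype(np.int64)
            inside = np.all((vox >= 0) & (vox < dims), axis=1)
            drop = ai[~inside]
            active[drop] = False
            ai = ai[inside]
            if ai.size == 0:
                break
            vox = vox[inside]
            flat = np.ravel_multi_index(vox.T, shape)
            rows = vol_idx.ravel()[flat]
            in_mask = rows >= 0
            visited[ai[in_mask], flat[in_mask]] = True
            active[ai[~in_mask]] = False
            ai = ai[in_mask]
            if ai.size == 0:
                break
            rows = rows[in_mask]
            if term is not None:
                hit = term.ravel()[flat[in_mask]]
                active[ai[hit]] = False
                ai = ai[~hit]
                rows = rows[~hit]
                if ai.size == 0:
                    continue
            # draw one posterior sample per streamline, pick a stick ∝ f
            ks = rng.integers(0, posterior.k, size=ai.size)
            f1 = posterior.f1[rows, ks]
            f2 = posterior.f2[rows, ks]
            p1 = np.where(f1 >= cfg.f_min, f1, 0.0)
            p2 = np.where(f2 >= cfg.f_min, f2, 0.0)
            tot = p1 + p2
            has_stick = tot > 0
            active[ai[~has_stick]] = False
            ai = ai[has_stick]
            if ai.size == 0:
                continue
            rows, ks = rows[has_stick], ks[has_stick]
            pick2 = rng.uniform(size=ai.size) * tot[has_stick] < p2[has_stick]
            direction = np.where(
                pick2[:, None], posterior.v2[rows, ks], posterior.v1[rows, ks]
            )
            # fold into the hemisphere of the current heading
            prev = heading[ai]
            sign = np.sign((direction * prev).sum(axis=1))
            sign = np.where(sign == 0, 1.0, sign)
            direction = direction * sign[:, None]
            cos = (direction * prev).sum(axis=1)
            bend_ok = cos >= cfg.curvature_cos_min
            active[ai[~bend_ok]] = False
            ai = ai[bend_ok]
            if ai.size == 0:
                continue
            direction = direction[bend_ok]
            pos[ai] += step_vox * direction
            heading[ai] = direction

    prob = visited.mean(axis=0).reshape(shape)
    prob[seed] = 1.0
    return SeedVoxelMap(seed=seed, prob=prob)


def hsc_from_seed_maps(maps: list) -> HSCMap:
    """Voxelwise maximum over per-seed connection-probability maps."""
    if len(maps) == 0:
        raise InputError("need at least one seed-voxel map")
    shape = maps[0].prob.shape
    for m in maps:
        if m.prob.shape != shape:
            raise InputError("seed-voxel maps lie on different grids")
    out = maps[0].prob.copy()
    for m in maps[1:]:
        np.maximum(out, m.prob, out=out)
    return HSCMap(prob=out)


def run_hsc(
    posterior: FiberPosterior,
    seed_mask: np.ndarray,
    cfg: StreamlineConfig,
    rng_seed: int,
    voxel_size: float = 1.0,
    seed_region_id: str = "hippocampus",
    keep_seed_maps: bool = False,
):
    """Track from every seed voxel and combine with the max function.

    Every seed voxel gets its own random substream (spawned from
    ``rng_seed`` keyed by the voxel's flat index), so results per seed voxel
    are independent of which other seeds are processed.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    seeds = np.argwhere(seed_mask & posterior.mask)
    if seeds.shape[0] == 0:
        raise InputError("seed mask is empty (or disjoint from the tracking mask)")
    vol_idx = posterior.voxel_index_volume()
    shape = posterior.shape
    maps = []
    for seed in seeds:
        flat = int(np.ravel_multi_index(tuple(seed), shape))
        rng = np.random.default_rng(
            np.random.SeedSequence(rng_seed, spawn_key=(flat,))
        )
        maps.append(
            track_from_voxel(
                tuple(seed), posterior, cfg, rng, voxel_size=voxel_size, _vol_idx=vol_idx
            )
        )
    hsc = hsc_from_seed_maps(maps)
    hsc.seed_region_id = seed_region_id
    if keep_seed_maps:
        return hsc, maps
    return hsc
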
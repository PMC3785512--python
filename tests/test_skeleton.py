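"""Skeletonization, projection, TFCE, permutation inference, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippoconn import phantom, skeleton
from hippoconn.errors import ConfigurationError, InputError
from hippoconn.skeleton import ProjectedMatrix, tfce


# ---------------------------------------------------------------------------
# brute-force TFCE oracle: explicit threshold sweep + BFS components
# ---------------------------------------------------------------------------

def tfce_brute(stat, neighbors, e_exp=0.5, h_exp=2.0, dh=None, n_steps=100):
    stat = np.asarray(stat, float)
    S = len(stat)
    out = np.zeros(S)
    smax = stat.max(initial=0.0)
    if smax <= 0:
        return out
    dh = dh or smax / n_steps
    for k in range(1, int(math.floor(smax / dh + 1e-12)) + 1):
        h = k * dh
        above = stat >= h
        seen = np.zeros(S, bool)
        for s in range(S):
            if above[s] and not seen[s]:
                comp, queue = [s], [s]
                seen[s] = True
                while queue:
                    x = queue.pop()
                    for u in neighbors[x]:
                        if above[u] and not seen[u]:
                            seen[u] = True
                            comp.append(u)
                            queue.append(u)
                for v in comp:
                    out[v] += len(comp) ** e_exp * h**h_exp * dh
    return out


def _chain_neighbors(S):
    return [[j for j in (i - 1, i + 1) if 0 <= j < S] for i in range(S)]


def _tube_fa_volume(shift_y: float = 0.0, shape=(24, 12, 10)):
    """FA-like volume of a straight tube along x, optionally shifted in y."""
    geom = phantom.FiberGeometry(
        shape=shape,
        voxel_size=2.0,
        bundles=[
            phantom.Bundle(
                control_points=[
                    [3.0, shape[1] / 2 + shift_y, shape[2] / 2],
                    [shape[0] - 4.0, shape[1] / 2 + shift_y, shape[2] / 2],
                ]
            )
        ],
        seed_mask=phantom.ellipsoid_mask(
            shape, (3.0, shape[1] / 2, shape[2] / 2), (1.4, 1.4, 1.4)
        ),
    )
    tv = phantom.tissue_volume_from_geometry(geom)
    fa, _ = tv.ground_truth_fa_md()
    return fa


class TestBuildSkeleton:
    def test_tube_skeleton_follows_centerline(self):
        fa = _tube_fa_volume()
        sk = skeleton.build_skeleton([fa, fa])
        on_axis = np.sum((np.abs(sk.coords[:, 1] - 6) <= 1) & (np.abs(sk.coords[:, 2] - 5) <= 1))
        assert on_axis / sk.n_voxels >= 0.9
        # contiguous coverage of the tube interior (the smoothed ridge erodes
        # a few voxels at each open end, as skeletonization does on real data)
        xs = np.unique(sk.coords[:, 0])
        assert np.array_equal(xs, np.arange(xs.min(), xs.max() + 1))
        assert len(xs) >= 0.6 * (24 - 7)

    def test_skeleton_is_thin_along_perpendicular(self):
        fa = _tube_fa_volume()
        sk = skeleton.build_skeleton([fa, fa])
        mask = sk.mask_volume()
        dims = np.array(sk.shape)
        for coord, perp in zip(sk.coords, sk.perp_dirs):
            n_perp = 0
            for s in (-1, 1):
                q = np.rint(coord + s * perp).astype(int)
                if np.all(q >= 0) and np.all(q < dims) and mask[tuple(q)]:
                    n_perp += 1
            assert n_perp < 2

    def test_threshold_one_gives_empty_skeleton_error(self):
        fa = _tube_fa_volume()
        with pytest.raises(ConfigurationError):
            skeleton.build_skeleton([fa, fa], fa_threshold=1.0)

    def test_uniform_subthreshold_field_rejected(self):
        fa = np.full((8, 8, 8), 0.1)
        with pytest.raises(ConfigurationError):
            skeleton.build_skeleton([fa, fa], fa_threshold=0.2)

    def test_needs_two_subjects(self):
        with pytest.raises(InputError):
            skeleton.build_skeleton([_tube_fa_volume()])


class TestProjection:
    def test_aligned_tract_projects_centerline_values(self):
        fa = _tube_fa_volume()
        sk = skeleton.build_skeleton([fa, fa])
        vals, flagged = skeleton.project_to_skeleton(fa, fa, sk, max_dist_mm=4, voxel_size=2.0)
        assert not flagged.any()
        assert np.allclose(vals, fa[tuple(sk.coords.T)], atol=1e-9)

    def test_shifted_tract_projects_shifted_maximum(self):
        fa_ref = _tube_fa_volume()
        sk = skeleton.build_skeleton([fa_ref, fa_ref])
        fa_shift = _tube_fa_volume(shift_y=1.0)  # subject's tract 1 voxel off
        vals, _ = skeleton.project_to_skeleton(fa_shift, fa_shift, sk, 4.0, 2.0)
        center = np.abs(sk.coords[:, 0] - 12) < 5
        # projected FA equals the shifted centerline's FA, not the lower
        # value at the (now off-center) skeleton voxel
        assert np.median(vals[center]) >= 0.9 * fa_shift.max()

    def test_zero_search_distance_samples_in_place(self):
        fa = _tube_fa_volume()
        sk = skeleton.build_skeleton([fa, fa])
        rng = np.random.default_rng(0)
        other = rng.uniform(size=fa.shape)
        vals, _ = skeleton.project_to_skeleton(other, fa, sk, max_dist_mm=0.0, voxel_size=2.0)
        assert np.allclose(vals, other[tuple(sk.coords.T)], atol=1e-9)

    def test_unreachable_voxels_filled_and_flagged(self):
        fa = _tube_fa_volume()
        sk = skeleton.build_skeleton([fa, fa])
        zero_fa = np.zeros_like(fa)
        vals, flagged = skeleton.project_to_skeleton(zero_fa, zero_fa, sk, 4.0, 2.0)
        assert flagged.all()
        assert np.allclose(vals, 0.0)


class TestTFCE:
    def test_zero_map_gives_zero(self):
        assert np.all(tfce(np.zeros(10), _chain_neighbors(10)) == 0)

    def test_matches_brute_force_on_random_1d_skeletons(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            S = int(rng.integers(2, 33))
            stat = rng.normal(0.5, 1.0, S)
            nb = _chain_neighbors(S)
            assert np.max(np.abs(tfce(stat, nb) - tfce_brute(stat, nb))) <= 1e-10

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            S = int(rng.integers(4, 20))
            nb = [[] for _ in range(S)]
            for _ in range(S):
                i, j = rng.integers(0, S, 2)
                if i != j and j not in nb[i]:
                    nb[i].append(int(j))
                    nb[j].append(int(i))
            stat = rng.exponential(1.0, S)
            assert np.max(np.abs(tfce(stat, nb) - tfce_brute(stat, nb))) <= 1e-10

    def test_single_voxel_closed_form_limit(self):
        s, h_exp = 1.7, 2.0
        limit = s ** (h_exp + 1) / (h_exp + 1)
        errs = [abs(tfce(np.array([s]), [[]], dh=dh)[0] - limit) for dh in (1e-2, 1e-3, 1e-4)]
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 1e-3 * limit

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_monotone_in_statistic(self, data):
        S = data.draw(st.integers(4, 16))
        stat = np.array(data.draw(st.lists(st.floats(0, 3), min_size=S, max_size=S)))
        nb = _chain_neighbors(S)
        base = tfce(stat, nb, dh=0.05)
        idx = data.draw(st.integers(0, S - 1))
        bumped = stat.copy()
        bumped[idx] += data.draw(st.floats(0.1, 2.0))
        assert np.all(tfce(bumped, nb, dh=0.05) >= base - 1e-12)


def _null_matrix(rng, n, S):
    return ProjectedMatrix(values=rng.normal(size=(n, S)), modality="MD")


class TestPermutationContrast:
    def test_exhaustive_3v3_minimum_p(self):
        rng = np.random.default_rng(5)
        S = 16
        values = rng.normal(size=(6, S))
        values[:3] += 5.0  # strong group-A elevation
        pm = ProjectedMatrix(values=values, modality="MD")
        groups = np.array(["A"] * 3 + ["B"] * 3)
        res = skeleton.permutation_contrast(
            pm, groups, "A", "B", _chain_neighbors(S), "A>B", n_perm=500, rng_seed=0
        )
        assert res.exhaustive and res.n_perm == 20  # C(6,3) label assignments
        assert res.p_corrected.min() == pytest.approx(1.0 / 20.0)

    def test_p_values_in_permutation_range(self):
        rng = np.random.default_rng(6)
        pm = _null_matrix(rng, 12, 20)
        groups = np.array(["A"] * 6 + ["B"] * 6)
        res = skeleton.permutation_contrast(
            pm, groups, "A", "B", _chain_neighbors(20), "A>B", n_perm=200, rng_seed=1
        )
        assert np.all(res.p_corrected >= 1.0 / res.n_perm - 1e-12)
        assert np.all(res.p_corrected <= 1.0)

    def test_direction_flip_swaps_roles(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(8, 10))
        values[4:] += 3.0  # B elevated
        pm = ProjectedMatrix(values=values, modality="MD")
        groups = np.array(["A"] * 4 + ["B"] * 4)
        nb = _chain_neighbors(10)
        res_wrong = skeleton.permutation_contrast(pm, groups, "A", "B", nb, "A>B",
                                                  n_perm=100, rng_seed=2)
        res_right = skeleton.permutation_contrast(pm, groups, "A", "B", nb, "A<B",
                                                  n_perm=100, rng_seed=2)
        assert not res_wrong.significant.any()
        assert res_right.significant.any()

    def test_small_groups_rejected(self):
        pm = _null_matrix(np.random.default_rng(8), 3, 5)
        groups = np.array(["A", "B", "B"])
        with pytest.raises(InputError):
            skeleton.permutation_contrast(pm, groups, "A", "B", _chain_neighbors(5), "A>B")


class TestSummaries:
    def _result(self, S, sig_idx):
        sig = np.zeros(S, bool)
        sig[sig_idx] = True
        return skeleton.ContrastResult(
            group_a="aMCI", group_b="CN", direction="A>B",
            t=np.zeros(S), tfce_scores=np.zeros(S),
            p_corrected=np.where(sig, 0.01, 1.0), significant=sig,
            alpha=0.05, n_perm=100, exhaustive=False,
        )

    def test_abnormal_fraction_ratio_and_extremes(self):
        sk = skeleton.SkeletonModel(
            coords=np.zeros((500, 3), int), perp_dirs=np.zeros((500, 3)),
            mean_fa=np.zeros((1, 1, 1)), fa_threshold=0.2, shape=(1, 1, 1),
        )
        assert skeleton.abnormal_fraction(self._result(500, range(150)), sk) == 0.30
        assert skeleton.abnormal_fraction(self._result(500, []), sk) == 0.0
        assert skeleton.abnormal_fraction(self._result(500, range(500)), sk) == 1.0

    def test_percent_difference_and_z_scores(self):
        S = 40
        rng = np.random.default_rng(9)
        cn = 1.0 + 0.01 * rng.normal(size=(10, S))
        pat = cn * 1.071  # regional mean elevated 7.1%
        pm = ProjectedMatrix(values=np.vstack([cn, pat]), modality="MD")
        groups = np.array(["CN"] * 10 + ["aMCI"] * 10)
        rep = skeleton.summary_metrics(pm, groups, self._result(S, range(S)), "CN")
        gt = rep["groups"].set_index("group")
        assert gt.loc["aMCI", "regional_pct_diff"] == pytest.approx(7.1, abs=0.2)
        per = rep["per_subject"]
        cn_z = per.loc[per.group == "CN", "z_global"]
        assert cn_z.mean() == pytest.approx(0.0, abs=1e-12)
        assert cn_z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_identical_groups_give_null_summary(self):
        S = 10
        vals = np.tile(np.linspace(1, 2, S), (8, 1))
        pm = ProjectedMatrix(values=vals, modality="FA")
        groups = np.array(["CN"] * 4 + ["aMCI"] * 4)
        rep = skeleton.summary_metrics(pm, groups, self._result(S, range(S)), "CN")
        gt = rep["groups"].set_index("group")
        assert gt.loc["aMCI", "global_pct_diff"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_control_group_rejected(self):
        pm = ProjectedMatrix(values=np.ones((4, 5)), modality="FA")
        with pytest.raises(InputError):
            skeleton.summary_metrics(
                pm, np.array(["A"] * 4), self._result(5, []), "CN"
            )
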
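"""Synthetic-cohort generator: gradient schemes, forward model, noise,
group effects and the amnestic classification rule."""

import numpy as np
import pytest

from hippoconn import phantom
from hippoconn.errors import ConfigurationError


class TestGradientScheme:
    def test_acquisition_scale_layout(self):
        sch = phantom.make_gradient_scheme(99, 10, 1000.0, rng_seed=0)
        assert len(sch) == 109
        assert sch.n_b0 == 10
        assert np.all(sch.bvals[:10] == 0)

    def test_minimal_identifiable_scheme(self):
        sch = phantom.make_gradient_scheme(6, 1, 1000.0, rng_seed=0)
        assert len(sch) == 7

    def test_directions_are_unit_norm(self):
        sch = phantom.make_gradient_scheme(33, 2, 1000.0, rng_seed=4)
        norms = np.linalg.norm(sch.bvecs[sch.bvals > 0], axis=1)
        assert np.all(np.abs(norms - 1.0) < 1e-6)

    def test_deterministic_given_seed(self):
        a = phantom.make_gradient_scheme(20, 2, 1000.0, rng_seed=3)
        b = phantom.make_gradient_scheme(20, 2, 1000.0, rng_seed=3)
        assert np.array_equal(a.bvecs, b.bvecs)

    @pytest.mark.parametrize("n_dirs,n_b0,b", [(5, 1, 1000.0), (6, 0, 1000.0), (6, 1, 0.0)])
    def test_invalid_designs_rejected(self, n_dirs, n_b0, b):
        with pytest.raises(ConfigurationError):
            phantom.make_gradient_scheme(n_dirs, n_b0, b)


class TestForwardModel:
    def test_isotropic_closed_form(self):
        # d = 0.7e-3 mm²/s at b = 1000 → S = exp(-0.7) in every direction
        sch = phantom.make_gradient_scheme(12, 2, 1000.0, rng_seed=0)
        model = phantom.VoxelTissueModel(s0=1.0, compartments=[(1.0, 0.7e-3 * np.eye(3))])
        sig = phantom.simulate_signal(model, sch)
        assert np.allclose(sig[sch.bvals == 0], 1.0)
        assert np.allclose(sig[sch.bvals > 0], np.exp(-0.7), atol=1e-12)

    def test_perpendicular_stick_contributes_unattenuated(self):
        stick = np.zeros((3, 3))
        stick[0, 0] = 1.7e-3  # stick along x: λ_perp = 0
        model = phantom.VoxelTissueModel(s0=2.0, compartments=[(1.0, stick)])
        sch = phantom.GradientScheme(
            bvals=np.array([0.0] + [1000.0] * 6),
            bvecs=np.vstack([np.zeros(3), np.tile([0.0, 1.0, 0.0], (6, 1))]),
        )
        sig = phantom.simulate_signal(model, sch)
        assert np.allclose(sig, 2.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            phantom.VoxelTissueModel(s0=1.0, compartments=[(0.5, np.eye(3) * 1e-3)])

    def test_grid_simulation_matches_single_voxel_model(self, desk_scheme):
        geom = phantom.default_geometry()
        tv = phantom.tissue_volume_from_geometry(geom)
        dwi = tv.simulate(desk_scheme)
        vox = tuple(np.argwhere(geom.tract_mask())[0])
        t = tv.tangent[vox]
        lam_perp, lam_par = tv.lam_perp[vox], tv.lam_par[vox]
        D = lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(t, t)
        model = phantom.VoxelTissueModel(s0=1.0, compartments=[(1.0, D)])
        assert np.allclose(dwi[vox], phantom.simulate_signal(model, desk_scheme), atol=1e-12)


class TestRicianNoise:
    def test_zero_sigma_is_identity(self):
        sig = np.linspace(0.1, 1.0, 7)
        out = phantom.add_rician_noise(sig, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, sig)

    def test_outputs_nonnegative(self):
        rng = np.random.default_rng(1)
        out = phantom.add_rician_noise(np.zeros(1000), 0.3, rng)
        assert np.all(out >= 0)

    def test_rayleigh_mean_at_zero_signal(self):
        # E[sqrt(n1² + n2²)] = σ·sqrt(π/2); Monte-Carlo within 3 standard errors
        sigma, n = 0.7, 100_000
        rng = np.random.default_rng(2)
        out = phantom.add_rician_noise(np.zeros(n), sigma, rng)
        expected = sigma * np.sqrt(np.pi / 2.0)
        se = out.std(ddof=1) / np.sqrt(n)
        assert abs(out.mean() - expected) < 3 * se

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            phantom.add_rician_noise(np.ones(3), -0.1, np.random.default_rng(0))


def _small_spec(**overrides):
    geom = phantom.default_geometry((24, 24, 12))
    tract = np.argwhere(geom.tract_mask())
    base = dict(
        n_per_group={"CN": 2, "aMCI": 2},
        geometry=geom,
        effect_mask=phantom.effect_mask_by_axis_fraction(geom, tract, 0.3),
        md_elevation_pct=0.0,
        fa_reduction_pct=0.0,
        noise_sigma=0.0,
        rng_seed=5,
        behavioural={"CN": (12.9, 1.6), "aMCI": (6.7, 1.4)},
        scheme=phantom.make_gradient_scheme(16, 2, 1000.0, rng_seed=0),
    )
    base.update(overrides)
    return phantom.CohortSpec(**base)


class TestCohortGeneration:
    def test_null_effect_groups_identical(self):
        subs = phantom.generate_cohort(_small_spec())
        gt = {s.group: (s.gt_fa, s.gt_md) for s in subs}
        assert np.array_equal(gt["CN"][0], gt["aMCI"][0])
        assert np.array_equal(gt["CN"][1], gt["aMCI"][1])

    def test_md_elevation_scales_md_not_fa(self):
        spec = _small_spec(md_elevation_pct=10.0)
        subs = phantom.generate_cohort(spec)
        cn = next(s for s in subs if s.group == "CN")
        pat = next(s for s in subs if s.group == "aMCI")
        em = spec.effect_mask
        assert np.allclose(pat.gt_md[em], 1.10 * cn.gt_md[em], rtol=1e-12)
        assert np.allclose(pat.gt_fa[em], cn.gt_fa[em], rtol=1e-12)
        outside = ~em
        assert np.array_equal(pat.gt_md[outside], cn.gt_md[outside])

    def test_fa_reduction_hits_target(self):
        spec = _small_spec(fa_reduction_pct=11.3)
        subs = phantom.generate_cohort(spec)
        cn = next(s for s in subs if s.group == "CN")
        pat = next(s for s in subs if s.group == "aMCI")
        em = spec.effect_mask
        ratio = pat.gt_fa[em] / cn.gt_fa[em]
        assert np.allclose(ratio, 1.0 - 0.113, atol=1e-9)

    def test_bit_identical_on_rerun(self):
        spec = _small_spec(noise_sigma=0.05)
        a = phantom.generate_cohort(spec)
        b = phantom.generate_cohort(spec)
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            assert np.array_equal(sa.dwi, sb.dwi)
            assert sa.avlt_score == sb.avlt_score

    def test_missing_behavioural_group_rejected(self):
        with pytest.raises(ConfigurationError):
            phantom.generate_cohort(_small_spec(behavioural={"CN": (12.9, 1.6)}))

    def test_effect_mask_outside_tract_rejected(self):
        geom = phantom.default_geometry((24, 24, 12))
        bad = np.zeros(geom.shape, dtype=bool)
        bad[0, 0, 0] = True  # background corner
        with pytest.raises(ConfigurationError):
            _small_spec(effect_mask=bad)

    def test_seed_mask_must_touch_a_bundle(self):
        geom = phantom.default_geometry((24, 24, 12))
        lonely = np.zeros(geom.shape, dtype=bool)
        lonely[0, 0, 0] = True
        with pytest.raises(ConfigurationError):
            phantom.FiberGeometry(
                shape=geom.shape, voxel_size=2.0, bundles=geom.bundles, seed_mask=lonely
            )


class TestCohortOnDisk:
    def test_roundtrip_manifest_and_gradients(self, tmp_path):
        from hippoconn import io

        spec = _small_spec(noise_sigma=0.02)
        subs = phantom.generate_cohort(spec)
        manifest = phantom.write_cohort(subs, spec, str(tmp_path))
        df = io.load_manifest(manifest)
        assert len(df) == 4
        assert set(df.group) == {"CN", "aMCI"}
        row = df.iloc[0]
        bvals, bvecs = io.load_bvals_bvecs(
            str(tmp_path / row.bval_path), str(tmp_path / row.bvec_path)
        )
        assert bvecs.shape == (len(spec.scheme), 3)
        assert np.allclose(bvals, spec.scheme.bvals)
        dwi, vs = io.load_volume(str(tmp_path / row.dwi_path))
        subj = next(s for s in subs if s.subject_id == row.subject_id)
        assert np.allclose(dwi, subj.dwi, atol=1e-6)
        assert vs[0] == spec.geometry.voxel_size


class TestAmnesticRule:
    def test_reference_scores(self):
        # control delayed recall 12.9 ± 1.6 → cutoff 10.5
        assert phantom.classify_amnestic(6.7, 12.9, 1.6) == "amnestic"
        assert phantom.classify_amnestic(12.9, 12.9, 1.6) == "non_amnestic"

    def test_boundary_is_strict(self):
        assert phantom.classify_amnestic(10.5, 12.9, 1.6) == "non_amnestic"
        assert phantom.classify_amnestic(10.5 - 1e-9, 12.9, 1.6) == "amnestic"

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            phantom.classify_amnestic(5.0, 12.9, 0.0)
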
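"""Ball-and-stick model: forward prediction, point fit, posterior sampler."""

import numpy as np
import pytest

from hippoconn import fibermodel, phantom
from hippoconn.errors import ConfigurationError
from hippoconn.fibermodel import BallStickParams, angle_between_axes, mean_orientation


@pytest.fixture(scope="module")
def acq_scheme():
    """Acquisition-scale scheme (99 directions + 10 b0) for orientation work."""
    return phantom.make_gradient_scheme(99, 10, 1000.0, rng_seed=0)


class TestPredictSignal:
    def test_ball_only_is_monoexponential(self, desk_scheme):
        p = BallStickParams(s0=2.0, d=1e-3, f1=0.0, f2=0.0, v1=[1, 0, 0], v2=[0, 1, 0])
        sig = fibermodel.predict_signal(p, desk_scheme)
        assert np.allclose(sig, 2.0 * np.exp(-desk_scheme.bvals * 1e-3))

    def test_perpendicular_stick_unattenuated(self):
        sch = phantom.GradientScheme(
            bvals=np.array([0.0] + [1000.0] * 6),
            bvecs=np.vstack([np.zeros(3), np.tile([0.0, 1.0, 0.0], (6, 1))]),
        )
        p = BallStickParams(s0=1.0, d=1e-3, f1=0.5, f2=0.0, v1=[1, 0, 0], v2=[0, 0, 1])
        sig = fibermodel.predict_signal(p, sch)
        ball = 0.5 * np.exp(-sch.bvals * 1e-3)
        assert np.allclose(sig, ball + 0.5)

    def test_parallel_stick_equals_ball_attenuation(self, desk_scheme):
        g = desk_scheme.bvecs[desk_scheme.bvals > 0][0]
        p = BallStickParams(s0=1.0, d=1e-3, f1=0.7, f2=0.0, v1=g, v2=[0, 0, 1])
        sig = fibermodel.predict_signal(p, desk_scheme)
        i = desk_scheme.n_b0  # the entry whose direction equals the stick
        assert sig[i] == pytest.approx(np.exp(-1000.0 * 1e-3), abs=1e-12)

    def test_antipodal_symmetry(self, desk_scheme):
        v = np.array([1.0, 2.0, -0.5])
        v /= np.linalg.norm(v)
        pa = BallStickParams(s0=1.0, d=1e-3, f1=0.6, f2=0.0, v1=v, v2=[0, 0, 1])
        pb = BallStickParams(s0=1.0, d=1e-3, f1=0.6, f2=0.0, v1=-v, v2=[0, 0, 1])
        assert np.array_equal(
            fibermodel.predict_signal(pa, desk_scheme),
            fibermodel.predict_signal(pb, desk_scheme),
        )

    def test_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            BallStickParams(s0=1.0, d=1e-3, f1=0.7, f2=0.5, v1=[1, 0, 0], v2=[0, 1, 0])
        with pytest.raises(ConfigurationError):
            BallStickParams(s0=1.0, d=1e-3, f1=0.2, f2=0.5, v1=[1, 0, 0], v2=[0, 1, 0])
        with pytest.raises(ConfigurationError):
            BallStickParams(s0=1.0, d=1e-3, f1=0.5, f2=0.0, v1=[2, 0, 0], v2=[0, 1, 0])


class TestPointFit:
    def test_exact_single_stick_recovery(self, acq_scheme):
        v = np.array([0.2, 1.0, 0.4])
        v /= np.linalg.norm(v)
        truth = BallStickParams(s0=1.0, d=1.5e-3, f1=0.6, f2=0.0, v1=v, v2=[0, 0, 1])
        fit = fibermodel.fit_ball_stick(fibermodel.predict_signal(truth, acq_scheme), acq_scheme)
        assert angle_between_axes(fit.v1, v) < 1.0
        assert abs(fit.f1 - 0.6) < 0.02

    def test_isotropic_voxel_fits_no_stick(self, acq_scheme):
        model = phantom.VoxelTissueModel(s0=1.0, compartments=[(1.0, 0.8e-3 * np.eye(3))])
        fit = fibermodel.fit_ball_stick(phantom.simulate_signal(model, acq_scheme), acq_scheme)
        assert fit.f1 <= 0.05


class TestPosterior:
    def test_deterministic_given_rng_state(self, desk_scheme):
        p = BallStickParams(s0=1.0, d=1.2e-3, f1=0.6, f2=0.0, v1=[1, 0, 0], v2=[0, 1, 0])
        sig = phantom.add_rician_noise(
            fibermodel.predict_signal(p, desk_scheme), 0.05, np.random.default_rng(0)
        )
        a = fibermodel.sample_posterior(sig, desk_scheme, rng=np.random.default_rng(9))
        b = fibermodel.sample_posterior(sig, desk_scheme, rng=np.random.default_rng(9))
        assert np.array_equal(a.v1, b.v1)
        assert np.array_equal(a.f1, b.f1)

    def test_fraction_simplex_respected(self, desk_scheme):
        p = BallStickParams(s0=1.0, d=1.2e-3, f1=0.5, f2=0.3, v1=[1, 0, 0], v2=[0, 1, 0])
        sig = phantom.add_rician_noise(
            fibermodel.predict_signal(p, desk_scheme), 0.05, np.random.default_rng(1)
        )
        post = fibermodel.sample_posterior(sig, desk_scheme, rng=np.random.default_rng(2))
        assert np.all(post.f1 + post.f2 <= 1.0 + 1e-12)
        assert np.all(post.f1 >= post.f2)
        assert np.all(post.f2 >= 0)

    def test_single_fiber_recovery_at_snr20(self, acq_scheme):
        """Mean angular deviation of sampled v1 ≤ 5° on a single-fiber
        phantom at SNR 20 (acquisition-scale scheme)."""
        v = np.array([1.0, 1.0, 0.3])
        v /= np.linalg.norm(v)
        p = BallStickParams(s0=1.0, d=1.2e-3, f1=0.6, f2=0.0, v1=v, v2=[0, 0, 1])
        nvox = 12
        dwi = phantom.add_rician_noise(
            np.tile(fibermodel.predict_signal(p, acq_scheme), (nvox, 1, 1, 1)),
            0.05,
            np.random.default_rng(3),
        )
        post = fibermodel.sample_posterior_volume(
            dwi, acq_scheme, np.ones((nvox, 1, 1), bool), rng=np.random.default_rng(4)
        )
        cos = np.abs(np.einsum("vkj,j->vk", post.v1, v)).clip(0, 1)
        assert np.degrees(np.arccos(cos)).mean() <= 5.0

    def test_spurious_second_stick_suppressed_on_exact_data(self, desk_scheme):
        """True f2 = 0, noise-free data → posterior mean f2 ≤ 0.1.

        Averaged over replicate chains: a single chain can linger on the
        likelihood ridge where one stick splits into two nearby ones."""
        p = BallStickParams(s0=1.0, d=1.2e-3, f1=0.6, f2=0.0, v1=[1, 0, 0], v2=[0, 1, 0])
        clean = fibermodel.predict_signal(p, desk_scheme)
        dwi = np.tile(clean, (16, 1, 1, 1))
        post = fibermodel.sample_posterior_volume(
            dwi, desk_scheme, np.ones((16, 1, 1), bool), rng=np.random.default_rng(5)
        )
        assert post.f2.mean() <= 0.1

    def test_crossing_resolved_within_ten_degrees(self, acq_scheme):
        va, vb = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
        p = BallStickParams(s0=1.0, d=1.2e-3, f1=0.4, f2=0.4, v1=va, v2=vb)
        nvox = 8
        dwi = phantom.add_rician_noise(
            np.tile(fibermodel.predict_signal(p, acq_scheme), (nvox, 1, 1, 1)),
            0.05,
            np.random.default_rng(6),
        )
        post = fibermodel.sample_posterior_volume(
            dwi, acq_scheme, np.ones((nvox, 1, 1), bool), rng=np.random.default_rng(7)
        )
        worst = []
        for i in range(nvox):
            m1, m2 = mean_orientation(post.v1[i]), mean_orientation(post.v2[i])
            worst.append(
                max(min(angle_between_axes(m, ax) for m in (m1, m2)) for ax in (va, vb))
            )
        assert np.mean(worst) <= 10.0

    def test_axial_statistics_are_sign_invariant(self):
        rng = np.random.default_rng(8)
        vs = rng.normal(size=(40, 3))
        vs /= np.linalg.norm(vs, axis=1, keepdims=True)
        signs = rng.choice([-1.0, 1.0], size=(40, 1))
        m1, m2 = mean_orientation(vs), mean_orientation(vs * signs)
        assert angle_between_axes(m1, m2) < 1e-6


class TestPersistence:
    def test_roundtrip(self, tmp_path, desk_scheme):
        p = BallStickParams(s0=1.0, d=1.2e-3, f1=0.6, f2=0.0, v1=[1, 0, 0], v2=[0, 1, 0])
        sig = phantom.add_rician_noise(
            fibermodel.predict_signal(p, desk_scheme), 0.05, np.random.default_rng(0)
        )
        dwi = np.tile(sig, (2, 2, 1, 1))
        mask = np.ones((2, 2, 1), bool)
        mask[1, 1, 0] = False
        post = fibermodel.sample_posterior_volume(
            dwi, desk_scheme, mask, rng=np.random.default_rng(1)
        )
        prefix = str(tmp_path / "subj0")
        fibermodel.save_posterior(post, 2.0, prefix, settings={"note": "test"})
        back = fibermodel.load_posterior(prefix)
        assert np.array_equal(back.mask, post.mask)
        assert np.allclose(back.f1, post.f1, atol=1e-6)
        assert np.allclose(back.v1, post.v1, atol=1e-6)
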
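"""CS/TV and CORe solvers, Hadamard velocity decode, PC-MRA, tuning."""

import numpy as np
import pytest

from fetalflow import (
    PhantomConfig,
    bin_cardiac,
    generate_pseudo_spiral_trajectory,
    make_phantom,
    simulate_acquisition,
    simulate_triggers,
    tune_core_params,
)
from fetalflow.operators import SensingOperator, build_operator
from fetalflow.phantom import segment_images
from fetalflow.recon import (
    _block_soft_threshold,
    build_core_problem,
    compute_pcmra,
    cs_recon_l1wavelet,
    cs_recon_tv,
    decode_stack,
    group_norms,
    hadamard_decode,
    prescale,
    prox_tv_t,
    solve_core,
)
from fetalflow.sampling import HADAMARD_SIGNS, BinAssignment, KSpaceData


def _reference_stack(scene, scale):
    return np.stack(
        [segment_images(scene, f) for f in range(scene.n_frames)]
    ) * scale


class TestCsReconTV:
    def test_least_squares_limit_full_sampling(self, static_scene16, full_ks16):
        a = bin_cardiac(full_ks16, full_ks16.trigger_times, 1)
        x, diag = cs_recon_tv(full_ks16, a, lambda_tv=0.0, iters=5)
        _, s = prescale(full_ks16.samples)
        ref = _reference_stack(static_scene16, s)
        assert np.linalg.norm(x - ref) / np.linalg.norm(ref) < 1e-6
        obj = diag["objective"]
        assert np.all(np.diff(obj) <= 1e-8 * np.abs(obj[:-1]) + 1e-12)

    def test_huge_tv_weight_collapses_to_temporal_mean(self):
        # two fully sampled 8^3 "bins" with different images
        n = 8
        rng = np.random.default_rng(0)
        imgs = rng.normal(size=(2, 1, n, n, n)) + 1j * rng.normal(size=(2, 1, n, n, n))
        ky, kz = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        ky = np.tile(ky.ravel(), 2)
        kz = np.tile(kz.ravel(), 2)
        labels = np.repeat(np.arange(2), n * n)
        op = SensingOperator(
            matrix_size=(n, n, n), coil_sens=np.ones((1, n, n, n), complex),
            t_index=labels, segment=np.zeros(labels.size, int), ky=ky, kz=kz,
            n_t=2, n_seg=1,
        )
        y = op.forward(imgs)
        ks = KSpaceData(
            samples=y, time=np.arange(y.shape[0], dtype=float),
            ky=ky, kz=kz, segment=np.zeros(labels.size, int), resp=None,
            matrix_size=(n, n, n), voxel_size=(1.0, 1.0, 1.0), venc=150.0,
            n_frames=1, trigger_times=np.array([0.0, 1.0]),
            coil_sens=np.ones((1, n, n, n), complex),
        )
        # single-segment bookkeeping: replicate the one segment label
        a = BinAssignment(motion_bin=labels)
        x, _ = cs_recon_tv(ks, a, dim="motion_bin", lambda_tv=1e6, iters=60,
                           tol=0.0)
        # segments dimension is rebuilt as 4 inside; compare on segment 0
        mean = x.mean(axis=0, keepdims=True)
        spread = np.linalg.norm(x - mean) / np.linalg.norm(mean)
        assert spread < 1e-3

    def test_regularized_recon_beats_zero_filled(self, scene16):
        traj = generate_pseudo_spiral_trajectory((16, 16, 16), r=4,
                                                 n_interleaves=6, tr=0.003,
                                                 duration=45.0)
        trig = simulate_triggers(150, 0.01, 46.0, seed=0)
        ks = simulate_acquisition(scene16, traj, None, trig, noise_sd=0.02,
                                  seed=1)
        a = bin_cardiac(ks, ks.trigger_times, 10)
        x, _ = cs_recon_tv(ks, a, lambda_tv=0.01, iters=15)
        op, y, _ = build_operator(ks, a.cardiac_frame)
        y_scaled, s = prescale(y)
        ref = _reference_stack(scene16, s)
        x0 = op.adjoint_dc(y_scaled)
        nrmse = np.linalg.norm(x - ref) / np.linalg.norm(ref)
        nrmse0 = np.linalg.norm(x0 - ref) / np.linalg.norm(ref)
        assert nrmse < nrmse0


class TestProxTV:
    def test_prox_matches_small_fixed_point(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(6, 3))
        tau = 0.3
        x = prox_tv_t(y, tau, n_iter=500)
        # optimality: subgradient of 0.5||x-y||^2 + tau TV contains 0
        obj = 0.5 * np.sum((x - y) ** 2) + tau * np.abs(np.diff(x, axis=0)).sum()
        for _ in range(200):
            pert = x + rng.normal(scale=1e-4, size=x.shape)
            obj_p = 0.5 * np.sum((pert - y) ** 2) + tau * np.abs(
                np.diff(pert, axis=0)
            ).sum()
            assert obj_p >= obj - 1e-9

    def test_huge_tau_returns_temporal_mean(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(5, 4, 4))
        x = prox_tv_t(y, 1e6, n_iter=400)
        assert np.allclose(x, y.mean(axis=0, keepdims=True), atol=1e-3)


class TestSolveCore:
    def test_block_soft_threshold_closed_form(self):
        theta = 2.0
        r = np.zeros((2, 4, 2), complex)
        r[0] += 0.2  # ||r_0|| = 0.2*sqrt(8) < theta -> zeroed
        r[1] += 1.0  # ||r_1|| = sqrt(8) = 2*theta at theta=sqrt(2)
        v = _block_soft_threshold(r, theta)
        assert np.all(v[0] == 0)
        theta2 = np.sqrt(8.0) / 2.0
        v2 = _block_soft_threshold(r, theta2)
        assert np.allclose(v2[1], r[1] / 2.0)

    def test_infinite_lambda2_recovers_plain_cs(self, full_ks16):
        a = bin_cardiac(full_ks16, full_ks16.trigger_times, 1)
        prob = build_core_problem(full_ks16, a, lambda2=np.inf)
        x_inf, v, d = solve_core(prob, iters=6)
        assert np.abs(v).max() == 0.0
        op, y, _ = build_operator(full_ks16, a.cardiac_frame)
        y, _ = prescale(y)
        x_cs = cs_recon_l1wavelet(op, y, sigma2=1.0, iters=6)
        assert np.linalg.norm(x_inf - x_cs) / np.linalg.norm(x_cs) < 1e-6

    def test_identity_limit_full_sampling_no_regularization(
        self, static_scene16, full_ks16
    ):
        # lambda1 = 0, sigma^2 = 1, full sampling, v = 0: inverse FFT recon
        a = bin_cardiac(full_ks16, full_ks16.trigger_times, 1)
        prob = build_core_problem(full_ks16, a, lambda1=0.0, lambda2=np.inf,
                                  sigma2=1.0)
        x, _, _ = solve_core(prob, iters=4)
        _, s = prescale(full_ks16.samples)
        ref = _reference_stack(static_scene16, s)
        assert np.linalg.norm(x - ref) / np.linalg.norm(ref) < 1e-8

    def test_objective_monotone_on_undersampled_noisy_data(self, scene16):
        traj = generate_pseudo_spiral_trajectory((16, 16, 16), r=3, tr=0.004,
                                                 duration=30.0)
        trig = simulate_triggers(150, 0.01, 31.0, seed=2)
        ks = simulate_acquisition(scene16, traj, None, trig, noise_sd=0.05,
                                  seed=3)
        a = bin_cardiac(ks, ks.trigger_times, 10)
        prob = build_core_problem(ks, a)
        _, _, d = solve_core(prob, iters=8, tol=0.0)
        obj = d["objective"]
        assert np.all(np.diff(obj) <= 1e-8 * np.abs(obj[:-1]) + 1e-12)


class TestHadamardDecode:
    @staticmethod
    def _encode(v, venc=150.0, phi0=0.1, mag=2.0):
        scale = np.pi / (2 * venc)
        return np.stack(
            [mag * np.exp(1j * (phi0 + scale * (HADAMARD_SIGNS[s] @ v)))
             for s in range(4)]
        )

    def test_zero_velocity_decodes_to_zero(self):
        z = self._encode(np.zeros((3, 5)))
        assert np.allclose(np.angle(z[1] / z[0]), 0.0)
        _, v, aliased = hadamard_decode(z, 150.0)
        assert np.abs(v).max() < 1e-12
        assert not aliased.any()

    def test_round_trip_exact_below_venc(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(-149.9, 149.9, size=(3, 200))
        z = self._encode(v)
        mag, vd, _ = hadamard_decode(z, 150.0, phi0=0.1)
        assert np.abs(vd - v).max() < 1e-10
        assert np.allclose(mag, 2.0)

    def test_boundary_velocity_flagged_at_limit(self):
        z = self._encode(np.array([150.0, 0.0, 0.0]), phi0=0.0)
        _, v, aliased = hadamard_decode(z, 150.0, phi0=0.0)
        assert abs(abs(v[0]) - 150.0) < 1e-9
        assert aliased[0]

    def test_differences_only_decode_within_clinical_range(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(-60, 60, size=(3, 100))
        z = self._encode(v, phi0=0.73)
        _, vd, _ = hadamard_decode(z, 150.0, phi0=None)
        assert np.abs(vd - v).max() < 1e-10


class TestPcmra:
    def test_zero_velocity_gives_zero_pcmra(self):
        mag = np.ones((3, 4, 4, 4))
        vel = np.zeros((3, 3, 4, 4, 4))
        assert np.all(compute_pcmra(mag, vel) == 0)

    def test_single_voxel_value_forced_by_formula(self):
        mag = np.full((5, 1, 1, 1), 2.0)
        vel = np.zeros((5, 3, 1, 1, 1))
        vel[:, 0] = 3.0
        assert compute_pcmra(mag, vel)[0, 0, 0] == pytest.approx(6.0)

    def test_vessel_brighter_than_static_tissue(self, scene16):
        mag = np.repeat(scene16.magnitude_map[None], scene16.n_frames, axis=0)
        pcmra = compute_pcmra(mag, scene16.velocity_field)
        vessel = scene16.vessel_masks["DAo"]
        # static voxel far from the vessels, same magnitude scale
        assert pcmra[vessel].mean() > pcmra[~(vessel)].mean()

    def test_invariant_under_frame_relabeling(self, scene16):
        mag = np.repeat(scene16.magnitude_map[None], scene16.n_frames, axis=0)
        perm = np.random.default_rng(6).permutation(scene16.n_frames)
        a = compute_pcmra(mag, scene16.velocity_field)
        b = compute_pcmra(mag[perm], scene16.velocity_field[perm])
        assert np.allclose(a, b)


class TestTuneCoreParams:
    def test_grid_evaluation_prefers_no_regularization_when_noiseless(
        self, static_scene16, full_ks16
    ):
        a = bin_cardiac(full_ks16, full_ks16.trigger_times, 1)
        dao = static_scene16.vessel_masks["DAo"]
        grid = [(0.0, np.inf), (2.55e-4, 1.125e-1)]
        best, table = tune_core_params(full_ks16, a, dao, grid, iters=4,
                                       phi0=static_scene16.phi0)
        assert {(r["lambda1"], r["lambda2"]) for r in table} == set(grid)
        assert best[0] == 0.0

    def test_single_point_grid_returned(self, static_scene16, full_ks16):
        a = bin_cardiac(full_ks16, full_ks16.trigger_times, 1)
        dao = static_scene16.vessel_masks["DAo"]
        best, table = tune_core_params(full_ks16, a, dao, [(1e-4, 0.1)], iters=2)
        assert best == (1e-4, 0.1)
        assert len(table) == 1

    def test_empty_grid_rejected(self, static_scene16, full_ks16):
        a = bin_cardiac(full_ks16, full_ks16.trigger_times, 1)
        with pytest.raises(ValueError):
            tune_core_params(full_ks16, a, static_scene16.vessel_masks["DAo"], [])
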
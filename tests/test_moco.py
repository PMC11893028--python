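"""Bulk-motion binning, registration, rejection, and k-space correction."""

import numpy as np
import pytest

from fetalflow import (
    MotionConfig,
    PhantomConfig,
    UnrecoverableAcquisitionError,
    apply_translations_to_kspace,
    bin_bulk_motion,
    bin_cardiac,
    generate_pseudo_spiral_trajectory,
    make_phantom,
    reconstruct_bins,
    register_bins,
    reject_bins,
    select_reference_bin,
    simulate_acquisition,
    simulate_motion,
    simulate_triggers,
)
from fetalflow._fft import cifftn
from fetalflow.moco import MotionBin
from fetalflow.phantom import segment_images


def _acquire(scene, duration, shifts=None, change_times=None, seed=0,
             noise_sd=0.0, r=1.0, tr=0.002, resp_mm=0.0):
    traj = generate_pseudo_spiral_trajectory(scene.matrix_size, r=r, tr=tr,
                                             duration=duration)
    trig = simulate_triggers(150, 0.0, duration + 1, seed=seed)
    motion = None
    if shifts is not None or resp_mm > 0:
        motion = simulate_motion(
            MotionConfig(
                resp_amplitude_mm=resp_mm,
                bulk_change_times=change_times if change_times is not None else [],
                bulk_shifts_mm=shifts if shifts is not None else np.zeros((0, 3)),
            ),
            duration, traj.time, seed=seed,
        )
    return simulate_acquisition(scene, traj, motion, trig, noise_sd=noise_sd,
                                seed=seed)


@pytest.fixture(scope="module")
def static16():
    return make_phantom(PhantomConfig(matrix_size=(16, 16, 16), n_coils=2,
                                      n_frames=1, waveform=np.array([1.0])))


@pytest.fixture(scope="module")
def static16_uniform_coil():
    """Single flat coil: no stationary-coil modulation of a moved fetus.

    At this 20 mm test FOV a few-mm shift sweeps the object across an
    appreciable fraction of a realistic coil profile, which biases
    registration precision checks that are about the registration itself.
    """
    return make_phantom(PhantomConfig(matrix_size=(16, 16, 16), n_coils=1,
                                      n_frames=1, waveform=np.array([1.0])))


class TestReconstructBins:
    def test_motionless_bins_are_identical(self, static16):
        # full sampling per bin: every bin reconstructs the same volume
        ks = _acquire(static16, duration=20.0)
        a = bin_bulk_motion(ks, 10.0)
        bins = reconstruct_bins(ks, a, iters=8)
        assert len(bins) == 2
        p0, p1 = bins[0].pcmra, bins[1].pcmra
        assert np.linalg.norm(p0 - p1) / np.linalg.norm(p0) < 1e-6

    def test_ninety_second_scan_gives_six_angiograms(self, static16):
        ks = _acquire(static16, duration=90.0, tr=0.02)
        a = bin_bulk_motion(ks, 15.0)
        bins = reconstruct_bins(ks, a, iters=2)
        assert len(bins) == 6
        assert all(b.pcmra is not None for b in bins)

    def test_translated_bin_matches_shifted_reference(self):
        # single coil with flat magnitude: the stationary-coil weighting that
        # otherwise modulates a moved fetus at this small test FOV drops out
        scene = make_phantom(PhantomConfig(matrix_size=(16, 16, 16), n_coils=1,
                                           n_frames=1, waveform=np.array([1.0])))
        shift_vox = np.array([4.0, 0.0, 0.0])
        ks = _acquire(scene, duration=20.0, change_times=[10.0],
                      shifts=[shift_vox * scene.voxel_size])
        a = bin_bulk_motion(ks, 10.0)
        # bins are fully sampled here: no need for the inter-bin TV coupling,
        # which would otherwise mix the two positions
        bins = reconstruct_bins(ks, a, lambda_tv=0.0, iters=8)
        ref = bins[0].pcmra
        moved = np.roll(ref, 4, axis=0)
        assert np.linalg.norm(bins[1].pcmra - moved) / np.linalg.norm(ref) < 0.05


class TestSelectReference:
    def test_identical_bins_tie_break_to_lowest_index(self):
        p = np.ones((4, 4, 4))
        bins = [MotionBin(i, 0, 1, np.arange(2), pcmra=p.copy()) for i in range(3)]
        assert select_reference_bin(bins) == 0

    def test_doubled_signal_selected(self):
        bins = [MotionBin(i, 0, 1, np.arange(2), pcmra=np.ones((4, 4, 4)))
                for i in range(3)]
        bins[1].pcmra = 2 * np.ones((4, 4, 4))
        assert select_reference_bin(bins) == 1

    def test_auto_matches_brute_force_argmax(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            bins = [MotionBin(i, 0, 1, np.arange(2),
                              pcmra=rng.uniform(size=(4, 4, 4)))
                    for i in range(5)]
            scores = [b.pcmra.sum() for b in bins]
            assert select_reference_bin(bins) == int(np.argmax(scores))

    def test_manual_index_honored_and_validated(self):
        bins = [MotionBin(i, 0, 1, np.arange(2), pcmra=np.ones((4, 4, 4)))
                for i in range(3)]
        assert select_reference_bin(bins, index=2) == 2
        with pytest.raises(IndexError):
            select_reference_bin(bins, index=5)


class TestRegisterBins:
    def test_identical_bin_registers_to_zero(self, static16):
        ks = _acquire(static16, duration=20.0)
        a = bin_bulk_motion(ks, 10.0)
        bins = reconstruct_bins(ks, a, iters=8)
        register_bins(bins, 0, np.asarray(static16.voxel_size))
        assert np.abs(bins[1].translation_mm).max() < 1e-3 * 1.25

    @pytest.mark.parametrize("shift_vox", [(2.0, 0.0, -1.0), (0.5, 0.0, 0.0)],
                             ids=["integer", "subvoxel"])
    def test_known_shift_recovered_within_quantum(self, static16_uniform_coil,
                                                  shift_vox):
        scene = static16_uniform_coil
        shift_vox = np.array(shift_vox)
        ks = _acquire(scene, duration=20.0, change_times=[10.0],
                      shifts=[shift_vox * scene.voxel_size])
        a = bin_bulk_motion(ks, 10.0)
        bins = reconstruct_bins(ks, a, lambda_tv=0.0, iters=8)
        register_bins(bins, 0, np.asarray(scene.voxel_size))
        err_vox = np.abs(bins[1].translation_mm / 1.25 - shift_vox)
        assert err_vox.max() <= 0.25  # the 4x sub-voxel quantum

    def test_degenerate_reference_rejected(self):
        bins = [MotionBin(0, 0, 1, np.arange(2), pcmra=np.zeros((4, 4, 4))),
                MotionBin(1, 1, 2, np.arange(2), pcmra=np.ones((4, 4, 4)))]
        with pytest.raises(ValueError):
            register_bins(bins, 0, np.ones(3))

    def test_all_zero_moving_image_flagged_not_raised(self):
        rng = np.random.default_rng(1)
        bins = [MotionBin(0, 0, 1, np.arange(2), pcmra=rng.uniform(size=(8, 8, 8))),
                MotionBin(1, 1, 2, np.arange(2), pcmra=np.zeros((8, 8, 8)))]
        register_bins(bins, 0, np.ones(3))
        assert bins[1].rejection_reason == "registration_failure"


class TestRejectBins:
    def _bins(self, translations, signals=None):
        bins = []
        for i, t in enumerate(translations):
            p = np.ones((4, 4, 4)) * (1.0 if signals is None else signals[i])
            b = MotionBin(i, i, i + 1, np.arange(2), pcmra=p,
                          translation_mm=np.asarray(t, float))
            bins.append(b)
        return bins

    def test_no_motion_no_rejections(self):
        bins = self._bins([(0, 0, 0), (0.1, 0, 0), (0, 0.2, 0)])
        reject_bins(bins, reference=0)
        assert all(b.accepted for b in bins)

    def test_large_shift_rejected_with_reason(self):
        bins = self._bins([(0, 0, 0), (25.0, 0, 0)])
        reject_bins(bins, max_shift_mm=10.0, reference=0)
        assert not bins[1].accepted
        assert bins[1].rejection_reason == "large_shift"

    def test_signal_loss_rejected(self):
        bins = self._bins([(0, 0, 0), (1.0, 0, 0)], signals=[1.0, 0.1])
        reject_bins(bins, min_signal_fraction=0.5, reference=0)
        assert not bins[1].accepted
        assert bins[1].rejection_reason == "signal_loss"

    def test_reference_never_rejected_and_overrides_apply(self):
        bins = self._bins([(0, 0, 0), (25.0, 0, 0), (1, 0, 0)])
        reject_bins(bins, reference=0, accept_overrides=[1],
                    reject_overrides=[2])
        assert bins[1].accepted and not bins[2].accepted

    def test_all_rejected_raises_unrecoverable(self):
        bins = self._bins([(0, 0, 0), (30.0, 0, 0)])
        for b in bins:  # every bin starved of data during reconstruction
            b.rejection_reason = "signal_loss"
            b.accepted = False
        with pytest.raises(UnrecoverableAcquisitionError):
            reject_bins(bins, max_shift_mm=10.0, reference=0)


class TestApplyTranslations:
    def test_zero_translation_is_identity_minus_rejections(self, static16):
        ks = _acquire(static16, duration=20.0)
        a = bin_bulk_motion(ks, 10.0)
        bins = reconstruct_bins(ks, a, iters=2)
        for b in bins:
            b.translation_mm = np.zeros(3)
            b.accepted = b.index == 0  # reject bin 1
        out = apply_translations_to_kspace(ks, bins)
        assert out.n_readouts == bins[0].readout_ids.size
        assert np.array_equal(out.samples, ks.samples[bins[0].readout_ids])

    def test_accounting_retained_plus_rejected_equals_total(self, static16):
        ks = _acquire(static16, duration=20.0)
        a = bin_bulk_motion(ks, 10.0)
        bins = reconstruct_bins(ks, a, iters=2)
        for b in bins:
            b.translation_mm = np.zeros(3)
            b.accepted = b.index == 0
        out = apply_translations_to_kspace(ks, bins)
        n_rejected = sum(b.readout_ids.size for b in bins if not b.accepted)
        assert out.n_readouts + n_rejected == ks.n_readouts

    def test_exact_correction_of_known_translation(self, static16):
        # simulated integer-voxel translation, corrected with the true value:
        # the motionless k-space is restored to machine precision
        shift_vox = np.array([3.0, -2.0, 1.0])
        ks_moved = _acquire(static16, duration=20.0, change_times=[10.0],
                            shifts=[shift_vox * static16.voxel_size])
        ks_still = _acquire(static16, duration=20.0)
        a = bin_bulk_motion(ks_moved, 10.0)
        bins = reconstruct_bins(ks_moved, a, iters=2)
        bins[0].translation_mm = np.zeros(3)
        bins[0].accepted = True
        bins[1].translation_mm = shift_vox * np.asarray(static16.voxel_size)
        bins[1].accepted = True
        out = apply_translations_to_kspace(ks_moved, bins)
        assert np.abs(out.samples - ks_still.samples).max() < 1e-10

    def test_corrected_full_sampling_recon_is_shifted_original(self, static16):
        # correcting with d moves the image content by -d exactly
        ks = _acquire(static16, duration=10.0)
        a = bin_bulk_motion(ks, 20.0)
        bins = reconstruct_bins(ks, a, iters=2)
        bins[0].translation_mm = np.array([-2.0, 0.0, 0.0]) * 1.25
        bins[0].accepted = True
        out = apply_translations_to_kspace(ks, bins)
        sel = out.segment == 0
        grid = np.zeros((16, 16, 16), complex)
        grid[:, out.ky[sel], out.kz[sel]] = out.samples[sel][:, :, 0].T
        img = cifftn(grid)
        ref = segment_images(static16, 0)[0] * static16.coil_sensitivities[0]
        assert np.abs(img - np.roll(ref, 2, axis=0)).max() < 1e-10

    def test_unassigned_readout_rejected(self, static16):
        ks = _acquire(static16, duration=10.0)
        bins = [MotionBin(0, 0, 5, np.arange(10), pcmra=np.ones((16,) * 3),
                          translation_mm=np.zeros(3), accepted=True)]
        with pytest.raises(ValueError):
            apply_translations_to_kspace(ks, bins)


class TestIdempotence:
    def test_registering_corrected_bins_yields_subvoxel_translations(
        self, static16
    ):
        shift_vox = np.array([2.0, 1.0, 0.0])
        ks = _acquire(static16, duration=20.0, change_times=[10.0],
                      shifts=[shift_vox * static16.voxel_size])
        a = bin_bulk_motion(ks, 10.0)
        bins = reconstruct_bins(ks, a, iters=8)
        register_bins(bins, 0, np.asarray(static16.voxel_size))
        for b in bins:
            b.accepted = True
        out = apply_translations_to_kspace(ks, bins)
        a2 = bin_bulk_motion(out, 10.0)
        bins2 = reconstruct_bins(out, a2, iters=8)
        register_bins(bins2, 0, np.asarray(static16.voxel_size))
        assert np.abs(bins2[1].translation_mm / 1.25).max() <= 0.25
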
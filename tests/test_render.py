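import numpy as np
import pytest

from octaquant import (AcquisitionSetting, EnFaceImage, PhantomParams,
                       generate_phantom, render_slab, signal_strength)


def test_unknown_slab_rejected(small_phantom, clean_acq):
    with pytest.raises(ValueError):
        render_slab(small_phantom, "ONL", clean_acq)


def test_noise_free_render_separates_flow_from_background(
        retina_phantom, clean_acq):
    """With no filter and no noise, every true-flow pixel outshines every
    background pixel."""
    img = render_slab(retina_phantom, "SCP", clean_acq)
    truth = retina_phantom.scp_truth_map
    assert img.pixels[truth].min() > img.pixels[~truth].max()


def test_mean_intensity_strictly_decreasing_in_od(small_phantom):
    for slab in ("SCP", "DCP", "CC"):
        means = []
        for od in (0.0, 0.3, 0.6):
            acq = AcquisitionSetting.for_device("SD", ndf_od=od, seed=3)
            means.append(render_slab(small_phantom, slab, acq).pixels.mean())
        assert means[0] > means[1] > means[2], slab


def test_render_is_deterministic(small_phantom):
    acq = AcquisitionSetting.for_device("SS", ndf_od=0.3, seed=11)
    a = render_slab(small_phantom, "DCP", acq, repeat=1)
    b = render_slab(small_phantom, "DCP", acq, repeat=1)
    assert np.array_equal(a.pixels, b.pixels)


def test_repeats_differ_only_in_stochastic_terms(small_phantom):
    """Noise-free repeats share the zero background; speckle differs on flow."""
    acq = AcquisitionSetting.for_device("SD", ndf_od=0.0, seed=4,
                                        noise_floor=0.0)
    r0 = render_slab(small_phantom, "SCP", acq, repeat=0).pixels
    r1 = render_slab(small_phantom, "SCP", acq, repeat=1).pixels
    truth = small_phantom.scp_truth_map
    assert np.array_equal(r0[~truth], r1[~truth])      # background identical
    assert not np.array_equal(r0[truth], r1[truth])    # speckle redrawn


def test_dcp_projection_switch(small_phantom, clean_acq):
    with_proj = render_slab(small_phantom, "DCP", clean_acq,
                            projection_removal=False).pixels
    without = render_slab(small_phantom, "DCP", clean_acq,
                          projection_removal=True).pixels
    vessels = small_phantom.large_vessel_map & ~small_phantom.dcp_capillary_map
    assert with_proj[vessels].mean() > without[vessels].mean()


def test_enface_image_validation():
    acq = AcquisitionSetting()
    with pytest.raises(ValueError):
        EnFaceImage(np.zeros((32, 32)), 6000 / 32, "SCP", acq)  # side < 64
    with pytest.raises(ValueError):
        EnFaceImage(np.zeros((64, 64)), 10.0, "SCP", acq)  # pitch mismatch
    with pytest.raises(ValueError):
        EnFaceImage(np.full((64, 64), 2.0), 6000 / 64, "SCP", acq)


class TestSignalStrength:
    def test_noise_free_unattenuated_scores_ten(self, retina_phantom,
                                                clean_acq):
        img = render_slab(retina_phantom, "SCP", clean_acq)
        assert signal_strength(img) == 10.0

    def test_pure_noise_scores_zero(self, small_phantom):
        acq = AcquisitionSetting.for_device("SD", ndf_od=6.0, seed=2,
                                            noise_floor=0.02)
        img = render_slab(small_phantom, "SCP", acq)
        assert signal_strength(img) == 0.0

    def test_monotone_in_attenuation(self):
        for seed in (1, 2, 3):
            ph = generate_phantom(seed, PhantomParams(side=64))
            scores = []
            for od in (0.0, 0.3, 0.6):
                acq = AcquisitionSetting.for_device("SD", ndf_od=od, seed=8)
                scores.append(signal_strength(render_slab(ph, "SCP", acq)))
            assert scores[0] >= scores[1] >= scores[2]

    def test_sd_device_loses_more_signal_than_ss(self, small_phantom):
        for od in (0.3, 0.6):
            sd = signal_strength(render_slab(
                small_phantom, "SCP",
                AcquisitionSetting.for_device("SD", ndf_od=od, seed=8)))
            ss = signal_strength(render_slab(
                small_phantom, "SCP",
                AcquisitionSetting.for_device("SS", ndf_od=od, seed=8)))
            assert sd < ss

    def test_invariant_to_sub_quantisation_offset(self, small_phantom):
        acq = AcquisitionSetting.for_device("SD", ndf_od=0.3, seed=8)
        img = render_slab(small_phantom, "SCP", acq)
        shifted = EnFaceImage(np.clip(img.pixels + 1 / 512, 0, 1),
                              img.pixel_pitch_um, img.slab, acq)
        base = signal_strength(img)
        if img.pixels.max() <= 1 - 1 / 512:  # offset must not clip
            assert signal_strength(shifted) == pytest.approx(base, abs=1e-6)
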
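import math

import numpy as np
import pytest

from condensate.exceptions import GeometryError
from condensate.frap import exponential_recovery
from condensate.io_formats import CircleRoi
from condensate import synth_data as sd

from conftest import grid_centers, tangent_parents


class TestRenderScene:
    def test_droplet_brighter_than_background(self, meta64):
        drop = sd.DropletSpec((31.5, 31.5), 2.0, 150.0)
        stack = sd.render_scene(meta64, [drop], background=100.0)
        mask = CircleRoi((31.5, 31.5), 2.0).mask((64, 64), 0.1)
        assert stack.data[0, 0][mask].mean() > 100.0

    def test_zero_droplets_is_flat_background(self, meta64):
        stack = sd.render_scene(meta64, [], background=100.0)
        np.testing.assert_array_equal(stack.data, 100.0)

    def test_droplet_outside_frame_names_index(self, meta64):
        drops = [
            sd.DropletSpec((31.5, 31.5), 2.0, 150.0),
            sd.DropletSpec((62.0, 31.5), 2.0, 150.0),  # disk exits the frame
        ]
        with pytest.raises(GeometryError, match="droplet 1"):
            sd.render_scene(meta64, drops)


class TestFrapSeries:
    def test_noiseless_trace_matches_closed_form_everywhere(self, frap_setup):
        meta, droplet, bleach, _bg = frap_setup
        truth = sd.FrapTruth(1.841, 66.18, 20.0, bleach_frame=5, bleach_roi=bleach)
        stack, _ = sd.simulate_frap_series(meta, droplet, truth, 60, background=20.0)
        mask = bleach.mask((64, 64), meta.pixel_size_um)
        signal = stack.data[:, 0][:, mask].mean(axis=1) - 20.0
        pct = signal / signal[:5].mean() * 100.0
        t = stack.times_s(origin_frame=5)
        expected = np.where(
            t >= 0, exponential_recovery(np.clip(t, 0, None), 1.841, 66.18, 20.0), 100.0
        )
        assert np.max(np.abs(pct - expected) / expected) < 1e-3  # < 0.1% everywhere

    def test_intensity_at_bleach_frame_is_i0(self, frap_setup):
        meta, droplet, bleach, _bg = frap_setup
        truth = sd.FrapTruth(0.7, 80.0, 25.0, bleach_frame=3, bleach_roi=bleach)
        stack, _ = sd.simulate_frap_series(meta, droplet, truth, 10, background=0.0)
        mask = bleach.mask((64, 64), meta.pixel_size_um)
        pre = stack.data[:3, 0][:, mask].mean()
        at_bleach = stack.data[3, 0][mask].mean()
        assert at_bleach / pre * 100.0 == pytest.approx(25.0, rel=1e-9)

    def test_trace_reaches_plateau_at_ten_tau(self, frap_setup):
        meta, droplet, bleach, _bg = frap_setup
        # tau = 0.5 s, dt = 0.2 s -> frame bleach+25 sits at t = 10*tau
        truth = sd.FrapTruth(0.5, 66.18, 10.0, bleach_frame=2, bleach_roi=bleach)
        stack, _ = sd.simulate_frap_series(meta, droplet, truth, 30, background=0.0)
        mask = bleach.mask((64, 64), meta.pixel_size_um)
        pre = stack.data[:2, 0][:, mask].mean()
        pct = stack.data[27, 0][mask].mean() / pre * 100.0
        assert abs(pct - 66.18) < 0.01

    def test_invalid_truth_rejected(self, frap_setup):
        _meta, _droplet, bleach, _bg = frap_setup
        with pytest.raises(ValueError, match="i0"):
            sd.FrapTruth(1.0, 50.0, 60.0, bleach_frame=2, bleach_roi=bleach)

    def test_roi_must_overlap_droplet(self, frap_setup):
        meta, droplet, _bleach, _bg = frap_setup
        far = CircleRoi((5.0, 5.0), 0.5)
        truth = sd.FrapTruth(1.0, 60.0, 10.0, bleach_frame=2, bleach_roi=far)
        with pytest.raises(GeometryError, match="overlap"):
            sd.simulate_frap_series(meta, droplet, truth, 10)


class TestFusionSeries:
    def test_truth_tau_from_area_conserving_diameter(self, meta64):
        # equal 2-um parents: d_merged = 2*sqrt(2) um, tau_f = K * d_merged
        parents = tangent_parents(2.0)
        _, truth = sd.simulate_fusion_series(meta64, parents, 0.65, 1.6, 20, contact_frame=4)
        assert truth.final_diameter_um == pytest.approx(2 * math.sqrt(2), rel=1e-12)
        assert truth.tau_f_s == pytest.approx(0.65 * 2 * math.sqrt(2), rel=1e-12)

    def test_area_conserved_by_rendered_masks(self, meta64):
        parents = tangent_parents(2.4)
        stack, truth = sd.simulate_fusion_series(
            meta64, parents, 0.65, 1.6, 20, contact_frame=4, background=20.0, sigma_psf_px=0.5
        )
        level = 20.0 + 50.0  # half-max of peak 100 over background 20
        pre = (stack.data[0, 0] >= level).sum()
        post = (stack.data[4, 0] >= level).sum()
        assert abs(post - pre) / pre < 0.01

    def test_ar_unity_stays_circular(self, meta64):
        from skimage.measure import label, regionprops

        parents = tangent_parents(2.0)
        stack, _ = sd.simulate_fusion_series(meta64, parents, 0.65, 1.0, 12, contact_frame=4)
        for k in (4, 8, 11):
            mask = stack.data[k, 0] >= 20.0 + 50.0
            props = regionprops(label(mask))[0]
            assert props.axis_major_length / props.axis_minor_length == pytest.approx(1.0, abs=0.03)

    def test_ar_closed_form_at_tau(self, meta64):
        # AR(tau_f) - 1 = (ar0 - 1)/e by construction
        parents = tangent_parents(2.0)
        _, truth = sd.simulate_fusion_series(meta64, parents, 0.65, 1.8, 20, contact_frame=4)
        ar_at_tau = 1 + (truth.ar0 - 1) * math.exp(-1.0)
        assert ar_at_tau == pytest.approx(1 + 0.8 / math.e, rel=1e-12)

    def test_overlapping_parents_rejected(self, meta64):
        p1 = sd.DropletSpec((28.0, 31.5), 2.0, 100.0)
        p2 = sd.DropletSpec((34.0, 31.5), 2.0, 100.0)  # centers 6 px apart, radii 10 px
        with pytest.raises(GeometryError, match="overlap"):
            sd.simulate_fusion_series(meta64, (p1, p2), 0.65, 1.6, 10)


class TestTwoChannelScene:
    def test_gain_one_zero_baseline_channels_identical(self, meta64_2ch):
        drop = sd.DropletSpec((48.0, 48.0), 1.5, 150.0)
        stack, _ = sd.simulate_two_channel_scene(
            meta64_2ch, [drop], [True], gain=1.0, baselines=(0.0, 0.0), nucleolus=False
        )
        np.testing.assert_allclose(stack.data[0, 0], stack.data[0, 1], atol=1e-12)

    def test_non_colocalized_droplet_flat_in_partner(self, meta64_2ch):
        drop = sd.DropletSpec((48.0, 48.0), 1.5, 150.0)
        stack, _ = sd.simulate_two_channel_scene(
            meta64_2ch, [drop], [False], gain=2.0, baselines=(50.0, 30.0), nucleolus=False
        )
        mask = CircleRoi((48.0, 48.0), 1.5).mask((96, 96), 0.1)
        ring = CircleRoi((48.0, 48.0), 4.5).mask((96, 96), 0.1) & ~mask
        enrichment = stack.data[0, 1][mask].mean() / stack.data[0, 1][ring].mean()
        assert enrichment == pytest.approx(1.0, abs=0.02)

    def test_flags_returned_as_truth(self, meta64_2ch):
        drops = [sd.DropletSpec((30.0, 48.0), 1.2, 150.0), sd.DropletSpec((60.0, 48.0), 1.2, 150.0)]
        _, flags = sd.simulate_two_channel_scene(meta64_2ch, drops, [True, False])
        assert flags == (True, False)

    def test_nonpositive_gain_rejected(self, meta64_2ch):
        drop = sd.DropletSpec((48.0, 48.0), 1.5, 150.0)
        with pytest.raises(ValueError, match="gain"):
            sd.simulate_two_channel_scene(meta64_2ch, [drop], [True], gain=0.0)


class TestPerturbationSeries:
    def test_exact_recoverable_count(self, meta64):
        drops = [sd.DropletSpec(c, 0.8, 100.0) for c in grid_centers(10, 12.0, 8.0)]
        _, truth = sd.simulate_perturbation_series(meta64, drops, recover_fraction=0.6)
        assert sum(truth.recover_flags) == 6

    def test_fast_dispersal_limit(self, meta64):
        drop = sd.DropletSpec((31.5, 31.5), 1.5, 200.0)
        stack, truth = sd.simulate_perturbation_series(
            meta64, [drop], dispersal_tau_s=0.01, treat_frame=5, washout_frame=60,
            recover_fraction=0.0, n_frames=70, baseline=50.0,
        )
        # one frame after treatment the droplet signal is e^-20 of itself
        center = stack.data[6, 0][31, 31]
        assert center == pytest.approx(50.0, rel=1e-6)

    def test_no_recovery_when_fraction_zero(self, meta64):
        drops = [sd.DropletSpec(c, 0.8, 200.0) for c in grid_centers(4, 16.0, 12.0, per_row=2)]
        stack, truth = sd.simulate_perturbation_series(
            meta64, drops, recover_fraction=0.0, baseline=50.0
        )
        post = stack.data[truth.washout_frame + 20:, 0]
        assert post.max() < 50.0 * 1.05

    def test_washout_must_follow_treatment(self, meta64):
        drop = sd.DropletSpec((31.5, 31.5), 1.5, 200.0)
        with pytest.raises(ValueError, match="washout"):
            sd.simulate_perturbation_series(meta64, [drop], treat_frame=30, washout_frame=30)


class TestScreenCounts:
    def test_enriched_genes_have_higher_output_ratio(self):
        table, truth = sd.simulate_screen_counts(200, 4, 300, n_enriched=8, seed=3)
        norm_out = table["output"] + 1
        norm_in = table["input2"] + 1
        ratio = norm_out / norm_in
        enriched = table["gene"].isin(truth.enriched_genes)
        assert ratio[enriched].mean() > 2 * ratio[~enriched].mean()

    def test_zero_dispersion_counts_equal_rounded_means(self):
        table, truth = sd.simulate_screen_counts(50, 3, 400, n_enriched=5, dispersion=0.0, seed=1)
        enriched = table["gene"].isin(truth.enriched_genes)
        ratio = table.loc[table["input1"] > 0, "output"] / table.loc[table["input1"] > 0, "input1"]
        # deterministic means: non-enriched ratios ~1, enriched ~effect_fold
        assert ratio[~enriched[table["input1"] > 0]].median() == pytest.approx(1.0, abs=0.05)

    def test_column_sums_near_depth_times_n(self):
        table, _ = sd.simulate_screen_counts(500, 4, 500, n_enriched=0, seed=2)
        for col in ("input1", "input2", "output"):
            assert table[col].sum() == pytest.approx(500 * 2000, rel=0.1)

    def test_invalid_sgrnas_per_gene(self):
        with pytest.raises(ValueError, match="sgrnas_per_gene"):
            sd.simulate_screen_counts(10, 0, 100)


class TestSiteTable:
    def test_planted_class_counts(self):
        _, truth = sd.simulate_site_table(100, (0.3, 0.4, 0.3), seed=4)
        labels = list(truth.class_labels)
        assert (labels.count("up"), labels.count("permanent"), labels.count("down")) == (30, 40, 30)

    def test_intervals_half_open(self):
        table, _ = sd.simulate_site_table(20, seed=0)
        assert (table["start"] < table["end"]).all()
        assert table["start"].min() == 0

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sd.simulate_site_table(10, (0.5, 0.4, 0.3))


def _simulator_outputs(name, meta, seed):
    """Run one simulator with noise and return its array/table output."""
    drop = sd.DropletSpec((31.5, 31.5), 2.0, 150.0)
    if name == "render_scene":
        return sd.render_scene(meta, [drop], noise=("gaussian", 2.0), seed=seed).data
    if name == "frap":
        bleach = CircleRoi((31.5, 31.5), 1.0)
        truth = sd.FrapTruth(1.0, 70.0, 20.0, bleach_frame=2, bleach_roi=bleach)
        return sd.simulate_frap_series(
            meta, drop, truth, 10, noise=("gaussian", 2.0), seed=seed
        )[0].data
    if name == "fusion":
        return sd.simulate_fusion_series(
            meta, tangent_parents(2.0), 0.65, 1.6, 10, contact_frame=3,
            noise=("gaussian", 2.0), seed=seed,
        )[0].data
    if name == "perturbation":
        stack, truth = sd.simulate_perturbation_series(
            meta, [drop], treat_frame=2, washout_frame=5, n_frames=10,
            noise=("gaussian", 2.0), seed=seed,
        )
        return stack.data
    if name == "screen":
        return sd.simulate_screen_counts(50, 3, 200, n_enriched=5, seed=seed)[0]
    if name == "sites":
        return sd.simulate_site_table(40, factor_noise_sd=0.5, seed=seed)[0]
    raise AssertionError(name)


@pytest.mark.parametrize(
    "name", ["render_scene", "frap", "fusion", "perturbation", "screen", "sites"]
)
def test_seeded_determinism_bit_identical(name, meta64):
    a = _simulator_outputs(name, meta64, 123)
    b = _simulator_outputs(name, meta64, 123)
    c = _simulator_outputs(name, meta64, 124)
    if isinstance(a, np.ndarray):
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
    else:
        assert a.equals(b)
        assert not a.equals(c)
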
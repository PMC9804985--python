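"""Generator: geometry, rendering, cohorts — all against exact ground truth."""

import numpy as np
import pytest

from isletquant.experiments import sim_params
from isletquant.synthetic import (
    CohortSpec,
    GeneratorParams,
    GroupSpec,
    PlacementError,
    compose_ihc_rgb,
    generate_cohort,
    iter_cohort,
    render_if_image,
    render_ihc_tile,
    sample_islet_geometry,
    stain_amount_maps,
)
from isletquant.segmentation import deconvolve_ihc
from isletquant.types import StainMatrix

from conftest import make_field


class TestIsletGeometry:
    def test_zero_target_gives_empty_islet_map(self):
        p = sim_params(islet_area_fraction_target=0.0)
        gt = sample_islet_geometry(p, np.random.default_rng(0))
        assert not gt.islet_label_map.any()
        assert gt.true_islet_fraction == 0.0

    def test_same_seed_reproduces_ground_truth_pixel_for_pixel(self):
        p = sim_params()
        a = sample_islet_geometry(p, np.random.default_rng(5))
        b = sample_islet_geometry(p, np.random.default_rng(5))
        assert np.array_equal(a.islet_label_map, b.islet_label_map)
        assert np.array_equal(a.beta_mask, b.beta_mask)
        assert np.array_equal(a.tissue_mask, b.tissue_mask)

    def test_full_frame_target_fraction_within_ten_percent(self):
        # 2048 px frame at 0.25 um/px, median islet radius 40 um, target 1%
        p = GeneratorParams(islet_area_fraction_target=0.01,
                            islet_radius_lognormal=(40.0, 0.25))
        gt = sample_islet_geometry(p, np.random.default_rng(3))
        assert 0.9 <= gt.true_islet_fraction <= 1.1

    @pytest.mark.parametrize("seed", range(8))
    def test_mask_nesting_and_consistency(self, seed):
        rng = np.random.default_rng(seed)
        p = sim_params(
            islet_area_fraction_target=float(rng.uniform(0.001, 0.02)),
            beta_fraction=float(rng.uniform(0.2, 0.8)),
            tissue_frame_fraction=float(rng.uniform(0.6, 0.85)),
        )
        gt = sample_islet_geometry(p, rng)
        gt.validate()  # nesting beta <= islet <= tissue + count consistency
        assert gt.tissue_mask.mean() >= 0.55

    def test_beta_fraction_hit_within_two_points(self):
        for mode in ("blob", "bernoulli"):
            p = sim_params(beta_fraction=0.47, beta_mode=mode)
            gt = sample_islet_geometry(p, np.random.default_rng(11))
            assert gt.true_beta_fraction_of_islet == pytest.approx(47.0, abs=2.0)

    def test_beta_blob_is_connected_per_islet(self):
        from scipy import ndimage as ndi

        p = sim_params(islet_area_fraction_target=0.01, beta_fraction=0.5)
        gt = sample_islet_geometry(p, np.random.default_rng(2))
        for lab in np.unique(gt.islet_label_map)[1:]:
            blob = gt.beta_mask & (gt.islet_label_map == lab)
            if blob.any():
                _, n = ndi.label(blob)
                assert n == 1

    def test_unreachable_target_raises_placement_error(self):
        # 45% coverage with many small separated islets exceeds the packing
        # limit imposed by the inter-islet margin, whatever the seed
        p = sim_params(image_shape=(128, 128), pixel_size=1.0,
                       islet_area_fraction_target=0.45,
                       islet_radius_lognormal=(3.0, 0.01),
                       islet_fraction_animal_sd=0.0)
        with pytest.raises(PlacementError) as err:
            sample_islet_geometry(p, np.random.default_rng(0))
        assert err.value.requested == 0.45
        assert 0 < err.value.achieved < 0.45
        assert "achieved" in str(err.value)


class TestIfRendering:
    def test_all_zero_intensities_render_zero_channels(self):
        p = sim_params(insulin_intensity=0, synaptophysin_intensity=0,
                       background_level=0, glass_level=0, dapi_intensity=0,
                       noise_model=(0.0, 0.0))
        gt = sample_islet_geometry(p, np.random.default_rng(0))
        img = render_if_image(gt, p, np.random.default_rng(0))
        for chan in img.channels.values():
            assert not chan.any()

    def test_noise_free_insulin_mean_is_exact(self, noise_free_field,
                                              noise_free_params):
        gt, img = noise_free_field
        ins = img.channels["insulin"]
        assert ins[gt.beta_mask].mean() == noise_free_params.insulin_intensity
        syn = img.channels["synaptophysin"]
        assert syn[gt.islet_label_map > 0].mean() == \
            noise_free_params.synaptophysin_intensity

    def test_doubling_insulin_intensity_doubles_islet_sum(self):
        from dataclasses import replace

        p = sim_params(noise_model=(0.0, 0.0), insulin_intensity=100.0,
                       background_level=0.0)
        gt = sample_islet_geometry(p, np.random.default_rng(4))
        islet = gt.islet_label_map > 0
        base = render_if_image(gt, p, np.random.default_rng(4))
        doubled = render_if_image(gt, replace(p, insulin_intensity=200.0),
                                  np.random.default_rng(4))
        s1 = base.channels["insulin"][islet].sum()
        s2 = doubled.channels["insulin"][islet].sum()
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_noise_is_clipped_to_bit_depth(self):
        p = sim_params(insulin_intensity=254.0, noise_model=(1.0, 30.0))
        gt = sample_islet_geometry(p, np.random.default_rng(1))
        img = render_if_image(gt, p, np.random.default_rng(1))
        for chan in img.channels.values():
            assert chan.min() >= 0 and chan.max() <= 255


class TestIhcRendering:
    def test_zero_od_everywhere_renders_pure_white(self):
        stains = StainMatrix.default()
        shape = (16, 16)
        amounts = {n: np.zeros(shape) for n in stains.names}
        rgb = compose_ihc_rgb(amounts, stains)
        assert np.all(rgb == 255.0)

    def test_round_trip_recovers_od_exactly(self):
        p = sim_params(ihc_od_noise_sd=0.0)
        gt = sample_islet_geometry(p, np.random.default_rng(2))
        stains = StainMatrix.default()
        amounts = stain_amount_maps(gt, p, np.random.default_rng(2))
        recovered = deconvolve_ihc(compose_ihc_rgb(amounts, stains), stains)
        for name in stains.names:
            assert np.abs(recovered[name] - amounts[name]).max() <= 1e-6

    def test_same_seed_renders_identical_tile(self):
        p = sim_params()
        gt = sample_islet_geometry(p, np.random.default_rng(6))
        a = render_ihc_tile(gt, p, rng=np.random.default_rng(9))
        b = render_ihc_tile(gt, p, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_stain_matrix_validation(self):
        with pytest.raises(ValueError, match="unit-norm"):
            StainMatrix(np.eye(3) * 2.0)
        with pytest.raises(ValueError, match="invertible"):
            StainMatrix.from_rows((1, 0, 0), (1, 1e-9, 0), (0, 0, 1))


class TestCohorts:
    @staticmethod
    def small_spec(master_seed=7, images_per_animal=3):
        return CohortSpec(
            groups=[GroupSpec("non_diabetic", 2, is_control=True),
                    GroupSpec("diabetic", 2,
                              overrides={"islet_area_fraction_target": 0.003})],
            images_per_animal=images_per_animal,
            base_params=sim_params(),
            master_seed=master_seed,
        )

    def test_manifest_has_one_row_per_image(self, tmp_path):
        manifest = generate_cohort(self.small_spec(), tmp_path / "c")
        assert len(manifest) == 2 * 2 * 3
        assert set(manifest["group"]) == {"non_diabetic", "diabetic"}

    def test_ground_truth_csv_is_byte_identical_across_reruns(self, tmp_path):
        generate_cohort(self.small_spec(), tmp_path / "a")
        generate_cohort(self.small_spec(), tmp_path / "b")
        assert (tmp_path / "a/ground_truth.csv").read_bytes() == \
            (tmp_path / "b/ground_truth.csv").read_bytes()

    def test_control_group_mean_fraction_near_target(self):
        # 25 control animals at target 0.8% with the default between-animal
        # spread (log10 sd 0.25): the group mean of the true per-animal
        # fractions stays near the target
        spec = CohortSpec(
            groups=[GroupSpec("ctrl", 25, is_control=True),
                    GroupSpec("other", 2)],
            images_per_animal=1,
            base_params=sim_params(islet_area_fraction_target=0.008),
            master_seed=12345,
        )
        fractions = [item.ground_truth.true_islet_fraction
                     for item in iter_cohort(spec) if item.group == "ctrl"]
        assert len(fractions) == 25
        assert 0.6 <= np.mean(fractions) <= 1.0

    def test_adding_a_group_does_not_perturb_existing_animals(self):
        spec = self.small_spec(images_per_animal=1)
        extra = CohortSpec(
            groups=spec.groups + [GroupSpec("extra", 2)],
            images_per_animal=1, base_params=spec.base_params,
            master_seed=spec.master_seed)
        before = {i.image_id: i.ground_truth.true_islet_fraction
                  for i in iter_cohort(spec)}
        after = {i.image_id: i.ground_truth.true_islet_fraction
                 for i in iter_cohort(extra) if not i.group == "extra"}
        assert before == after

    def test_cohort_spec_validation(self):
        with pytest.raises(ValueError, match="control"):
            CohortSpec(groups=[GroupSpec("a", 2), GroupSpec("b", 2)])
        with pytest.raises(ValueError, match="animals"):
            CohortSpec(groups=[GroupSpec("a", 1, is_control=True),
                               GroupSpec("b", 2)])


def test_render_requires_matching_geometry():
    p = sim_params()
    gt, _ = make_field(p)
    other = sim_params(image_shape=(64, 64))
    with pytest.raises(ValueError, match="geometry"):
        render_if_image(gt, other, np.random.default_rng(0))
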
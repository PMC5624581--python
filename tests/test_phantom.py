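"""Phantom generator: rendering, coverage targeting, artifacts, cohort draws."""

import numpy as np
import pandas as pd
import pytest

from uvcover import (
    CohortModel,
    CoverageScenario,
    CoverageTargetError,
    PhantomSpec,
    add_artifacts,
    apply_coverage,
    correlate,
    derive_regions,
    draw_cohort_fractions,
    generate_cohort,
    generate_phantom,
)
from uvcover.phantom import region_masks


@pytest.fixture()
def covered_letterbox(clean_phantom):
    scenario = CoverageScenario(
        applied_fraction={"letterbox": 0.75, "rest": 1.0,
                          "canthus_left": 1.0, "canthus_right": 1.0}
    )
    return apply_coverage(clean_phantom, scenario, seed=3), scenario


class TestGeneratePhantom:
    def test_noise_free_phantom_has_exact_levels(self, clean_phantom):
        spec = clean_phantom.spec
        face = spec.face_mask()
        assert np.all(clean_phantom.image[face] == 200)
        assert np.all(clean_phantom.image[~face] == 20)

    def test_truth_mask_equals_ellipse_scan_oracle(self, clean_phantom):
        """Brute-force per-pixel ellipse inequality scan."""
        spec = clean_phantom.spec
        cx, cy = spec.face_center
        a, b = spec.face_axes
        count = sum(
            ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
            for y in range(0, spec.image_height, 1)
            for x in range(0, spec.image_width, 1)
        )
        assert clean_phantom.truth_mask.sum() == count

    def test_same_spec_same_seed_reproduces_bytes(self):
        spec = PhantomSpec()
        b1, b2 = generate_phantom(spec, 7), generate_phantom(spec, 7)
        np.testing.assert_array_equal(b1.image, b2.image)
        b3 = generate_phantom(spec, 8)
        assert np.any(b3.image != b1.image)

    def test_ellipse_exceeding_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            PhantomSpec(face_axes=(200.0, 120.0))


class TestApplyCoverage:
    def test_full_application_leaves_no_missed_skin(self, clean_phantom):
        scenario = CoverageScenario(
            applied_fraction={r: 1.0 for r in
                              ("letterbox", "rest", "canthus_left", "canthus_right")}
        )
        out = apply_coverage(clean_phantom, scenario, seed=2)
        assert not out.truth_mask.any()

    def test_letterbox_quarter_missed_hits_tolerance(self, covered_letterbox):
        """Pixel-count oracle: truth pixels in the letterbox over its area."""
        out, _ = covered_letterbox
        regions = derive_regions(out.landmarks, out.spec.shape)
        rows, cols = regions.eyelid_letterbox.slices()
        frac = out.truth_mask[rows, cols].sum() / regions.eyelid_letterbox.area
        assert frac == pytest.approx(0.25, abs=0.005)

    def test_zero_application_is_identity(self, clean_phantom):
        out = apply_coverage(clean_phantom, CoverageScenario(applied_fraction={}), 4)
        np.testing.assert_array_equal(out.image, clean_phantom.image)
        np.testing.assert_array_equal(out.truth_mask, clean_phantom.truth_mask)

    def test_raising_applied_fraction_never_raises_missed(self, clean_phantom):
        prev = None
        for a in (0.2, 0.5, 0.8, 1.0):
            out = apply_coverage(
                clean_phantom,
                CoverageScenario(applied_fraction={"letterbox": a, "rest": a}),
                seed=5,
            )
            missed = out.metadata["truth_pct_face"]
            if prev is not None:
                assert missed <= prev + 1e-9
            prev = missed

    def test_unreachable_target_fails_loudly(self, clean_phantom):
        # rest-of-face rectangle includes background corners, so a missed
        # fraction near 1 of the rectangle exceeds the available skin
        with pytest.raises(CoverageTargetError):
            apply_coverage(
                clean_phantom, CoverageScenario(applied_fraction={"rest": 0.02}), 6
            )

    def test_partition_of_face_pixels(self, covered_letterbox):
        """Missed + covered + background partition every pixel exactly."""
        out, scenario = covered_letterbox
        spec = out.spec
        face = spec.face_mask()
        missed = out.truth_mask
        # noise-free phantom: covered pixels are exactly the sunscreen level
        covered = out.image == scenario.sunscreen_intensity
        assert not np.any(missed & ~face)
        assert not np.any(covered & missed)
        np.testing.assert_array_equal(missed | covered, face)


class TestAddArtifacts:
    def test_zero_counts_is_no_op(self, covered_letterbox):
        out, _ = covered_letterbox
        same = add_artifacts(out, CoverageScenario(applied_fraction={}), 8)
        np.testing.assert_array_equal(same.image, out.image)

    def test_glare_disc_area_matches_pixel_scan(self, clean_phantom):
        full = apply_coverage(
            clean_phantom,
            CoverageScenario(applied_fraction={r: 1.0 for r in
                             ("letterbox", "rest", "canthus_left", "canthus_right")}),
            9,
        )
        scenario = CoverageScenario(applied_fraction={}, glare_count=1,
                                    glare_radius=(4, 4))
        out = add_artifacts(full, scenario, seed=10)
        (kind, cx, cy, r), = out.metadata["artifacts"]
        assert kind == "glare" and r == 4
        changed = np.argwhere(out.image != full.image)
        skin = clean_phantom.spec.face_mask()
        expected = sum(
            (x - cx) ** 2 + (y - cy) ** 2 <= r * r and skin[y, x]
            for y in range(cy - r, cy + r + 1)
            for x in range(cx - r, cx + r + 1)
        )
        assert len(changed) == expected
        assert np.all(out.image[changed[:, 0], changed[:, 1]] == scenario.glare_intensity)

    def test_glare_and_damage_leave_truth_untouched(self, covered_letterbox):
        out, _ = covered_letterbox
        scenario = CoverageScenario(applied_fraction={}, glare_count=3, damage_count=4)
        art = add_artifacts(out, scenario, seed=11)
        np.testing.assert_array_equal(art.truth_mask, out.truth_mask)


class TestCohortModel:
    def test_drawn_medians_recover_targets(self):
        df = draw_cohort_fractions(CohortModel(seed=13))
        v1 = df[df.visit == 1]
        assert v1.target_missed_letterbox.median() == pytest.approx(0.14, abs=0.02)
        assert v1.target_missed_rest.median() == pytest.approx(0.07, abs=0.02)

    def test_no_improvement_duplicates_visits(self):
        model = CohortModel(
            visit2_improvement_letterbox=0.0, visit2_improvement_rest=0.0, seed=14
        )
        df = draw_cohort_fractions(model)
        wide = df.pivot_table(index="participant_id", columns="visit",
                              values=["target_missed_letterbox", "target_missed_rest"])
        for col in ("target_missed_letterbox", "target_missed_rest"):
            np.testing.assert_allclose(wide[col][1], wide[col][2])

    def test_skill_correlation_band_over_seeds(self):
        """Requested Spearman 0.84 lands in [0.7, 0.95] across seeded cohorts."""
        rhos = []
        for seed in range(10):
            df = draw_cohort_fractions(CohortModel(seed=seed))
            v1 = df[df.visit == 1]
            rhos.append(
                correlate(v1.target_missed_letterbox, v1.target_missed_rest).statistic
            )
        assert all(0.7 <= r <= 0.95 for r in rhos)

    def test_rendered_cohort_matches_drawn_targets(self, cohort_bundles):
        bundles, table = cohort_bundles
        assert len(bundles) == 2 * 57
        err = (table.truth_pct_letterbox / 100 - table.target_missed_letterbox).abs()
        assert err.max() <= 0.02  # canthal contribution can exceed tiny targets
        assert (table.truth_pct_face <= 100).all()

    def test_cohort_generation_is_deterministic(self):
        model = CohortModel(n_participants=3, seed=15)
        b1, t1 = generate_cohort(model)
        b2, t2 = generate_cohort(model)
        pd.testing.assert_frame_equal(t1, t2)
        for x, y in zip(b1, b2):
            np.testing.assert_array_equal(x.image, y.image)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortModel(n_participants=1)
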
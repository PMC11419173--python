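"""Cohort sampling, tissue synthesis and Beer-Lambert rendering."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import stainshift as ss
from stainshift.synthetic import (
    CYTO_H_BASE,
    StainProfile,
    TissuePhenotype,
    VirtualPatient,
    rotate_stain_matrix,
)


class TestSampleCohort:
    def test_exact_positive_count(self):
        cohort = ss.sample_cohort(154, 63 / 154, 0.3, seed=1)
        assert sum(p.label for p in cohort) == 63
        assert len({p.patient_id for p in cohort}) == 154

    @pytest.mark.parametrize("n,frac,expected", [(10, 0.5, 5), (7, 0.3, 2), (9, 1.0, 9)])
    def test_rounding_rule(self, n, frac, expected):
        assert sum(p.label for p in ss.sample_cohort(n, frac, 0.1, seed=2)) == expected

    def test_determinism(self):
        a = ss.sample_cohort(12, 0.4, 0.5, seed=7)
        b = ss.sample_cohort(12, 0.4, 0.5, seed=7)
        assert a == b

    def test_zero_effect_is_label_independent(self):
        """At effect 0 the phenotype law cannot depend on the label."""
        base = ss.sample_cohort(30, 0.5, 0.0, seed=5)
        relabelled = ss.sample_cohort(30, 0.2, 0.0, seed=5)
        for p, q in zip(base, relabelled):
            assert p.phenotype == q.phenotype

    def test_morphology_effect_shifts_texture_only(self):
        c0 = ss.sample_cohort(20, 0.5, 0.0, seed=9)
        c1 = ss.sample_cohort(20, 0.5, 0.4, seed=9, signal_channel="morphology")
        for p0, p1 in zip(c0, c1):
            if p1.label == 1:
                assert p1.phenotype.chromatin_texture_amp == pytest.approx(
                    p0.phenotype.chromatin_texture_amp + 0.4
                )
            else:
                assert p1.phenotype == p0.phenotype
            assert p1.phenotype.hematoxylin_level == p0.phenotype.hematoxylin_level

    def test_color_effect_scales_hematoxylin(self):
        c0 = ss.sample_cohort(20, 0.5, 0.0, seed=9)
        c1 = ss.sample_cohort(20, 0.5, 0.3, seed=9, signal_channel="color")
        for p0, p1 in zip(c0, c1):
            factor = 1.3 if p1.label == 1 else 1.0
            assert p1.phenotype.hematoxylin_level == pytest.approx(
                p0.phenotype.hematoxylin_level * factor
            )

    @pytest.mark.parametrize("bad", [1, 0, -3, 2.5])
    def test_invalid_n_patients(self, bad):
        with pytest.raises(ValueError):
            ss.sample_cohort(bad, 0.5, 0.1, seed=0)


def _fixed_patient(density=6e-4, coverage=0.7, amp=0.3, h_level=1.0, seed=100):
    phenotype = TissuePhenotype(
        nuclear_density=density,
        nuclear_radius_mean=6.0,
        nuclear_radius_sd=1.0,
        chromatin_texture_amp=amp,
        stroma_fraction=0.5,
        tissue_coverage=coverage,
        hematoxylin_level=h_level,
    )
    return VirtualPatient(patient_id=0, label=0, phenotype=phenotype, tissue_seed=seed)


class TestConcentrationFields:
    def test_minimum_size(self):
        with pytest.raises(ValueError):
            ss.synthesize_concentration_fields(_fixed_patient(), 32, 128)

    def test_no_nuclei_keeps_hematoxylin_below_cyto_base(self):
        conc = ss.synthesize_concentration_fields(_fixed_patient(density=0.0), 256, 256)
        assert conc[0].max() < CYTO_H_BASE

    def test_determinism(self):
        p = _fixed_patient()
        a = ss.synthesize_concentration_fields(p, 256, 256)
        b = ss.synthesize_concentration_fields(p, 256, 256)
        np.testing.assert_array_equal(a, b)

    def test_background_margin_is_blank(self):
        conc = ss.synthesize_concentration_fields(_fixed_patient(), 256, 256)
        for ch in range(2):
            assert conc[ch, :8, :].max() == 0.0
            assert conc[ch, -8:, :].max() == 0.0
            assert conc[ch, :, :8].max() == 0.0
            assert conc[ch, :, -8:].max() == 0.0

    def test_nucleus_coverage_matches_poisson_expectation(self):
        """Painted-nucleus fraction ~= density x mean disk area (MC oracle)."""
        density, mu_r, sd_r = 3e-4, 6.0, 1.0
        expected = density * np.pi * (mu_r**2 + sd_r**2)
        fracs = []
        for seed in range(20):
            p = _fixed_patient(density=density, seed=seed)
            conc = ss.synthesize_concentration_fields(p, 384, 384)
            nuclei = conc[0] > CYTO_H_BASE
            tissue = conc[1] > 0
            fracs.append(nuclei.sum() / tissue.sum())
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) < 3 * se + 0.1 * expected

    def test_effect_size_monotonicity_on_rendered_slides(self):
        """Intra-nuclear OD variance separates classes iff an effect is planted."""
        profile, _ = ss.default_profiles(noise_sd=0.0)
        profile = replace(profile, slide_rotation_sd=0.0, slide_intensity_log_sd=0.0)

        def texture_stats(effect, seed):
            cohort = ss.sample_cohort(50, 0.5, effect, seed=seed)
            out = {0: [], 1: []}
            for p in cohort:
                conc = ss.synthesize_concentration_fields(p, 256, 256)
                img = ss.render_rgb(conc, profile, seed=p.tissue_seed)
                od = ss.rgb_to_od(img)
                nuclei = conc[0] > CYTO_H_BASE * p.phenotype.hematoxylin_level
                out[p.label].append(float(od[..., 0][nuclei].var()))
            return out

        strong = texture_stats(0.6, seed=31)
        p_strong = stats.mannwhitneyu(strong[1], strong[0], alternative="greater").pvalue
        assert p_strong < 0.01

        null = texture_stats(0.0, seed=32)
        p_null = stats.mannwhitneyu(null[1], null[0]).pvalue
        assert p_null > 0.01


class TestRender:
    def test_zero_concentration_is_pure_white(self, profiles):
        conc = np.zeros((2, 64, 64))
        img = ss.render_rgb(conc, profiles[0], seed=0)
        assert (img == 255).all()

    def test_single_pixel_matches_formula(self, profiles):
        profile = profiles[0]
        c = np.array([0.7, 0.4]).reshape(2, 1, 1)
        img = ss.render_rgb(c, profile, seed=0)
        od = profile.stain_matrix @ (profile.intensity_scale * np.array([0.7, 0.4]))
        expected = np.clip(np.rint(255.0 * np.exp(-od)), 0, 255)
        np.testing.assert_array_equal(img[0, 0].astype(float), expected)

    def test_doubling_hematoxylin_never_brightens(self, profiles):
        rng = np.random.default_rng(4)
        conc = rng.uniform(0, 1.5, size=(2, 64, 64))
        light = ss.render_rgb(conc, profiles[0], seed=0)
        darker_profile = replace(
            profiles[0], intensity_scale=profiles[0].intensity_scale * np.array([2.0, 1.0])
        )
        dark = ss.render_rgb(conc, darker_profile, seed=0)
        assert dark.mean() <= light.mean()
        assert (dark.astype(int) <= light.astype(int)).all()

    def test_negative_concentration_rejected(self, profiles):
        conc = np.full((2, 64, 64), -0.1)
        with pytest.raises(ValueError):
            ss.render_rgb(conc, profiles[0], seed=0)

    def test_od_conservation_roundtrip(self, patient, profiles):
        """-ln(I/I0) of a noise-free rendering equals W (s o c) within rounding."""
        conc = ss.synthesize_concentration_fields(patient, 256, 256)
        profile = profiles[0]
        img = ss.render_rgb(conc, profile, seed=0)
        od_true = np.tensordot(
            profile.stain_matrix, profile.intensity_scale[:, None, None] * conc, 1
        ).transpose(1, 2, 0)
        intensity_true = 255.0 * np.exp(-od_true)
        assert np.abs(img.astype(float) - intensity_true).max() <= 0.5 + 1e-6


class TestBatchPair:
    def test_identical_profiles_render_identically(self, patient, profiles):
        pair = ss.make_batch_pair(patient, profiles[0], profiles[0], 640, 640, seed=2)
        np.testing.assert_array_equal(pair.slide_A, pair.slide_B)

    def test_conc_fields_shared_and_reproducible(self, patient, profiles, pair):
        expected = ss.synthesize_concentration_fields(patient, 768, 768)
        np.testing.assert_array_equal(pair.conc_fields, expected)
        assert pair.slide_A.shape[:2] == expected.shape[1:]

    def test_darker_batch_has_lower_mean_intensity(self, pair):
        # batch A carries full stain intensity; batch B renders lighter
        assert pair.slide_A.mean() < pair.slide_B.mean()

    def test_swapping_profiles_swaps_slides_exactly(self, patient, profiles):
        ab = ss.make_batch_pair(patient, profiles[0], profiles[1], 640, 640, seed=3)
        ba = ss.make_batch_pair(patient, profiles[1], profiles[0], 640, 640, seed=3)
        np.testing.assert_array_equal(ab.slide_A, ba.slide_B)
        np.testing.assert_array_equal(ab.slide_B, ba.slide_A)


class TestStainProfile:
    def test_invalid_profiles_rejected(self):
        w = np.stack([[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]], axis=1)
        w = w / np.linalg.norm(w, axis=0)
        with pytest.raises(ValueError):
            StainProfile(w, np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            StainProfile(w * 2, np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            StainProfile(w, np.array([1.0, 1.0]), noise_sd=-0.1)

    def test_rotation_preserves_unit_norm_and_nonnegativity(self):
        w, _ = ss.default_profiles()
        rotated = rotate_stain_matrix(w.stain_matrix, 25.0)
        np.testing.assert_allclose(np.linalg.norm(rotated, axis=0), 1.0, atol=1e-9)
        assert (rotated >= 0).all()
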
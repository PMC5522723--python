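"""Tiered absorptance optics: closed form vs oracles and physical properties."""

import numpy as np
import pytest

from specsens import (
    ArrayStructure,
    EyeModel,
    PigmentSpec,
    ReceptorClass,
    SpectralCurve,
    Tier,
    alpha_band,
    apply_prefilters,
    array_absorptance,
    build_eye_model,
    cross_section_absorbance,
    normalize_peak,
    residual_transmittance,
    tier_xi,
)
from specsens.exceptions import DegenerateModelError, StructuralError
from specsens.optics import eye_model_from_dict, eye_model_to_dict

from conftest import random_eye_model, slab_absorptance


def single_tier_model(lmax=500.0, k=0.008, length=100.0, family="SSH"):
    return EyeModel(
        (Tier(length, (ReceptorClass(PigmentSpec(family, lmax), 1.0, k),)),)
    )


class TestTierXi:
    def test_single_receptor_peak_equals_k(self, grid_1nm):
        tier = Tier(10.0, (ReceptorClass(PigmentSpec("SSH", 500.0), 1.0, 0.008),))
        xi = tier_xi(tier, grid_1nm)
        assert xi.values[int(np.searchsorted(grid_1nm, 500.0))] == pytest.approx(0.008)

    def test_split_identical_pigments_degenerate(self, grid_1nm):
        one = Tier(10.0, (ReceptorClass(PigmentSpec("SSH", 500.0), 1.0, 0.008),))
        two = Tier(
            10.0,
            (
                ReceptorClass(PigmentSpec("SSH", 500.0), 0.5, 0.008),
                ReceptorClass(PigmentSpec("SSH", 500.0), 0.5, 0.008),
            ),
        )
        np.testing.assert_allclose(
            tier_xi(one, grid_1nm).values, tier_xi(two, grid_1nm).values, atol=1e-15
        )

    def test_four_class_sum_matches_manual_summation(self, daphnia_tier, grid_1nm):
        xi = tier_xi(daphnia_tier, grid_1nm)
        at = int(np.searchsorted(grid_1nm, 442.0))
        expected = sum(
            alpha_band(r.pigment, grid_1nm)[at] * r.rel_area * r.k
            for r in daphnia_tier.receptors
        )
        assert xi.values[at] == pytest.approx(expected, abs=1e-12)

    def test_areas_renormalized_within_tier(self):
        # published area sets sometimes sum to slightly more than 1
        tier = Tier(
            10.0,
            (
                ReceptorClass(PigmentSpec("SSH", 400.0), 0.6, 0.008),
                ReceptorClass(PigmentSpec("SSH", 500.0), 0.6, 0.008),
            ),
        )
        assert sum(r.rel_area for r in tier.receptors) == pytest.approx(1.0)


class TestArrayAbsorptance:
    def test_no_pigment_no_absorption(self, grid_1nm):
        model = single_tier_model(k=1e-9, length=1e-3)
        assert np.max(array_absorptance(model, grid_1nm).values) < 1e-9

    def test_saturation_at_high_optical_density(self, grid_1nm):
        model = single_tier_model(k=0.1, length=1000.0)
        s = array_absorptance(model, grid_1nm)
        assert s.values[int(np.searchsorted(grid_1nm, 500.0))] == pytest.approx(1.0, abs=1e-9)

    def test_two_tier_closed_form(self, grid_1nm):
        # S = (1-e^{-xi1 l1}) + e^{-xi1 l1} (1-e^{-xi2 l2})
        model = build_eye_model(
            "SSH",
            (400.0, 550.0),
            (0.5, 0.5),
            0.008,
            ArrayStructure((20.0, 30.0), replace_shortest=True),
        )
        s = array_absorptance(model, grid_1nm)
        from specsens.optics import _tier_xi_values

        a1 = np.exp(-_tier_xi_values(model.tiers[0], grid_1nm) * 20.0)
        a2 = np.exp(-_tier_xi_values(model.tiers[1], grid_1nm) * 30.0)
        np.testing.assert_allclose(s.values, (1 - a1) + a1 * (1 - a2), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_slab_discretization_oracle(self, seed, grid_1nm):
        rng = np.random.default_rng(seed)
        model = random_eye_model(rng)
        closed = array_absorptance(model, grid_1nm).values
        slabs = slab_absorptance(model, grid_1nm, n_slabs=10_000)
        assert np.max(np.abs(closed - slabs)) < 1e-4

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation(self, seed, grid_1nm):
        rng = np.random.default_rng(100 + seed)
        model = random_eye_model(rng)
        s = array_absorptance(model, grid_1nm).values
        t = residual_transmittance(model, grid_1nm).values
        assert np.max(np.abs(s + t - 1.0)) < 1e-12

    def test_monotone_in_k_and_length(self, grid_1nm):
        base = single_tier_model(k=0.005, length=50.0)
        more_k = single_tier_model(k=0.008, length=50.0)
        longer = single_tier_model(k=0.005, length=80.0)
        s0 = array_absorptance(base, grid_1nm).values
        assert np.all(array_absorptance(more_k, grid_1nm).values >= s0 - 1e-15)
        assert np.all(array_absorptance(longer, grid_1nm).values >= s0 - 1e-15)

    def test_self_screening_broadens_fwhm(self, grid_1nm):
        def fwhm(kl):
            model = single_tier_model(k=0.008, length=kl / 0.008)
            s = normalize_peak(array_absorptance(model, grid_1nm)).values
            above = grid_1nm[s >= 0.5]
            return above[-1] - above[0]

        widths = [fwhm(kl) for kl in (0.1, 0.5, 1.0, 2.0, 4.0)]
        assert all(w2 > w1 for w1, w2 in zip(widths, widths[1:]))

    def test_empty_tiers_rejected(self):
        with pytest.raises(StructuralError):
            EyeModel(())


class TestPrefiltersAndNormalization:
    def test_no_prefilters_identity(self, grid_1nm):
        model = single_tier_model()
        s = array_absorptance(model, grid_1nm)
        np.testing.assert_array_equal(apply_prefilters(model, s).values, s.values)

    def test_constant_half_filter(self, grid_1nm):
        flat = SpectralCurve(np.array([250.0, 800.0]), np.array([0.5, 0.5]))
        model = EyeModel(single_tier_model().tiers, (flat,))
        s = array_absorptance(model, grid_1nm)
        np.testing.assert_allclose(
            apply_prefilters(model, s).values, 0.5 * s.values, atol=1e-15
        )

    def test_prefilter_order_commutes(self, grid_1nm):
        wl = np.array([250.0, 800.0])
        f1 = SpectralCurve(wl, np.array([0.8, 0.3]))
        f2 = SpectralCurve(wl, np.array([0.2, 0.9]))
        tiers = single_tier_model().tiers
        s = array_absorptance(EyeModel(tiers), grid_1nm)
        a = apply_prefilters(EyeModel(tiers, (f1, f2)), s).values
        b = apply_prefilters(EyeModel(tiers, (f2, f1)), s).values
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_normalize_peak(self, grid_1nm):
        const = SpectralCurve(grid_1nm, np.full(grid_1nm.size, 0.2))
        assert np.all(normalize_peak(const).values == 1.0)
        s = array_absorptance(single_tier_model(), grid_1nm)
        normed = normalize_peak(s)
        assert normed.argmax_wavelength() == s.argmax_wavelength()
        np.testing.assert_array_equal(normalize_peak(normed).values, normed.values)

    def test_all_zero_curve_degenerate(self, grid_1nm):
        with pytest.raises(DegenerateModelError):
            normalize_peak(SpectralCurve(grid_1nm, np.zeros(grid_1nm.size)))


class TestCrossSection:
    def test_one_tier_any_depth(self, daphnia_tier, grid_1nm):
        model = EyeModel((daphnia_tier,))
        expected = normalize_peak(tier_xi(daphnia_tier, grid_1nm)).values
        for depth in (0.0, 0.5, 1.0):
            np.testing.assert_allclose(
                cross_section_absorbance(model, grid_1nm, depth).values, expected
            )

    def test_depth_selects_proximal_tier(self, grid_1nm):
        model = build_eye_model(
            "SSH",
            (360.0, 550.0),
            (0.5, 0.5),
            0.008,
            ArrayStructure((6.0, 6.0), replace_shortest=True),
        )
        deep = cross_section_absorbance(model, grid_1nm, 0.9)
        # proximal tier has lost the UV receptor
        assert deep.argmax_wavelength() == pytest.approx(550.0, abs=1.0)
        shallow = cross_section_absorbance(model, grid_1nm, 0.25)
        assert shallow.values[int(np.searchsorted(grid_1nm, 360.0))] > 0.4

    def test_five_class_component_peaks(self, grid_1nm):
        lams = (360.0, 390.0, 460.0, 520.0, 600.0)
        model = build_eye_model(
            "GFKRD",
            lams,
            (0.1, 0.25, 0.32, 0.2, 0.12),
            0.008,
            ArrayStructure((1000.0 / 3.0, 500.0 / 3.0), replace_shortest=True),
        )
        # per-term argmax: each receptor's contribution peaks at its own lambda_max
        section = model.tiers[0]
        assert len(section.receptors) == 5
        for r in section.receptors:
            contrib = alpha_band(r.pigment, grid_1nm) * r.rel_area * r.k
            assert abs(grid_1nm[int(np.argmax(contrib))] - r.pigment.lambda_max) <= 1.0
        # depth fraction 2/3 sits on the tier boundary and belongs distally
        sec = cross_section_absorbance(model, grid_1nm, 2.0 / 3.0)
        assert sec.values[int(np.searchsorted(grid_1nm, 360.0))] > 0.1


class TestReplacementRule:
    def test_proximal_tier_reassigns_shortest_area(self):
        model = build_eye_model(
            "SSH",
            (356.0, 440.0, 521.0, 592.0),
            (0.52, 0.21, 0.12, 0.15),
            0.008,
            ArrayStructure((6.0, 6.0), replace_shortest=True),
        )
        distal, proximal = model.tiers
        assert [r.pigment.lambda_max for r in distal.receptors] == [356, 440, 521, 592]
        assert [r.pigment.lambda_max for r in proximal.receptors] == [440, 521, 592]
        # shortest class's area goes to the replacement (longest) receptor
        assert proximal.receptors[-1].rel_area == pytest.approx(0.15 + 0.52)
        assert proximal.receptors[0].rel_area == pytest.approx(0.21)

    def test_single_class_replacement_is_noop(self, grid_1nm):
        tiered = build_eye_model(
            "SSH", (481.0,), (1.0,), 0.008,
            ArrayStructure((50.0, 50.0), replace_shortest=True),
        )
        flat = build_eye_model("SSH", (481.0,), (1.0,), 0.008, ArrayStructure((100.0,)))
        np.testing.assert_allclose(
            array_absorptance(tiered, np.arange(350.0, 691.0)).values,
            array_absorptance(flat, np.arange(350.0, 691.0)).values,
            atol=1e-12,
        )


def test_eye_model_dict_round_trip(daphnia_tier):
    model = EyeModel((daphnia_tier,), label="daphnia")
    restored = eye_model_from_dict(eye_model_to_dict(model))
    assert restored.label == "daphnia"
    assert len(restored.tiers[0].receptors) == 4
    assert restored.tiers[0].receptors[2].pigment.lambda_max == 518.0
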
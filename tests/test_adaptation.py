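"""Adaptation updates: shapes, the mu-sigma coupling, and composition laws."""

import math

import numpy as np
import pytest

from speechadapt import (
    AUDITORY,
    AdaptationSpec,
    ConfigurationError,
    FUSION,
    LocalWindow,
    MuSigmaRelation,
    Perturbation,
    Phoneme,
    PHONEMES,
    apply_auditory_char_update,
    apply_general_update,
    apply_local_update,
    apply_somato_char_update,
    build_adapted_state,
    categorization_curve,
    find_boundary,
    mu_from_sigma,
    perception_posterior,
    production_posterior,
)
from speechadapt.experiments import default_sigma_grid

I, EH, AH = Phoneme.I, Phoneme.EH, Phoneme.AH


class TestGeneralUpdate:
    def test_full_update_shifts_map_by_delta(self, normal, pert):
        adapted = apply_general_update(normal, pert, 1.0)
        assert adapted.rho_A(1.0) == pytest.approx(1.4, abs=1e-15)

    def test_zero_magnitude_is_identity(self, normal, pert):
        assert apply_general_update(normal, pert, 0.0) is normal

    def test_partial_update_is_uniform_shift(self, normal, pert, grid):
        adapted = apply_general_update(normal, pert, 0.5)
        m = grid.points()
        assert np.allclose(adapted.rho_A(m), m + 0.2, atol=1e-12)
        # only the auditory-motor map changed
        assert adapted.rho_S == normal.rho_S
        assert adapted.aud_chars == normal.aud_chars
        assert adapted.som_chars == normal.som_chars


class TestLocalUpdate:
    def test_plateau_and_ramp_values(self, normal, pert):
        window = LocalWindow(core_lo=0.6, core_hi=1.0, ramp=0.6)
        adapted = apply_local_update(normal, pert, 1.0, window)
        assert adapted.rho_A(0.8) == pytest.approx(1.2, abs=1e-12)  # core
        assert adapted.rho_A(0.3) == pytest.approx(0.5, abs=1e-12)  # up-ramp midpoint
        assert adapted.rho_A(-0.5) == -0.5  # outside
        assert adapted.rho_A(2.5) == 2.5

    def test_default_window_spans_compensated_interval(self, normal, pert):
        adapted = apply_local_update(normal, pert, 1.0)
        # full update on [mu - |delta|, mu], untouched far away
        assert adapted.rho_A(0.6) == pytest.approx(1.0, abs=1e-12)
        assert adapted.rho_A(1.0) == pytest.approx(1.4, abs=1e-12)
        assert adapted.rho_A(-0.5) == -0.5
        assert adapted.rho_A(2.0) == 2.0

    def test_too_narrow_ramp_rejected(self, normal, pert):
        window = LocalWindow(core_lo=0.6, core_hi=1.0, ramp=0.3)
        with pytest.raises(ConfigurationError):
            apply_local_update(normal, pert, 1.0, window)

    def test_degenerates_to_general_update(self, normal, pert, grid):
        # core covering the grid with ramps beyond it: identical inference
        window = LocalWindow(core_lo=-2.0, core_hi=4.0, ramp=1.0)
        local = apply_local_update(normal, pert, 1.0, window)
        general = apply_general_update(normal, pert, 1.0)
        p_local = production_posterior(local, EH, FUSION, grid)
        p_general = production_posterior(general, EH, FUSION, grid)
        assert np.max(np.abs(p_local.density - p_general.density)) <= 1e-9
        for pathways in (AUDITORY, FUSION):
            cl = categorization_curve(local, grid, pathways)
            cg = categorization_curve(general, grid, pathways)
            for p in PHONEMES:
                assert np.max(np.abs(cl.probs[p] - cg.probs[p])) <= 1e-9


class TestMuSigmaRelation:
    def test_normal_sd_maps_to_zero_shift(self, normal):
        rel = MuSigmaRelation.from_state(normal)
        assert mu_from_sigma(rel, 0.125) == pytest.approx(0.0, abs=1e-12)

    def test_half_sd_closed_form_value(self, normal):
        rel = MuSigmaRelation.from_state(normal)
        # b0 - sigma*sqrt(2*(B + ln(sd_a/sigma))) with B = (b0-mu_a)^2/(2 sd_a^2)
        expected = (1.5 - 0.0625 * math.sqrt(2.0 * (8.0 + math.log(2.0)))) - 1.0
        shift = mu_from_sigma(rel, 0.0625)
        assert shift == pytest.approx(expected, abs=1e-12)
        assert shift == pytest.approx(0.2393945, abs=1e-6)

    @pytest.mark.parametrize("sigma", [0.2, 0.0, -0.1])
    def test_domain_error(self, normal, sigma):
        rel = MuSigmaRelation.from_state(normal)
        with pytest.raises(ConfigurationError):
            mu_from_sigma(rel, sigma)

    def test_boundary_invariance_across_sigma_grid(self, normal, grid):
        # the relation is designed to pin the auditory-only boundary on the
        # perturbed side at its normal location for every narrowing level
        for sigma in default_sigma_grid():
            adapted = apply_auditory_char_update(normal, sigma)
            curve = categorization_curve(adapted, grid, AUDITORY)
            b = find_boundary(curve, (EH, AH), reference=1.5)
            assert b.location == pytest.approx(1.5, abs=5e-4)


class TestAuditoryCharUpdate:
    def test_normal_sd_leaves_state_unchanged(self, normal):
        assert apply_auditory_char_update(normal, 0.125) is normal

    def test_only_target_auditory_char_changes(self, normal):
        adapted = apply_auditory_char_update(normal, 0.0625)
        assert adapted.aud_chars[EH].sd == 0.0625
        assert adapted.aud_chars[EH].mean > 1.0
        assert adapted.aud_chars[I] == normal.aud_chars[I]
        assert adapted.aud_chars[AH] == normal.aud_chars[AH]
        assert adapted.som_chars == normal.som_chars
        assert adapted.rho_A == normal.rho_A

    def test_near_boundary_moves_toward_perturbation(self, normal, grid):
        adapted = apply_auditory_char_update(normal, 0.0625)
        curve = categorization_curve(adapted, grid, AUDITORY)
        b = find_boundary(curve, (I, EH), reference=0.5)
        assert b.location > 0.5  # /i-ɛ/ boundary moves toward /a/

    def test_production_moves_with_the_perturbation(self, normal, grid):
        adapted = apply_auditory_char_update(normal, 0.0625)
        pre = production_posterior(normal, EH, FUSION, grid)
        post = production_posterior(adapted, EH, FUSION, grid)
        assert post.mean > pre.mean  # toward /a/, same direction as delta > 0


class TestSomatoCharUpdate:
    def test_zero_shift_is_identity(self, normal):
        assert apply_somato_char_update(normal, 0.0) is normal

    def test_auditory_categorization_bit_identical(self, normal, grid):
        adapted = apply_somato_char_update(normal, -0.2)
        a = grid.points()
        base = perception_posterior(normal, a, AUDITORY)
        probs = perception_posterior(adapted, a, AUDITORY)
        for p in PHONEMES:
            assert np.array_equal(probs[p], base[p])

    def test_fusion_boundary_moves_opposite_to_perturbation(self, normal, grid):
        adapted = apply_somato_char_update(normal, -0.2)
        curve = categorization_curve(adapted, grid, FUSION)
        b = find_boundary(curve, (I, EH), reference=0.5)
        assert b.location < 0.5


class TestBuildAdaptedState:
    def test_combined_update_touches_disjoint_components(self, normal, pert):
        spec = AdaptationSpec(
            internal_model="local", update_magnitude=1.0, aud_char_sigma=0.0625
        )
        adapted = build_adapted_state(normal, spec, pert)
        assert adapted.rho_A != normal.rho_A
        assert adapted.aud_chars[EH] != normal.aud_chars[EH]
        assert adapted.rho_S == normal.rho_S
        assert adapted.aud_chars[I] == normal.aud_chars[I]
        assert adapted.aud_chars[AH] == normal.aud_chars[AH]
        assert adapted.som_chars == normal.som_chars

    def test_all_none_returns_normal(self, normal, pert):
        spec = AdaptationSpec(internal_model="none")
        assert build_adapted_state(normal, spec, pert) == normal

    def test_updates_commute_bit_exactly(self, normal, pert):
        rel = MuSigmaRelation.from_state(normal)
        window = LocalWindow(core_lo=0.6, core_hi=1.0, ramp=0.45)
        forward = apply_somato_char_update(
            apply_auditory_char_update(
                apply_local_update(normal, pert, 1.0, window), 0.0625, rel=rel
            ),
            -0.2,
        )
        reverse = apply_local_update(
            apply_auditory_char_update(
                apply_somato_char_update(normal, -0.2), 0.0625, rel=rel
            ),
            pert,
            1.0,
            window,
        )
        assert forward == reverse

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            AdaptationSpec(internal_model="weird")
        with pytest.raises(ConfigurationError):
            AdaptationSpec(update_magnitude=1.3)
        with pytest.raises(ConfigurationError):
            Perturbation(delta=1.5)
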
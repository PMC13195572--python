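"""Fraying and displacement landscapes; exact Boltzmann occupancies."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdnkit import (
    DEFAULT_MODEL,
    EnergyModel,
    Landscape1D,
    R_KCAL,
    calibrate_increments,
    delta_G_profile_report,
    displacement_landscape,
    fraying_landscape,
    pair_strands,
    retained_duplex,
    toehold_availability,
    two_state_landscape,
)
from tdnkit.thermo import segment_stacks

from conftest import make_strand

RT = R_KCAL * 310.15


class TestFraying:
    def test_default_retained_segment_eight_states(self, default_fraying):
        assert len(default_fraying) == 8
        assert default_fraying.coords == tuple(float(s) for s in range(8))
        # the fully bound state is more stable than the open toehold
        assert default_fraying.dG[-1] < default_fraying.dG[0]

    def test_first_base_pair_pays_tether_entropy(self, default_fraying):
        assert default_fraying.dG[1] == pytest.approx(
            DEFAULT_MODEL.tether_init_dG, abs=1e-12
        )

    def test_flat_when_all_energies_zero(self, zero_model):
        a = make_strand("a", "ACGU", "RRRR")
        b = make_strand("b", "ACGT")
        duplex = pair_strands(a, (1, 4), b, (1, 4))
        landscape = fraying_landscape(duplex, zero_model)
        assert all(g == 0.0 for g in landscape.dG)

    def test_three_bp_hand_sum(self):
        a = make_strand("a", "ACG", "RRR")
        b = make_strand("b", "CGT")
        duplex = pair_strands(a, (1, 3), b, (1, 3))
        stacks = segment_stacks(duplex)  # ascending strand-A position
        landscape = fraying_landscape(duplex, free_end="low")
        # anchor at the high-position end: state s holds the s pairs nearest it
        t = DEFAULT_MODEL.tether_init_dG
        expected = [0.0, t, t + stacks[1], t + stacks[1] + stacks[0]]
        assert landscape.dG == pytest.approx(expected, abs=1e-12)

    def test_too_short_segment_rejected(self):
        a = make_strand("a", "A", "R")
        b = make_strand("b", "T")
        duplex = pair_strands(a, (1, 1), b, (1, 1))
        with pytest.raises(ValueError):
            fraying_landscape(duplex)


class TestOccupancy:
    def test_two_state_symmetric(self):
        occ = toehold_availability(two_state_landscape(0.0))
        assert occ.open_fraction == pytest.approx(0.5, abs=1e-12)

    def test_two_state_closed_form(self):
        occ = toehold_availability(two_state_landscape(3.0))
        expected = math.exp(-3.0 / RT) / (1.0 + math.exp(-3.0 / RT))
        assert occ.open_fraction == pytest.approx(expected, rel=1e-12)
        assert occ.delta_G_open == pytest.approx(3.0)

    def test_open_fraction_decreasing_in_delta_G(self):
        fractions = [
            toehold_availability(two_state_landscape(g)).open_fraction
            for g in np.linspace(0.0, 6.0, 13)
        ]
        assert all(a > b for a, b in zip(fractions, fractions[1:]))

    def test_open_fraction_increasing_in_temperature(self):
        landscape = two_state_landscape(3.0)
        fractions = [
            toehold_availability(landscape, EnergyModel(temperature=T)).open_fraction
            for T in (290.0, 310.0, 330.0, 350.0)
        ]
        assert all(a < b for a, b in zip(fractions, fractions[1:]))

    def test_stabilizing_increment_never_opens_toehold(self, default_design):
        """More stabilizing LNA/OME increments on the retained segment can
        only reduce the open fraction (monotone coupling over a grid)."""
        retained = retained_duplex(default_design)
        fractions = []
        for factor in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0):
            model = DEFAULT_MODEL.with_scaled_increments(factor)
            occ = toehold_availability(fraying_landscape(retained, model), model)
            fractions.append(occ.open_fraction)
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    @given(
        energies=st.lists(
            st.floats(min_value=-15, max_value=15, allow_nan=False), min_size=2, max_size=12
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_probabilities_normalized(self, energies):
        landscape = Landscape1D.from_energies(
            "x", list(range(len(energies))), energies, reference_index=0
        )
        occ = toehold_availability(landscape)
        assert sum(occ.probabilities) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in occ.probabilities)


class TestDisplacement:
    def test_flat_branch_migration_identical_chemistries(self):
        model = replace(DEFAULT_MODEL, bm_plateau_dG=0.0)
        landscape = displacement_landscape(
            3, 4, model, invader_stacks=[-1.5] * 6, incumbent_stacks=[-1.5] * 3,
            incumbent_dissoc_credit=0.0,
        )
        idx = {c: g for c, g in zip(landscape.coords, landscape.dG)}
        # migration intermediates (toehold-bound through last exchange) are
        # level; only the committed final state drops
        bm_values = [idx[c] for c in sorted(idx) if 3 <= c < 7]
        assert all(v == pytest.approx(bm_values[0], abs=1e-12) for v in bm_values)
        assert idx[7.0] < bm_values[0]

    def test_plateau_height_is_exact_barrier(self):
        landscape = displacement_landscape(
            3, 4, invader_stacks=[-1.5] * 6, incumbent_stacks=[-1.5] * 3
        )
        idx = {c: g for c, g in zip(landscape.coords, landscape.dG)}
        assert idx[3.5] - idx[3.0] == pytest.approx(DEFAULT_MODEL.bm_plateau_dG, abs=1e-12)

    def test_default_global_minimum_at_full_displacement(self, default_design):
        from tdnkit import displacement_landscape_for_design, generate_target, target_gapmer_duplex
        from tdnkit.generate import GeneratorSpec

        spec = GeneratorSpec(seed=1)
        target = generate_target(spec, default_design)
        duplex = target_gapmer_duplex(default_design, target)
        landscape = displacement_landscape_for_design(default_design, duplex)
        m_min = landscape.coords[int(np.argmin(landscape.dG))]
        assert m_min == 20.0
        assert landscape.dG[-1] < landscape.dG[0]

    def test_thermodynamic_drive_generic_defaults(self):
        landscape = displacement_landscape(7, 13)
        assert landscape.dG[-1] < landscape.dG[0]

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            displacement_landscape(0, 5)


class TestCalibration:
    def test_calibrated_delta_matches_target(self, default_design):
        retained = retained_duplex(default_design)
        model = calibrate_increments(retained, DEFAULT_MODEL, 3.0)
        landscape = fraying_landscape(retained, model)
        assert landscape.dG[0] - landscape.dG[-1] == pytest.approx(3.0, abs=1e-6)

    def test_calibration_returns_new_model(self, default_design):
        retained = retained_duplex(default_design)
        model = calibrate_increments(retained, DEFAULT_MODEL, 3.0)
        assert model is not DEFAULT_MODEL
        assert DEFAULT_MODEL.mod_increments["LNA"] == -1.0


class TestProfileReport:
    def test_reference_row_and_row_count(self, default_fraying):
        text = delta_G_profile_report(default_fraying)
        lines = text.strip().splitlines()
        assert len(lines) == 1 + len(default_fraying)
        ref_line = lines[1 + default_fraying.reference_index]
        assert ref_line.split("\t")[1] == "0.000000"

    def test_byte_stable(self, default_fraying):
        assert delta_G_profile_report(default_fraying) == delta_G_profile_report(
            default_fraying
        )

    def test_flat_landscape_all_zero(self):
        flat = Landscape1D("x", (0.0, 1.0, 2.0), (0.0, 0.0, 0.0), 0)
        rows = delta_G_profile_report(flat).strip().splitlines()[1:]
        assert all(r.split("\t")[1] == "0.000000" for r in rows)


class TestLandscapeInvariants:
    def test_reference_state_must_be_zero(self):
        with pytest.raises(ValueError):
            Landscape1D("x", (0.0, 1.0), (1.0, 1.0), 0)

    def test_coordinates_strictly_increasing(self):
        with pytest.raises(ValueError):
            Landscape1D("x", (0.0, 0.0), (0.0, 1.0), 0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            Landscape1D("x", (0.0, 1.0), (0.0, float("inf")), 0)
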
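"""Mamdani engine, fuzzy dynamics, and fuzzy-vs-ODE qualitative agreement."""

import numpy as np
import pytest

from phfeedback.fuzzy import (
    FuzzySpecies,
    FuzzyState,
    fuzzify,
    fuzzy_iterate,
    fuzzy_sweep_pair,
    fuzzy_sweep_single,
    infer_density_change,
    infer_ph_change,
    load_fuzzy_config,
)
from phfeedback.outcomes import MotifLabel, label_motif, species_character
from tests.conftest import MOTIF_PAIRS


class TestFuzzify:
    def test_degree_one_at_label_peak(self, fuzzy_config):
        part = fuzzy_config.partitions["pH"]
        assert fuzzify(6.5, part)["medium"] == 1.0
        assert fuzzify(2.0, part)["low"] == 1.0

    def test_crossover_splits_half_half(self, fuzzy_config):
        part = fuzzy_config.partitions["pH"]
        mid = (2.0 + 6.5) / 2  # halfway between adjacent peaks
        mu = fuzzify(mid, part)
        assert mu["low"] == pytest.approx(0.5)
        assert mu["medium"] == pytest.approx(0.5)

    @pytest.mark.parametrize("name", ["pH", "preferred_pH", "cell_density"])
    def test_partition_of_unity(self, fuzzy_config, name):
        part = fuzzy_config.partitions[name]
        lo, hi = part.universe
        xs = np.linspace(lo, hi, 501)
        total = sum(fuzzify(xs, part)[lab] for lab in part.mfs)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_out_of_universe_rejected(self, fuzzy_config):
        with pytest.raises(ValueError):
            fuzzify(14.5, fuzzy_config.partitions["pH"])


class TestDensityInference:
    def test_matched_niche_grows(self, fuzzy_config):
        dn = infer_density_change(2.5, 2.5, 0.3, fuzzy_config)
        assert dn > 0

    def test_mismatched_niche_declines(self, fuzzy_config):
        assert infer_density_change(10.5, 2.5, 0.3, fuzzy_config) < 0

    def test_label_swap_symmetry(self, fuzzy_config):
        """Swapping current and preferred pH leaves the change invariant
        (the rule base only depends on label distance)."""
        for ph, pref in [(3.0, 9.0), (5.0, 8.0), (2.5, 6.5)]:
            a = infer_density_change(ph, pref, 0.4, fuzzy_config)
            b = infer_density_change(pref, ph, 0.4, fuzzy_config)
            assert a == pytest.approx(b, abs=1e-9)

    def test_rule_base_is_label_symmetric(self, fuzzy_config):
        """Automated enumeration: for every (pH=X, pref=Y) rule there is the
        mirrored (pH=Y, pref=X) rule with the same consequent."""
        seen = {}
        for rule in fuzzy_config.density_rules:
            ants = rule.antecedents
            if "pH" in ants and "preferred_pH" in ants:
                seen[(ants["pH"], ants["preferred_pH"])] = rule.consequent
        for (x, y), consequent in seen.items():
            assert seen.get((y, x)) == consequent

    def test_gain_scales_output(self, fuzzy_config):
        base = infer_density_change(2.5, 2.5, 0.3, fuzzy_config)
        cfg2 = load_fuzzy_config(gain=0.1)
        assert infer_density_change(2.5, 2.5, 0.3, cfg2) == pytest.approx(2 * base)


class TestPhInference:
    def test_no_bacteria_no_change(self, fuzzy_config):
        assert infer_ph_change(0.0, 7.0, 1, config=fuzzy_config) == pytest.approx(0.0, abs=1e-9)

    def test_opposite_abilities_cancel(self, fuzzy_config):
        net = infer_ph_change([0.4, 0.4], 7.0, [1, -1], config=fuzzy_config)
        assert net == pytest.approx(0.0, abs=1e-9)

    def test_relative_strength_scales_partner(self, fuzzy_config):
        solo_b = infer_ph_change([0.0, 0.4], 7.0, [1, -1], config=fuzzy_config)
        doubled = infer_ph_change([0.0, 0.4], 7.0, [1, -1], relative_strength=2.0, config=fuzzy_config)
        assert doubled == pytest.approx(2 * solo_b, rel=1e-9)

    def test_drive_magnitude_grows_with_density(self, fuzzy_config):
        mags = [
            abs(infer_ph_change(d, 7.0, 1, config=fuzzy_config)) for d in (0.05, 0.4, 0.95)
        ]
        assert mags[0] < mags[1] < mags[2]


class TestFuzzyIterate:
    def test_sterile_ph_constant(self, fuzzy_config, fuzzy_archetypes):
        tr = fuzzy_iterate(
            FuzzyState(0.0, 0.0, 6.2), fuzzy_archetypes["lp"], fuzzy_archetypes["ca"], fuzzy_config
        )
        np.testing.assert_allclose(tr.pH, 6.2, atol=1e-12)

    def test_self_killer_rises_then_collapses(self, fuzzy_config, fuzzy_archetypes):
        tr = fuzzy_iterate(FuzzyState(0.1, 0.0, 8.5), fuzzy_archetypes["sm"], None, fuzzy_config)
        assert tr.n_a.max() > 3 * tr.n_a[0]
        assert tr.n_a[-1] < 1e-3

    def test_deterministic(self, fuzzy_config, fuzzy_archetypes):
        runs = [
            fuzzy_iterate(FuzzyState(0.3, 0.2, 7.0), fuzzy_archetypes["lp"], fuzzy_archetypes["ca"], fuzzy_config)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].n_a, runs[1].n_a)
        np.testing.assert_array_equal(runs[0].pH, runs[1].pH)

    def test_states_clamped_to_universes(self, fuzzy_config, fuzzy_archetypes):
        tr = fuzzy_iterate(
            FuzzyState(0.9, 0.9, 10.9), fuzzy_archetypes["pv"], fuzzy_archetypes["sm"], fuzzy_config
        )
        for arr, (lo, hi) in [
            (tr.n_a, (0, 1)),
            (tr.n_b, (0, 1)),
            (tr.pH, fuzzy_config.partitions["pH"].universe),
        ]:
            assert arr.min() >= lo - 1e-12 and arr.max() <= hi + 1e-12


class TestFuzzySweeps:
    def test_boundary_fraction_column_matches_single_run(self, fuzzy_config, fuzzy_archetypes):
        lp, ca = fuzzy_archetypes["lp"], fuzzy_archetypes["ca"]
        ph_grid = np.linspace(3.0, 10.0, 5)
        gp = fuzzy_sweep_pair(lp, ca, fuzzy_config, np.array([0.0, 0.5, 1.0]), ph_grid,
                              total_density=0.5)
        gs = fuzzy_sweep_single(ca, fuzzy_config, np.array([0.5]), ph_grid)
        np.testing.assert_array_equal(gp.b_survives[0], gs.a_survives[0])

    def test_archetype_characters(self, fuzzy_config, fuzzy_archetypes):
        grids = {
            k: fuzzy_sweep_single(v, fuzzy_config, np.geomspace(1e-3, 0.9, 7),
                                  np.linspace(2.5, 10.5, 7))
            for k, v in fuzzy_archetypes.items()
        }
        assert species_character(grids["pv"]) == "suicide"
        assert species_character(grids["sm"]) == "suicide"
        assert species_character(grids["lp"]) == "conditional"
        assert species_character(grids["ca"]) == "conditional"

    def test_canonical_pair_motifs_match_ode(self, fuzzy_config, fuzzy_archetypes):
        """The fuzzy backend reproduces the ODE backend's four coculture
        motifs on a reduced grid (full-size agreement is checked in the
        acceptance suite)."""
        ph_grid = np.linspace(2.5, 10.5, 7)
        singles = {
            k: fuzzy_sweep_single(v, fuzzy_config, np.geomspace(1e-3, 0.9, 7), ph_grid)
            for k, v in fuzzy_archetypes.items()
        }
        for motif, (a, b) in MOTIF_PAIRS.items():
            gp = fuzzy_sweep_pair(
                fuzzy_archetypes[a], fuzzy_archetypes[b], fuzzy_config,
                np.linspace(0, 1, 7), ph_grid,
            )
            assert label_motif(singles[a], singles[b], gp) == MotifLabel(motif)
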
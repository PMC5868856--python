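"""Sweeps, survival classification, Allee thresholds, and motif labeling."""

import numpy as np
import pytest

from phfeedback.model import SystemState, NULL_SPECIES
from phfeedback.outcomes import (
    MotifLabel,
    MotifConflictError,
    OutcomeGrid,
    classify_survival,
    sweep_single,
    sweep_pair,
    allee_threshold,
    species_character,
    label_motif,
    write_outcome_csv,
)
from phfeedback.simulate import Trajectory, integrate
from tests.conftest import MOTIF_PAIRS


class TestClassifySurvival:
    def test_final_state_rules(self):
        tr = Trajectory(t=[0, 1], n_a=[1.0, 0.0], n_b=[0.0, 10.0], p=[5, 5])
        assert classify_survival(tr, 0.01) == (False, True)
        tr = Trajectory(t=[0, 1], n_a=[1.0, 10.0], n_b=[0.0, 0.0], p=[5, 5])
        assert classify_survival(tr, 0.01) == (True, False)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            classify_survival(Trajectory(t=[], n_a=[], n_b=[], p=[]), 0.01)

    def test_threshold_insensitive_on_archetypes(self, archetypes):
        """Survival calls are stable across two decades of threshold."""
        species, env = archetypes
        finals = []
        for n0, p0 in [(0.5, 4.0), (0.01, 4.0), (5.0, 8.0), (0.1, 1.0)]:
            tr = integrate(SystemState(n0, 0, p0), species["lp"], NULL_SPECIES, env, 200)
            finals.append(tr)
        for thr in (1e-2 * 10, 1e-3 * 10, 1e-4 * 10):
            calls = [classify_survival(tr, thr)[0] for tr in finals]
            assert calls == [classify_survival(tr, 0.01)[0] for tr in finals]


class TestSweeps:
    def test_self_benefiting_has_allee_wedge(self, single_sweeps_small):
        grid = single_sweeps_small["lp"]
        assert species_character(grid) == "conditional"
        # survival monotone (a step) in initial density within each p column
        s = grid.a_survives
        assert np.all(np.diff(s.astype(int), axis=0) >= 0)

    def test_self_harming_extinct_everywhere(self, single_sweeps_small):
        for key in ("pv", "sm"):
            assert species_character(single_sweeps_small[key]) == "suicide"
            assert not single_sweeps_small[key].a_survives.any()

    def test_pair_boundary_rows_match_monocultures(self, archetypes, small_grids):
        species, env = archetypes
        lp, ca = species["lp"], species["ca"]
        p0 = small_grids["p0"]
        gp = sweep_pair(lp, ca, env, np.array([0.0, 0.5, 1.0]), p0, total_density=1.0)
        g_b = sweep_single(ca, env, np.array([1.0]), p0)
        g_a = sweep_single(lp, env, np.array([1.0]), p0)
        np.testing.assert_array_equal(gp.b_survives[0], g_b.a_survives[0])
        np.testing.assert_array_equal(gp.a_survives[-1], g_a.a_survives[0])
        # and the coculture boundary rows agree with their embedded references
        np.testing.assert_array_equal(gp.a_alone_survives[-1], gp.a_survives[-1])
        np.testing.assert_array_equal(gp.b_alone_survives[0], gp.b_survives[0])

    def test_empty_grid_rejected(self, archetypes):
        species, env = archetypes
        with pytest.raises(ValueError):
            sweep_single(species["lp"], env, np.array([]), np.array([5.0]))

    def test_fraction_out_of_range_rejected(self, archetypes):
        species, env = archetypes
        with pytest.raises(ValueError):
            sweep_pair(species["lp"], species["ca"], env, np.array([0.0, 1.5]), np.array([5.0]))

    def test_outcome_csv_deterministic(self, tmp_path, archetypes):
        species, env = archetypes
        grids = [
            sweep_single(species["lp"], env, np.geomspace(0.01, 5, 4), np.linspace(2, 8, 4))
            for _ in range(2)
        ]
        paths = []
        for i, g in enumerate(grids):
            path = tmp_path / f"g{i}.csv"
            write_outcome_csv(g, path, meta={"seed": 0})
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestAlleeThreshold:
    def test_matches_brute_force_scan(self, archetypes):
        species, env = archetypes
        lp = species["lp"]
        p0 = 4.0  # adverse: needs self-acidification to reach its optimum
        thr = allee_threshold(lp, env, p0)
        assert thr is not None
        scan = np.geomspace(1e-3, 9.0, 400)
        surv = np.array(
            [
                integrate(SystemState(n0, 0, p0), lp, NULL_SPECIES, env, 200).n_a[-1] >= 0.01
                for n0 in scan
            ]
        )
        idx = int(np.argmax(surv))
        assert surv[idx]  # the scan does find survivors
        lo, hi = scan[idx - 1], scan[idx]
        assert lo / 1.01 <= thr <= hi * 1.01

    def test_absent_at_favorable_p0(self, archetypes):
        species, env = archetypes
        lp = species["lp"]
        assert allee_threshold(lp, env, lp.p_pref) is None

    def test_weaker_drive_raises_threshold(self, archetypes):
        """A weaker pH drive (stronger buffering analog) needs more cells."""
        species, env = archetypes
        lp = species["lp"]
        thresholds = [
            allee_threshold(lp.with_(c=c), env, 4.0) for c in (0.1, 0.05, 0.025)
        ]
        assert all(t is not None for t in thresholds)
        assert thresholds[0] < thresholds[1] < thresholds[2]


def _grid(a, b, osc=None, alone_a=None, alone_b=None, kind="pair"):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    shape = a.shape
    return OutcomeGrid(
        axis1=np.linspace(0, 1, shape[0]),
        axis2=np.linspace(1, 9, shape[1]),
        a_survives=a,
        b_survives=b,
        n_a_final=a.astype(float),
        n_b_final=b.astype(float),
        p_final=np.full(shape, 5.0),
        oscillatory=np.zeros(shape, bool) if osc is None else np.asarray(osc, bool),
        kind=kind,
        a_alone_survives=None if alone_a is None else np.asarray(alone_a, bool),
        b_alone_survives=None if alone_b is None else np.asarray(alone_b, bool),
    )


class TestMotifRules:
    """Rule-level checks on constructed grids (no integration)."""

    def _singles(self, a_pattern, b_pattern):
        z = np.zeros((3, 3), bool)
        ga = _grid(a_pattern, z, kind="single")
        gb = _grid(b_pattern, z, kind="single")
        return ga, gb

    def test_bistability_needs_both_sole_winner_regions(self):
        full = np.ones((3, 3), bool)
        ga, gb = self._singles(full, full)
        # winner flips with the initial fraction within every initial-p column
        only_a = np.array([[1, 1, 1], [1, 1, 1], [0, 0, 0]], bool)
        gp = _grid(only_a, ~only_a, alone_a=full, alone_b=full)
        assert label_motif(ga, gb, gp) == MotifLabel.BISTABILITY
        # winner selected purely by initial p (niche partitioning) is not
        only_a_by_p = np.array([[1, 1, 0]] * 3, bool)
        gp2 = _grid(only_a_by_p, ~only_a_by_p, alone_a=full, alone_b=full)
        assert label_motif(ga, gb, gp2) != MotifLabel.BISTABILITY

    def test_successive_growth_from_rescued_cells(self):
        dead = np.zeros((3, 3), bool)
        allee = np.array([[0, 0, 0], [1, 1, 1], [1, 1, 1]], bool)
        ga, gb = self._singles(dead, allee)  # A is the self-killer
        b_pair = np.ones((3, 3), bool)
        gp = _grid(dead, b_pair, alone_a=dead, alone_b=allee)
        assert label_motif(ga, gb, gp) == MotifLabel.SUCCESSIVE_GROWTH

    def test_extended_suicide_from_murdered_cells(self):
        dead = np.zeros((3, 3), bool)
        robust = np.ones((3, 3), bool)
        ga, gb = self._singles(dead, robust)
        gp = _grid(dead, dead, alone_a=dead, alone_b=robust)
        assert label_motif(ga, gb, gp) == MotifLabel.EXTENDED_SUICIDE

    def test_stabilization_from_mutual_rescue(self):
        dead = np.zeros((3, 3), bool)
        ga, gb = self._singles(dead, dead)
        both = np.array([[0, 1, 0]] * 3, bool)
        gp = _grid(both, both, alone_a=dead, alone_b=dead)
        assert label_motif(ga, gb, gp) == MotifLabel.STABILIZATION

    def test_conflict_raises_in_strict_mode(self):
        dead = np.zeros((3, 3), bool)
        allee = np.array([[0, 0, 0], [1, 1, 1], [1, 1, 1]], bool)
        ga, gb = self._singles(dead, allee)
        # B is both rescued somewhere and murdered elsewhere
        b_pair = np.array([[1, 1, 1], [0, 0, 0], [0, 0, 0]], bool)
        gp = _grid(dead, b_pair, alone_a=dead, alone_b=allee)
        with pytest.raises(MotifConflictError):
            label_motif(ga, gb, gp, strict=True)
        assert label_motif(ga, gb, gp) == MotifLabel.SUCCESSIVE_GROWTH  # ordered

    def test_identical_self_benefiting_species_never_bistable(self):
        full = np.ones((3, 3), bool)
        ga, gb = self._singles(full, full)
        gp = _grid(full, full, alone_a=full, alone_b=full)
        assert label_motif(ga, gb, gp) in (MotifLabel.COEXISTENCE, MotifLabel.EXCLUSION)

    def test_missing_alone_references_rejected(self):
        full = np.ones((3, 3), bool)
        ga, gb = self._singles(full, full)
        gp = _grid(full, full)
        with pytest.raises(ValueError):
            label_motif(ga, gb, gp)


class TestArchetypeMotifs:
    def test_canonical_pairs_reproduce_their_motifs(
        self, single_sweeps_small, pair_sweeps_small
    ):
        for motif, (a, b) in MOTIF_PAIRS.items():
            got = label_motif(
                single_sweeps_small[a], single_sweeps_small[b], pair_sweeps_small[motif]
            )
            assert got == MotifLabel(motif)

    def test_extended_suicide_low_killer_corner_oscillates(self, pair_sweeps_small):
        gp = pair_sweeps_small["extended_suicide"]
        low_killer = gp.oscillatory[: len(gp.axis1) // 2 + 1]
        assert low_killer.any()
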
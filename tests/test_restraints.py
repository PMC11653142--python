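import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexrestrain.errors import MalformedInput, MissingScore, MissingSS, RangeError
from flexrestrain.restraints import (
    CategoryRules,
    Restraint,
    RestraintConfig,
    RestraintMode,
    RestraintSet,
    StrengthMatrix,
    assign_category,
    generate_restraints,
    pair_strength,
    read_restraints,
    restraint_energy,
    subsample_restraints,
    total_restraint_energy,
    write_restraints,
)
from flexrestrain.structure import ProteinStructure, Residue, SecondaryStructure

from conftest import random_toy_structure
from oracle import brute_force_restraints

HELIX = SecondaryStructure.HELIX
SHEET = SecondaryStructure.SHEET
TURN = SecondaryStructure.TURN
COIL = SecondaryStructure.COIL

ALL_MODES = list(RestraintMode)


def structure_with_pair(d, plddt_i, plddt_j, ss_i=COIL, ss_j=COIL, n=11):
    """n residues; only residues 0 and n-1 are near each other (distance d),
    the rest are parked far away so exactly one candidate pair exists."""
    residues = [Residue("A", 1, ca=np.zeros(3), plddt=plddt_i, ss=ss_i)]
    for k in range(1, n - 1):
        residues.append(
            Residue("A", k + 1, ca=np.array([500.0 + 100.0 * k, 0, 0]), plddt=70.0, ss=COIL)
        )
    residues.append(Residue("A", n, ca=np.array([d, 0.0, 0.0]), plddt=plddt_j, ss=ss_j))
    return ProteinStructure(residues)


class TestAssignCategory:
    @pytest.mark.parametrize(
        "ss,plddt,expected",
        [
            (COIL, 40.0, 0),   # base 0, low-confidence bump clamps at 0
            (HELIX, 95.0, 3),  # base 2 + high-confidence bump
            (TURN, 60.0, 1),   # base 1, mid confidence
            (SHEET, 45.0, 1),  # base 2 − low-confidence bump
            (COIL, 95.0, 1),
            (COIL, 50.0, 0),   # boundary: 50 is not "below 50"
            (HELIX, 90.0, 3),  # boundary: 90 reaches the high cutoff
        ],
    )
    def test_base_plus_bump(self, ss, plddt, expected):
        assert assign_category(ss, plddt) == expected

    def test_missing_score_rejected(self):
        with pytest.raises(MissingScore):
            assign_category(HELIX, None)

    @given(
        ss=st.sampled_from(list(SecondaryStructure)),
        lo=st.floats(0, 100),
        hi=st.floats(0, 100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_plddt(self, ss, lo, hi):
        lo, hi = sorted([lo, hi])
        assert assign_category(ss, lo) <= assign_category(ss, hi)


class TestPairStrength:
    @pytest.mark.parametrize(
        "a,b,expected", [(0, 3, 0.0), (2, 3, 1.0), (1, 2, 0.5), (0, 0, 0.0), (1, 1, 0.5)]
    )
    def test_default_matrix(self, a, b, expected):
        assert pair_strength(a, b) == expected

    def test_symmetric(self):
        for a in range(4):
            for b in range(4):
                assert pair_strength(a, b) == pair_strength(b, a)

    def test_custom_matrix_validation(self):
        bad = np.zeros((4, 4))
        bad[0, 1] = 0.7  # asymmetric
        with pytest.raises(RangeError):
            StrengthMatrix(bad)
        with pytest.raises(RangeError):
            StrengthMatrix(np.full((4, 4), 1.5))


class TestGenerateRestraints:
    def test_min_mode_weight_is_min_plddt_over_100(self):
        s = structure_with_pair(7.2, 80.0, 60.0)
        rset = generate_restraints(s, RestraintConfig(mode=RestraintMode.MIN))
        assert len(rset) == 1
        r = rset.restraints[0]
        assert r.weight == pytest.approx(0.60)
        assert r.d0 == pytest.approx(7.2)
        assert r.slope_min == pytest.approx(0.60 * 3.5)
        assert r.slope_max == pytest.approx(0.60 * 0.5)

    def test_min_mode_floor_drops_low_confidence_pairs(self):
        s = structure_with_pair(7.2, 45.0, 90.0)
        assert len(generate_restraints(s, RestraintConfig(mode=RestraintMode.MIN))) == 0

    def test_floor_boundary_half_strength_passes(self):
        s = structure_with_pair(7.2, 50.0, 50.0)
        rset = generate_restraints(s, RestraintConfig(mode=RestraintMode.MIN))
        assert len(rset) == 1 and rset.restraints[0].weight == pytest.approx(0.5)

    def test_plddt2_requires_both_above_cutoff(self):
        s = structure_with_pair(7.2, 49.0, 90.0)
        assert len(generate_restraints(s, RestraintConfig(mode=RestraintMode.PLDDT2))) == 0
        rset = generate_restraints(s, RestraintConfig(mode=RestraintMode.PLDDT1))
        assert len(rset) == 1 and rset.restraints[0].weight == 1.0

    def test_cutoff_is_strictly_greater_than(self):
        s = structure_with_pair(7.2, 50.0, 50.0)
        assert len(generate_restraints(s, RestraintConfig(mode=RestraintMode.PLDDT2))) == 0
        assert len(generate_restraints(s, RestraintConfig(mode=RestraintMode.PLDDT1))) == 0

    def test_ss2_restrains_regular_pairs_only(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 9, size=(20, 3))
        residues = [
            Residue("A", i + 1, ca=coords[i], plddt=80.0, ss=HELIX if i < 10 else COIL)
            for i in range(20)
        ]
        s = ProteinStructure(residues)
        pairs = generate_restraints(s, RestraintConfig(mode=RestraintMode.SS2)).pair_set()
        assert (2, 7) in pairs
        assert all(not (i >= 10 or j >= 10) for i, j in pairs)
        pairs1 = generate_restraints(s, RestraintConfig(mode=RestraintMode.SS1)).pair_set()
        assert (2, 14) in pairs1

    def test_sequence_gap_excludes_close_pairs(self):
        rng = np.random.default_rng(4)
        s = random_toy_structure(rng, 10, 10)
        for gap in (1, 3, 5):
            cfg = RestraintConfig(mode=RestraintMode.ALL, min_seq_gap=gap)
            assert all(r.j - r.i >= gap for r in generate_restraints(s, cfg))

    def test_missing_annotations_rejected(self):
        bare = ProteinStructure(
            [Residue("A", i + 1, ca=np.array([3.8 * i, 0, 0])) for i in range(6)]
        )
        with pytest.raises(MissingScore):
            generate_restraints(bare, RestraintConfig(mode=RestraintMode.MIN))
        with pytest.raises(MissingSS):
            generate_restraints(bare, RestraintConfig(mode=RestraintMode.SS2))

    def test_residues_without_ca_are_never_restrained(self):
        residues = [
            Residue("A", i + 1, ca=None if i == 2 else np.array([0.0, 0.0, 2.0 * i]),
                    plddt=90.0, ss=HELIX)
            for i in range(8)
        ]
        s = ProteinStructure(residues)
        rset = generate_restraints(s, RestraintConfig(mode=RestraintMode.ALL))
        assert all(2 not in (r.i, r.j) for r in rset)

    @pytest.mark.parametrize("mode", ALL_MODES)
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(17)
        cfg = RestraintConfig(mode=mode)
        for _ in range(10):
            s = random_toy_structure(rng)
            got = [(r.i, r.j, r.d0, r.weight) for r in generate_restraints(s, cfg)]
            expected = brute_force_restraints(s, cfg)
            assert [(i, j) for i, j, *_ in got] == [(i, j) for i, j, *_ in expected]
            np.testing.assert_allclose(
                [x[2:] for x in got], [x[2:] for x in expected], rtol=0, atol=1e-12
            )

    def test_mode_subset_laws(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            s = random_toy_structure(rng)
            pairs = {
                m: generate_restraints(s, RestraintConfig(mode=m)).pair_set()
                for m in (RestraintMode.SS2, RestraintMode.SS1, RestraintMode.ALL,
                          RestraintMode.PLDDT2, RestraintMode.PLDDT1)
            }
            assert pairs[RestraintMode.SS2] <= pairs[RestraintMode.SS1] <= pairs[RestraintMode.ALL]
            assert pairs[RestraintMode.PLDDT2] <= pairs[RestraintMode.PLDDT1] <= pairs[RestraintMode.ALL]

    def test_raising_plddt_never_weakens(self):
        rng = np.random.default_rng(29)
        s = random_toy_structure(rng, 12, 16)
        k = int(rng.integers(len(s)))
        bumped = s.with_residues(
            [dataclasses.replace(r, plddt=min(100.0, r.plddt + 30.0)) if i == k else r
             for i, r in enumerate(s)]
        )
        for mode in (RestraintMode.MIN, RestraintMode.MAX, RestraintMode.MEAN):
            lo = generate_restraints(s, RestraintConfig(mode=mode))
            hi = generate_restraints(bumped, RestraintConfig(mode=mode))
            hi_w = {(r.i, r.j): r.weight for r in hi}
            for r in lo:
                assert hi_w[(r.i, r.j)] >= r.weight - 1e-12
        for mode in (RestraintMode.PLDDT1, RestraintMode.PLDDT2):
            lo = generate_restraints(s, RestraintConfig(mode=mode))
            hi = generate_restraints(bumped, RestraintConfig(mode=mode))
            assert lo.pair_set() <= hi.pair_set()

    def test_geometric_filters_hold_exhaustively(self):
        rng = np.random.default_rng(31)
        for mode in ALL_MODES:
            s = random_toy_structure(rng)
            cfg = RestraintConfig(mode=mode)
            for r in generate_restraints(s, cfg):
                assert r.d0 <= cfg.max_distance
                assert r.j - r.i >= cfg.min_seq_gap


def _dummy_set(n, seed=0):
    rng = np.random.default_rng(seed)
    restraints = [
        Restraint(i=k, j=k + 5, id_i=("A", k + 1, None), id_j=("A", k + 6, None),
                  d0=float(rng.uniform(4, 11)), weight=1.0, slope_min=3.5, slope_max=0.5)
        for k in range(n)
    ]
    return RestraintSet(restraints, RestraintConfig(mode=RestraintMode.ALL))


class TestSubsample:
    def test_exact_count_removed(self):
        out = subsample_restraints(_dummy_set(100), 0.05, seed=7503)
        assert len(out) == 95

    def test_zero_drop_is_identity_and_full_drop_empties(self):
        rset = _dummy_set(40)
        assert subsample_restraints(rset, 0.0, 1).restraints == rset.restraints
        assert len(subsample_restraints(rset, 1.0, 1)) == 0

    def test_config_drop_fraction_subsamples_during_generation(self, helix_coil_structure):
        full = generate_restraints(helix_coil_structure, RestraintConfig(mode=RestraintMode.ALL))
        dropped = generate_restraints(
            helix_coil_structure,
            RestraintConfig(mode=RestraintMode.ALL, drop_fraction=0.5, seed=99),
        )
        assert len(dropped) == len(full) - round(0.5 * len(full))
        assert dropped.pair_set() <= full.pair_set()

    def test_deterministic_and_order_preserving(self):
        rset = _dummy_set(60)
        a = subsample_restraints(rset, 0.25, seed=11)
        b = subsample_restraints(rset, 0.25, seed=11)
        assert a.restraints == b.restraints
        kept_idx = [rset.restraints.index(r) for r in a.restraints]
        assert kept_idx == sorted(kept_idx)


def _restraint(w=1.0, d0=8.0, min_force=3.5, max_force=0.5):
    return Restraint(i=0, j=5, id_i=("A", 1, None), id_j=("A", 6, None), d0=d0,
                     weight=w, slope_min=w * min_force, slope_max=w * max_force)


class TestRestraintEnergy:
    def test_flat_bottom_and_linear_arms(self):
        r = _restraint()
        assert restraint_energy(r.d0, r) == 0.0
        assert restraint_energy(r.d0 + 1.0, r) == 0.0  # boundary of the flat bottom
        assert restraint_energy(r.d0 - 1.0, r) == 0.0
        assert restraint_energy(r.d0 + 2.5, r) == pytest.approx(0.5 * 1.5)
        assert restraint_energy(r.d0 - 2.0, r) == pytest.approx(3.5 * 1.0)

    def test_continuous_at_kinks(self):
        r = _restraint(w=0.73)
        eps = 1e-7
        for kink in (r.d0 - 1.0, r.d0 + 1.0):
            assert abs(restraint_energy(kink + eps, r) - restraint_energy(kink - eps, r)) < 1e-6
            assert restraint_energy(kink, r) == 0.0

    def test_nonnegative_and_monotone_outside_flat_bottom(self):
        r = _restraint(w=0.5)
        devs = np.linspace(0, 6, 200)
        up = [restraint_energy(r.d0 + 1.0 + d, r) for d in devs]
        down = [restraint_energy(r.d0 - 1.0 - d, r) for d in devs if r.d0 - 1.0 - d > 0]
        assert all(e >= 0 for e in up + down)
        assert np.all(np.diff(up) >= 0) and np.all(np.diff(down) >= 0)

    def test_quadratic_shape_option(self):
        r = _restraint()
        assert restraint_energy(r.d0 + 3.0, r, penalty="quadratic") == pytest.approx(0.5 * 4.0)
        assert restraint_energy(r.d0 - 2.0, r, penalty="quadratic") == pytest.approx(3.5 * 1.0)

    def test_weight_scales_both_arms(self):
        full, half = _restraint(1.0), _restraint(0.5)
        d = full.d0 + 2.0
        assert restraint_energy(d, half) == pytest.approx(0.5 * restraint_energy(d, full))


class TestTotalEnergy:
    def test_zero_on_input_coordinates(self, helix_coil_structure):
        s = helix_coil_structure
        rset = generate_restraints(s, RestraintConfig(mode=RestraintMode.ALL))
        assert total_restraint_energy(s.ca_coords(), rset) == 0.0

    def test_dilation_costs_energy(self, helix_coil_structure):
        s = helix_coil_structure
        rset = generate_restraints(s, RestraintConfig(mode=RestraintMode.ALL))
        assert total_restraint_energy(1.5 * s.ca_coords(), rset) > 0.0

    def test_additive_over_partition(self, helix_coil_structure):
        s = helix_coil_structure
        rset = generate_restraints(s, RestraintConfig(mode=RestraintMode.ALL))
        coords = s.ca_coords() * 1.3
        half = len(rset) // 2
        a = RestraintSet(rset.restraints[:half], rset.config)
        b = RestraintSet(rset.restraints[half:], rset.config)
        total = total_restraint_energy(coords, rset)
        assert total == pytest.approx(
            total_restraint_energy(coords, a) + total_restraint_energy(coords, b)
        )

    def test_missing_coordinates_rejected(self):
        rset = _dummy_set(3)
        with pytest.raises(IndexError):
            total_restraint_energy(np.zeros((4, 3)), rset)


class TestRestraintIO:
    def test_roundtrip(self, helix_coil_structure):
        s = helix_coil_structure
        rset = generate_restraints(s, RestraintConfig())
        back = read_restraints(write_restraints(rset), s)
        assert len(back) == len(rset)
        for orig, rt in zip(rset, back):
            assert (rt.i, rt.j, rt.id_i, rt.id_j) == (orig.i, orig.j, orig.id_i, orig.id_j)
            assert rt.d0 == pytest.approx(orig.d0, abs=1e-3)
            assert rt.weight == pytest.approx(orig.weight, abs=1e-3)
            assert rt.slope_min == pytest.approx(orig.weight * 3.5, abs=1e-2)

    def test_single_line_parse(self):
        rset = read_restraints("A:12 A:40 9.135 1.000\n")
        r = rset.restraints[0]
        assert r.id_i == ("A", 12, None) and r.id_j == ("A", 40, None)
        assert r.d0 == pytest.approx(9.135) and r.weight == 1.0

    def test_bad_line_reports_line_number(self):
        text = "A:1 A:9 8.000 1.000\nA:12 A:40 abc 1.0\n"
        with pytest.raises(MalformedInput, match="line 2"):
            read_restraints(text)

    def test_byte_identical_for_identical_inputs(self, helix_coil_structure):
        cfg = RestraintConfig()
        a = write_restraints(generate_restraints(helix_coil_structure, cfg))
        b = write_restraints(generate_restraints(helix_coil_structure, cfg))
        assert a == b

    def test_header_carries_config(self, helix_coil_structure):
        cfg = RestraintConfig(mode=RestraintMode.MEAN, max_distance=9.0, min_force=2.0)
        text = write_restraints(generate_restraints(helix_coil_structure, cfg))
        back = read_restraints(text)
        assert back.config.mode is RestraintMode.MEAN
        assert back.config.max_distance == 9.0
        assert back.config.min_force == 2.0

    def test_insertion_codes_roundtrip(self):
        r = Restraint(i=0, j=4, id_i=("A", 52, "A"), id_j=("A", 60, None),
                      d0=7.5, weight=0.5, slope_min=1.75, slope_max=0.25)
        back = read_restraints(write_restraints(RestraintSet([r])))
        assert back.restraints[0].id_i == ("A", 52, "A")
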
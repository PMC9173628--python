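"""Diabatic energies, ground surface, mapping potential, and the topology format."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evbmech.constants import COULOMB_K
from evbmech.energy import (diabatic_energy, diabatic_energy_forces, energy_gap,
                            ground_state, mapping_energy, mapping_eval)
from evbmech.topology import (AngleTerm, BondTerm, CouplingTerm, DiabaticState,
                              EVBTopology, TopologyError, TopologyParseError,
                              TorsionTerm, read_topology, write_topology)


def two_atom_topology(kind="morse", charges=(0.0, 0.0), lj=False):
    if kind == "morse":
        bonds = [BondTerm(0, 1, "morse", 100.0, 1.5, 1.09)]
    else:
        bonds = [BondTerm(0, 1, "harmonic", 300.0, 1.0)]
    a, b = (480.0, 20.7) if lj else (0.0, 0.0)
    states = [
        DiabaticState(1, bonds, [], [], np.array(charges), 0.0),
        DiabaticState(2, [], [], [], np.array(charges), 0.0),
    ]
    return EVBTopology(atom_names=["A", "B"], atom_types=["X", "X"],
                       masses=np.array([12.0, 12.0]), lj_a={"X": a}, lj_b={"X": b},
                       states=states, couplings=[CouplingTerm(1, 2, 0.0)])


class TestDiabaticEnergy:
    def test_morse_minimum_is_minus_de(self):
        top = two_atom_topology("morse")
        coords = np.array([[0.0, 0.0, 0.0], [1.09, 0.0, 0.0]])
        assert diabatic_energy(top, 1, coords).total == pytest.approx(-100.0)

    def test_morse_dissociation_limit_zero(self):
        top = two_atom_topology("morse")
        coords = np.array([[0.0, 0.0, 0.0], [80.0, 0.0, 0.0]])
        assert diabatic_energy(top, 1, coords).total == pytest.approx(0.0, abs=1e-9)

    def test_coulomb_constant(self):
        # two +1 charges at 3.32 Å, no bonded path between them
        states = [DiabaticState(1, [], [], [], np.array([1.0, 1.0]), 0.0),
                  DiabaticState(2, [], [], [], np.array([1.0, 1.0]), 0.0)]
        top = EVBTopology(["A", "B"], ["X", "X"], np.array([1.0, 1.0]),
                          {"X": 0.0}, {"X": 0.0}, states, [])
        coords = np.array([[0.0, 0.0, 0.0], [3.32, 0.0, 0.0]])
        e = diabatic_energy(top, 1, coords).electrostatic
        assert e == pytest.approx(COULOMB_K / 3.32)
        assert e == pytest.approx(100.0, abs=0.05)

    def test_breakdown_total_is_sum(self):
        top = two_atom_topology("morse", charges=(0.3, -0.3), lj=True)
        # bonded pair is excluded from nonbonded, so use a third state-less check:
        coords = np.array([[0.0, 0.0, 0.0], [1.3, 0.4, -0.2]])
        bd = diabatic_energy(top, 1, coords)
        assert bd.total == pytest.approx(
            bd.bond + bd.angle + bd.torsion + bd.lj + bd.electrostatic + bd.shift,
            abs=1e-12)

    def test_shape_error(self):
        top = two_atom_topology()
        with pytest.raises(TopologyError, match="shape"):
            diabatic_energy(top, 1, np.zeros((3, 3)))


class TestForcesFiniteDifference:
    def test_all_terms_match_central_differences(self):
        # one topology exercising morse, harmonic, angle, torsion, LJ, Coulomb
        rng = np.random.default_rng(4)
        n = 5
        charges = np.array([0.4, -0.3, 0.2, -0.2, -0.1])
        bonds = [BondTerm(0, 1, "morse", 80.0, 1.8, 1.1),
                 BondTerm(1, 2, "harmonic", 250.0, 1.4),
                 BondTerm(2, 3, "harmonic", 250.0, 1.4),
                 BondTerm(3, 4, "harmonic", 250.0, 1.0)]
        angles = [AngleTerm(0, 1, 2, 40.0, 109.0), AngleTerm(1, 2, 3, 40.0, 120.0)]
        torsions = [TorsionTerm(0, 1, 2, 3, 1.5, 3, 0.0),
                    TorsionTerm(1, 2, 3, 4, 0.8, 2, 180.0)]
        states = [DiabaticState(1, bonds, angles, torsions, charges, 0.0),
                  DiabaticState(2, bonds[:1], angles[:1], [], -charges, 2.0)]
        top = EVBTopology([f"A{i}" for i in range(n)], ["X"] * n,
                          np.full(n, 12.0), {"X": 300.0}, {"X": 15.0}, states,
                          [CouplingTerm(1, 2, 1.0)])
        coords = np.array([[0.0, 0.0, 0.0], [1.1, 0.2, -0.1], [1.9, 1.3, 0.3],
                           [3.2, 1.5, -0.4], [4.0, 0.7, 0.5]])
        coords += 0.05 * rng.normal(size=coords.shape)
        for state in (1, 2):
            _, f = diabatic_energy_forces(top, state, coords)
            h = 1e-5
            for i in range(n):
                for c in range(3):
                    cp, cm = coords.copy(), coords.copy()
                    cp[i, c] += h
                    cm[i, c] -= h
                    fn = -(diabatic_energy(top, state, cp).total
                           - diabatic_energy(top, state, cm).total) / (2 * h)
                    assert f[i, c] == pytest.approx(fn, abs=1e-5)

    def test_fast_path_matches_reference_path(self):
        from evbmech.fixtures import make_active_site_fixture

        f = make_active_site_fixture(3, 12, "two_mg")
        coords = f.system.coordinates + 0.02 * np.random.default_rng(0).normal(
            size=f.system.coordinates.shape)
        lam = np.array([0.3, 0.5, 0.2])
        eps, fmap = mapping_eval(f.topology, coords, lam)
        ref_eps, ref_f = [], np.zeros_like(coords)
        for k, stt in enumerate(f.topology.states):
            bd, fk = diabatic_energy_forces(f.topology, stt.index, coords)
            ref_eps.append(bd.total)
            ref_f += lam[k] * fk
        assert np.allclose(eps, ref_eps, atol=1e-8)
        assert np.allclose(fmap, ref_f, atol=1e-8)


class TestGroundState:
    def test_degenerate_pair(self):
        e, w = ground_state(np.array([3.0, 3.0]), np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert e == pytest.approx(1.0)
        assert w == pytest.approx([0.5, 0.5])

    def test_zero_coupling_picks_minimum(self):
        e, w = ground_state(np.array([5.0, 2.0, 7.0]), np.zeros((3, 3)))
        assert e == pytest.approx(2.0)
        assert np.argmax(w) == 1

    def test_closed_form_asymmetric(self):
        e, w = ground_state(np.array([0.0, 10.0]), np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert e == pytest.approx(5.0 - np.sqrt(29.0))
        assert w.sum() == pytest.approx(1.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(TopologyError):
            ground_state(np.array([0.0, 1.0]), np.array([[0.0, 1.0], [2.0, 0.0]]))

    @given(e1=st.floats(-50, 50), e2=st.floats(-50, 50), e3=st.floats(-50, 50),
           h=st.floats(0.01, 10), shift=st.floats(-20, 20))
    @settings(max_examples=100, deadline=None)
    def test_bound_trace_and_shift_invariance(self, e1, e2, e3, h, shift):
        eps = np.array([e1, e2, e3])
        hm = np.array([[0.0, h, 0.0], [h, 0.0, h], [0.0, h, 0.0]])
        eg, w = ground_state(eps, hm)
        assert eg < eps.min() + 1e-9
        assert w.sum() == pytest.approx(1.0)
        eg2, w2 = ground_state(eps + shift, hm)
        assert eg2 == pytest.approx(eg + shift, abs=1e-8)
        assert np.allclose(w2, w, atol=1e-8)

    def test_equality_iff_no_coupling(self):
        eps = np.array([1.0, 4.0])
        eg0, _ = ground_state(eps, np.zeros((2, 2)))
        assert eg0 == pytest.approx(eps.min())
        eg1, _ = ground_state(eps, np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert eg1 < eps.min()


class TestMappingAndGap:
    def test_endpoints_and_midpoint(self):
        eps = np.array([2.0, 4.0])
        assert mapping_energy(eps, np.array([1.0, 0.0])) == 2.0
        assert mapping_energy(eps, np.array([0.0, 1.0])) == 4.0
        assert mapping_energy(eps, np.array([0.5, 0.5])) == 3.0

    def test_three_state_endpoint(self):
        assert mapping_energy(np.array([1.0, 2.0, 7.0]), np.array([0.0, 0.0, 1.0])) == 7.0

    def test_off_simplex_rejected(self):
        with pytest.raises(TopologyError):
            mapping_energy(np.array([1.0, 2.0]), np.array([0.7, 0.7]))
        with pytest.raises(TopologyError):
            mapping_energy(np.array([1.0, 2.0]), np.array([-0.1, 1.1]))

    def test_gap_antisymmetric(self):
        eps = np.array([3.0, 1.0])
        assert energy_gap(eps, 0, 1) == 2.0
        assert energy_gap(eps, 1, 0) == -2.0
        assert energy_gap(np.array([5.0, 5.0]), 0, 1) == 0.0

    def test_gap_same_state_rejected(self):
        with pytest.raises(TopologyError):
            energy_gap(np.array([1.0, 2.0]), 1, 1)


class TestTopologyFormat:
    def test_round_trip(self, tmp_path, two_mg_fixture):
        p = tmp_path / "f.top"
        write_topology(two_mg_fixture.topology, p)
        top2 = read_topology(p)
        top1 = two_mg_fixture.topology
        assert top2.atom_names == top1.atom_names
        assert top2.atom_types == top1.atom_types
        assert top2.n_states == top1.n_states
        for s1, s2 in zip(top1.states, top2.states):
            assert np.allclose(s1.charges, s2.charges, atol=1e-6)
            assert s2.shift == pytest.approx(s1.shift, abs=1e-6)
            assert len(s1.bonds) == len(s2.bonds)
            assert len(s1.angles) == len(s2.angles)
        h1 = top1.coupling_matrix()
        h2 = top2.coupling_matrix()
        assert np.allclose(h1, h2, atol=1e-6)

    def test_parse_error_carries_line_number(self, tmp_path):
        p = tmp_path / "bad.top"
        p.write_text("[atoms]\n0 A X 12.0\n[state 1]\nbond 0 1 wiggly 1 2 3\n")
        with pytest.raises(TopologyParseError, match="line 4"):
            read_topology(p)

    def test_unknown_section(self, tmp_path):
        p = tmp_path / "bad.top"
        p.write_text("[garbage]\n")
        with pytest.raises(TopologyParseError, match="line 1"):
            read_topology(p)

    def test_exclusions_and_one_four_scaling(self):
        # linear chain 0-1-2-3: (0,1),(1,2),(2,3) bonded; (0,2),(1,3) are 1-3;
        # (0,3) is 1-4 and must carry the 0.5 scaling
        bonds = [BondTerm(i, i + 1, "harmonic", 100.0, 1.0) for i in range(3)]
        states = [DiabaticState(1, bonds, [], [], np.zeros(4), 0.0),
                  DiabaticState(2, bonds, [], [], np.zeros(4), 0.0)]
        top = EVBTopology([f"A{i}" for i in range(4)], ["X"] * 4, np.full(4, 12.0),
                          {"X": 1.0}, {"X": 1.0}, states, [])
        pairs = top.compiled_pairs()
        listed = set(zip(pairs["i"].tolist(), pairs["j"].tolist()))
        assert listed == {(0, 3)}
        assert pairs["scale_elec"][0] == 0.5
        assert pairs["scale_lj"][0] == 0.5

    def test_charge_bookkeeping(self, two_mg_fixture):
        for state in two_mg_fixture.topology.states:
            assert state.net_charge() == pytest.approx(1.0, abs=1e-9)
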
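"""LRA binding electrostatics, protonation Monte Carlo, TST, and pH energetics."""

import numpy as np
import pytest

from evbmech.constants import COULOMB_K, KB, KB_OVER_H
from evbmech.energetics import (DielectricModel, LRAProtocol, ProtonationModel,
                                group_binding_decomposition,
                                hydroxide_formation_energy, lra_binding,
                                mcpt_protonation, tst_convert)
from evbmech.sampling import EVBSystem
from evbmech.topology import CouplingTerm, DiabaticState, EVBTopology


def point_charge_system(charges, positions):
    n = len(charges)
    states = [DiabaticState(1, [], [], [], np.array(charges, dtype=float), 0.0),
              DiabaticState(2, [], [], [], np.array(charges, dtype=float), 0.0)]
    top = EVBTopology([f"Q{i}" for i in range(n)], ["X"] * n, np.full(n, 12.0),
                      {"X": 0.0}, {"X": 0.0}, states, [CouplingTerm(1, 2, 0.0)])
    return EVBSystem(top, np.array(positions, dtype=float))


FROZEN = LRAProtocol(n_configurations=2, steps_per_configuration=0, seed=0)


class TestLRABinding:
    def test_frozen_limit_closed_form(self):
        # single ligand charge q against single environment charge Q:
        # both groups are formally charged → ε_eff screening
        q, big_q, r = 1.0, -1.0, 4.0
        sys = point_charge_system([q, big_q], [[0, 0, 0], [r, 0, 0]])
        est = lra_binding(sys, [0], FROZEN, DielectricModel(4.0, 60.0))
        assert est.delta_g == pytest.approx(COULOMB_K * q * big_q / (60.0 * r))
        assert est.mean_charged == est.mean_uncharged

    def test_zero_ligand_charges_zero_energy(self):
        sys = point_charge_system([0.0, -1.0], [[0, 0, 0], [3.0, 0, 0]])
        est = lra_binding(sys, [0], FROZEN)
        assert est.delta_g == 0.0

    def test_linear_in_environment_charge(self):
        base = point_charge_system([1.0, -0.8], [[0, 0, 0], [5.0, 0, 0]])
        double = point_charge_system([1.0, -1.6], [[0, 0, 0], [5.0, 0, 0]])
        e1 = lra_binding(base, [0], FROZEN).delta_g
        e2 = lra_binding(double, [0], FROZEN).delta_g
        assert e2 == pytest.approx(2 * e1)

    def test_empty_ligand_rejected(self):
        sys = point_charge_system([1.0, -1.0], [[0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            lra_binding(sys, [])

    def test_phosphate_prefers_two_metals(self, two_mg_fixture):
        """PO₄³⁻ electrostatic binding is far more favorable with both Mg²⁺
        present than with none (ordering, not the published magnitudes)."""
        from evbmech.fixtures import make_active_site_fixture

        proto = LRAProtocol(n_configurations=2, steps_per_configuration=150, seed=3)
        results = {}
        for variant in ("two_mg", "no_mg"):
            f = make_active_site_fixture(1, 24, variant)
            pi = [i for i, a in enumerate(f.structure.atoms)
                  if a.residue_name == "PO4"]
            results[variant] = lra_binding(f.system, pi, proto,
                                           structure=f.structure).delta_g
        assert results["two_mg"] < results["no_mg"]


class TestGroupDecomposition:
    def _arg_mg(self, fixture):
        s = fixture.structure
        arg = [i for i, a in enumerate(s.atoms) if a.residue_number == 233]
        mg = [fixture.mg_a_index]
        charges = np.array([a.partial_charge or 0.0 for a in s.atoms])
        return s.coordinates, charges, arg, mg

    def test_subgroup_additivity(self, two_mg_fixture):
        coords, charges, arg, mg = self._arg_mg(two_mg_fixture)
        whole = group_binding_decomposition(coords, charges, arg, mg)
        parts = sum(group_binding_decomposition(coords, charges, [i], mg)
                    for i in arg)
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_nh2_is_the_only_favorable_fragment(self, two_mg_fixture):
        """The amino nitrogen that coordinates Mg_A carries the group's only
        negative (favorable) electrostatic term."""
        s = two_mg_fixture.structure
        coords, charges, arg, mg = self._arg_mg(two_mg_fixture)
        terms = {s.atoms[i].name: group_binding_decomposition(coords, charges, [i], mg)
                 for i in arg}
        assert terms["NH2"] < 0
        assert all(v > 0 for k, v in terms.items() if k != "NH2")

    def test_whole_group_unfavorable_for_cation_pair(self, two_mg_fixture):
        coords, charges, arg, mg = self._arg_mg(two_mg_fixture)
        assert group_binding_decomposition(coords, charges, arg, mg) > 0

    def test_doubling_dielectric_halves_terms(self, two_mg_fixture):
        coords, charges, arg, mg = self._arg_mg(two_mg_fixture)
        e1 = group_binding_decomposition(coords, charges, arg, mg,
                                         DielectricModel(4.0, 60.0))
        e2 = group_binding_decomposition(coords, charges, arg, mg,
                                         DielectricModel(4.0, 120.0))
        assert e1 == pytest.approx(2 * e2)

    def test_overlapping_groups_rejected(self, two_mg_fixture):
        coords, charges, arg, mg = self._arg_mg(two_mg_fixture)
        with pytest.raises(ValueError):
            group_binding_decomposition(coords, charges, arg, arg[:1])


def single_site(pka, ph):
    return ProtonationModel(["ASP"], np.array([pka]), np.array([0.0]),
                            np.array([-1.0]), np.zeros((1, 1)), ph=ph)


class TestMCPT:
    def test_half_protonated_at_pka(self):
        res = mcpt_protonation(single_site(7.0, 7.0), sweeps=20000, seed=1)
        assert res.probabilities[0] == pytest.approx(0.5, abs=0.02)

    def test_three_units_above_pka(self):
        res = mcpt_protonation(single_site(4.0, 7.0), sweeps=60000, seed=2)
        assert 3.3e-4 < res.probabilities[0] < 3e-3

    def test_coupled_pair_matches_enumeration(self):
        w = np.array([[0.0, 1.2], [1.2, 0.0]])
        model = ProtonationModel(["ASP", "HIS"], np.array([4.0, 6.5]),
                                 np.array([0.0, 1.0]), np.array([-1.0, 0.0]),
                                 w, ph=5.5)
        exact = model.enumerate_probabilities()
        res = mcpt_protonation(model, sweeps=40000, seed=3)
        assert np.allclose(res.probabilities, exact, atol=0.02)

    def test_twelve_sites_match_enumeration(self):
        rng = np.random.default_rng(7)
        n = 12
        pka = rng.uniform(3.5, 11.0, n)
        protonated_q = np.where(rng.random(n) < 0.5, 0.0, 1.0)
        deprotonated_q = protonated_q - 1.0
        pos = rng.uniform(-6, 6, (n, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, 1.0)
        w = COULOMB_K / (60.0 * np.maximum(d, 2.0))
        np.fill_diagonal(w, 0.0)
        model = ProtonationModel([f"S{i}" for i in range(n)], pka, protonated_q,
                                 deprotonated_q, w, ph=7.0)
        exact = model.enumerate_probabilities()
        res = mcpt_protonation(model, sweeps=30000, seed=4)
        assert np.allclose(res.probabilities, exact, atol=0.03)
        assert model.energy(res.best_state) <= model.energy(
            (exact > 0.5).astype(int)) + 1e-9

    def test_asymmetric_interaction_rejected(self):
        w = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            ProtonationModel(["A", "B"], np.array([4.0, 7.0]),
                             np.array([0.0, 1.0]), np.array([-1.0, 0.0]), w)


class TestTST:
    def test_round_trip_identity(self):
        for barrier in (5.0, 16.05, 25.0):
            rate = tst_convert("barrier_to_rate", barrier, 300.0)
            back = tst_convert("rate_to_barrier", rate, 300.0)
            assert back == pytest.approx(barrier, abs=1e-9)

    def test_zero_barrier_prefactor(self):
        assert tst_convert("barrier_to_rate", 0.0, 300.0) == pytest.approx(
            KB_OVER_H * 300.0)
        assert tst_convert("barrier_to_rate", 0.0, 300.0) == pytest.approx(
            6.25e12, rel=0.001)

    def test_observed_turnover_maps_into_printed_barrier_range(self):
        """k_cat = 12.4 s⁻¹ corresponds to an activation free energy inside
        the printed 16.0–16.1 kcal/mol band for some T in 298–300 K, and the
        midpoint barrier recovers the rate within its ±0.71 uncertainty."""
        barriers = [tst_convert("rate_to_barrier", 12.4, t)
                    for t in (298.0, 298.15, 299.0, 300.0)]
        assert any(16.0 <= b <= 16.1 for b in barriers)
        rates = [tst_convert("barrier_to_rate", 16.05, t)
                 for t in (298.0, 299.0, 300.0)]
        assert any(abs(r - 12.4) <= 0.71 for r in rates)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tst_convert("rate_to_barrier", -1.0)
        with pytest.raises(ValueError):
            tst_convert("sideways", 1.0)


class TestHydroxideFormation:
    def test_printed_value_at_physiological_ph(self):
        for t in (298.0, 298.15, 300.0):
            assert hydroxide_formation_energy(7.4, t) == pytest.approx(11.3, abs=0.1)

    def test_zero_at_formula_root(self):
        assert hydroxide_formation_energy(15.7) == pytest.approx(0.0, abs=1e-12)

    def test_mitochondrial_range_endpoint(self):
        assert hydroxide_formation_energy(7.0, 298.0) == pytest.approx(11.9, abs=0.05)

    def test_monotone_decreasing_in_ph_linear_in_t(self):
        phs = np.linspace(5.0, 9.0, 9)
        vals = [hydroxide_formation_energy(p) for p in phs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        v300 = hydroxide_formation_energy(7.4, 300.0)
        v600 = hydroxide_formation_energy(7.4, 600.0)
        assert v600 == pytest.approx(2 * v300)
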
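"""Calibration of the EVB gas-phase shift and coupling to a reference reaction.

A two-state leg has two free parameters: the relative gas-phase shift
Δα = α₂ − α₁, which moves the reaction free energy one-to-one, and the
constant coupling A, which depresses the adiabatic barrier below the
diabatic crossing. Calibration runs the full mapping/umbrella protocol on
the *reference* system (the same reacting fragments in a pure water
droplet), compares (ΔG‡, ΔG_rxn) with the reference targets, and iterates a
damped Newton step with the approximate Jacobian

    ∂ΔG_rxn/∂Δα ≈ 1,   ∂ΔG‡/∂Δα ≈ ½,   ∂ΔG‡/∂A ≈ −1,   ∂ΔG_rxn/∂A ≈ 0,

which is exact for symmetric equal-curvature parabolas and a good
preconditioner everywhere else. Window seeds are held fixed across
iterations so the parameter→observable map is deterministic. The calibrated
(Δα, A) are then frozen for the protein-model runs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .fep import ProfileError, extract_barrier, us_profile
from .sampling import EVBSystem, LangevinParams, MappingSchedule, run_mapping
from .topology import CouplingTerm, DiabaticState, EVBTopology

__all__ = ["CalibrationProtocol", "CalibrationResult", "CalibrationError",
           "calibrate", "extract_leg", "apply_leg_parameters"]


class CalibrationError(RuntimeError):
    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals or []


@dataclass
class CalibrationProtocol:
    schedule: MappingSchedule
    params: LangevinParams
    tolerance: float = 0.1      # kcal/mol on both targets
    max_iterations: int = 12
    damping: float = 0.8
    bin_width: float = 2.0


@dataclass
class CalibrationResult:
    alpha: float                # calibrated relative shift Δα on the product state
    coupling: float             # calibrated A
    iterations: int
    residuals: list[tuple[float, float]] = field(default_factory=list)
    barrier: float = float("nan")
    dg_rxn: float = float("nan")


def extract_leg(top: EVBTopology, state_i: int, state_j: int) -> EVBTopology:
    """Two-state copy of a topology for mapping one leg at a time."""
    states = [copy.deepcopy(top.state(state_i)), copy.deepcopy(top.state(state_j))]
    coupling = [c for c in top.couplings
                if {c.state_i, c.state_j} == {state_i, state_j}]
    return EVBTopology(
        atom_names=list(top.atom_names), atom_types=list(top.atom_types),
        masses=np.array(top.masses),
        lj_a=dict(top.lj_a), lj_b=dict(top.lj_b),
        states=states, couplings=list(coupling),
        evb_region=list(top.evb_region),
        scale14_elec=top.scale14_elec, scale14_lj=top.scale14_lj,
    )


def apply_leg_parameters(top: EVBTopology, alpha: float, coupling: float) -> EVBTopology:
    """New two-state topology with product-state shift α and coupling A."""
    if top.n_states != 2:
        raise ValueError("apply_leg_parameters expects a two-state leg")
    s1, s2 = top.states
    states = [
        DiabaticState(s1.index, s1.bonds, s1.angles, s1.torsions, s1.charges, s1.shift),
        DiabaticState(s2.index, s2.bonds, s2.angles, s2.torsions, s2.charges, alpha),
    ]
    couplings = [CouplingTerm(s1.index, s2.index, max(coupling, 0.0))]
    return EVBTopology(
        atom_names=list(top.atom_names), atom_types=list(top.atom_types),
        masses=np.array(top.masses),
        lj_a=dict(top.lj_a), lj_b=dict(top.lj_b),
        states=states, couplings=couplings, evb_region=list(top.evb_region),
        scale14_elec=top.scale14_elec, scale14_lj=top.scale14_lj,
    )


def measure_leg(system: EVBSystem, schedule: MappingSchedule,
                params: LangevinParams, bin_width: float = 2.0):
    """Run the mapping protocol and return (ΔG‡, ΔG_rxn, profile)."""
    windows = run_mapping(system, schedule, params)
    profile = us_profile(windows, params.temperature, bin_width)
    barrier, dg_rxn = extract_barrier(profile)
    return barrier, dg_rxn, profile


def calibrate(system: EVBSystem, reference_barrier: float,
              reference_reaction_free_energy: float,
              protocol: CalibrationProtocol,
              initial_alpha: float | None = None,
              initial_coupling: float | None = None) -> CalibrationResult:
    """Adjust (Δα, A) until the reference system reproduces its targets.

    ``system`` must carry a two-state topology (one leg). Raises
    :class:`CalibrationError` with the residual trajectory if the targets
    are not met within ``protocol.max_iterations``.
    """
    top = system.topology
    if top.n_states != 2:
        raise CalibrationError("calibration requires a two-state leg")
    if not (np.isfinite(reference_barrier) and np.isfinite(reference_reaction_free_energy)):
        raise CalibrationError("reference targets must be finite")
    alpha = top.states[1].shift if initial_alpha is None else initial_alpha
    coupling = (top.coupling_matrix()[0, 1] if initial_coupling is None
                else initial_coupling)
    residuals: list[tuple[float, float]] = []
    barrier = dg_rxn = float("nan")
    for it in range(1, protocol.max_iterations + 1):
        trial_top = apply_leg_parameters(top, alpha, coupling)
        trial_system = EVBSystem(trial_top, np.array(system.coordinates),
                                 system.boundary, list(system.distance_restraints),
                                 list(system.position_restraints), system.mobile.copy())
        try:
            barrier, dg_rxn, _ = measure_leg(trial_system, protocol.schedule,
                                             protocol.params, protocol.bin_width)
        except ProfileError as exc:
            raise CalibrationError(f"iteration {it}: {exc}", residuals) from exc
        r_b = barrier - reference_barrier
        r_g = dg_rxn - reference_reaction_free_energy
        residuals.append((r_b, r_g))
        if abs(r_b) <= protocol.tolerance and abs(r_g) <= protocol.tolerance:
            return CalibrationResult(alpha=alpha, coupling=coupling, iterations=it,
                                     residuals=residuals, barrier=barrier, dg_rxn=dg_rxn)
        # damped Newton step with the parabolic-limit Jacobian
        d_alpha = -protocol.damping * r_g
        d_coupling = protocol.damping * (r_b - 0.5 * r_g)
        alpha += d_alpha
        coupling = max(0.0, coupling + d_coupling)
    raise CalibrationError(
        f"calibration did not converge in {protocol.max_iterations} iterations "
        f"(last residuals: barrier {residuals[-1][0]:+.2f}, "
        f"ΔG_rxn {residuals[-1][1]:+.2f} kcal/mol)", residuals)
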
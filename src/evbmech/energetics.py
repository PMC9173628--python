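"""Simplified-LRA binding electrostatics, protonation Monte Carlo, and
closed-form kinetics/pH energetics.

The binding estimator is the linear-response electrostatic core of the
semi-macroscopic PDLD/S-LRA family: sample configurations with the ligand
charges on and off, average the screened ligand–environment Coulomb
interaction in both ensembles, and take the half-sum

    ΔG_bind ≈ ½ (⟨ΔU⟩_charged + ⟨ΔU⟩_uncharged).

Screening uses two dielectrics: an effective ε_eff = 60 between pairs of
formally charged groups and ε_p = 4 otherwise. The Langevin-dipole solvent
grid of full PDLD is deliberately not reproduced — outputs are labeled
"simplified-LRA" and absolute values are comparable only as orderings and
signs, not against full-protocol numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_K, KB, KB_OVER_H, LN10, ROOM_T
from .sampling import EVBSystem, LangevinParams, run_langevin
from .topology import DiabaticState, EVBTopology

__all__ = [
    "DielectricModel", "LRAProtocol", "BindingEstimate", "ProtonationModel",
    "ProtonationResult", "lra_binding", "group_binding_decomposition",
    "mcpt_protonation", "tst_convert", "hydroxide_formation_energy",
    "DEFAULT_PKA",
]

def _load_default_pka() -> dict[str, float]:
    from importlib.resources import files

    table = {}
    text = files("evbmech.data").joinpath("intrinsic_pka.tsv").read_text()
    for line in text.splitlines()[1:]:
        if line.strip():
            res, pka = line.split("\t")
            table[res] = float(pka)
    return table


# intrinsic pKa values for ionizable side chains (shipped data file)
DEFAULT_PKA = _load_default_pka()


@dataclass(frozen=True)
class DielectricModel:
    protein: float = 4.0       # ε_p for neutral-group pairs
    effective: float = 60.0    # ε_eff for charge-charge pairs

    def __post_init__(self):
        if self.protein < 1 or self.effective < 1:
            raise ValueError("dielectric constants must be ≥ 1")


@dataclass(frozen=True)
class LRAProtocol:
    n_configurations: int = 4
    steps_per_configuration: int = 2000  # 2 ps at 1 fs
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.n_configurations < 1:
            raise ValueError("need at least 1 configuration per charge state")


@dataclass
class BindingEstimate:
    delta_g: float
    mean_charged: float
    mean_uncharged: float
    label: str = "simplified-LRA"
    protocol: LRAProtocol | None = None
    equilibrated: bool = True

    def __post_init__(self):
        expected = 0.5 * (self.mean_charged + self.mean_uncharged)
        assert abs(self.delta_g - expected) < 1e-9


def _group_net_charges(charges: np.ndarray, groups: list[list[int]]) -> np.ndarray:
    return np.array([float(np.sum(charges[g])) for g in groups])


def _screen_matrix(charges: np.ndarray, group_of: np.ndarray,
                   group_charge: np.ndarray, dielectric: DielectricModel,
                   idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Per-pair dielectric: ε_eff when both atoms sit in formally charged
    groups (|net| ≥ 0.5 e), ε_p otherwise."""
    charged = np.abs(group_charge) >= 0.5
    both = charged[group_of[idx_a]][:, None] & charged[group_of[idx_b]][None, :]
    return np.where(both, dielectric.effective, dielectric.protein)


def _interaction(coords, charges, idx_a, idx_b, eps_matrix):
    pa = coords[idx_a]
    pb = coords[idx_b]
    d = pa[:, None, :] - pb[None, :, :]
    r = np.sqrt(np.sum(d * d, axis=-1))
    r = np.maximum(r, 0.3)
    qa = charges[idx_a][:, None]
    qb = charges[idx_b][None, :]
    return float(np.sum(COULOMB_K * qa * qb / (eps_matrix * r)))


def _residue_groups(system: EVBSystem, structure=None) -> tuple[np.ndarray, list[list[int]]]:
    """Group atoms by residue when a structure is attached, else atom-per-group."""
    if structure is None:
        n = system.topology.n_atoms
        return np.arange(n), [[i] for i in range(n)]
    keys = {}
    group_of = np.zeros(len(structure.atoms), dtype=int)
    groups: list[list[int]] = []
    for i, a in enumerate(structure.atoms):
        key = (a.chain_id, a.residue_number)
        if key not in keys:
            keys[key] = len(groups)
            groups.append([])
        group_of[i] = keys[key]
        groups[keys[key]].append(i)
    return group_of, groups


def lra_binding(system: EVBSystem, ligand_indices: list[int],
                protocol: LRAProtocol = LRAProtocol(),
                dielectric: DielectricModel = DielectricModel(),
                structure=None, state_index: int | None = None) -> BindingEstimate:
    """Linear-response electrostatic binding energy of a ligand selection.

    Dynamics are run with the ligand charges on (charged ensemble) and
    zeroed (uncharged ensemble), ``n_configurations`` independent seeded
    segments each; the screened ligand–environment interaction with the
    *full* ligand charges is averaged in both and half-summed. With
    ``steps_per_configuration = 0`` the frozen-geometry closed form is
    returned (both averages equal the static screened Coulomb sum).
    """
    if not ligand_indices:
        raise ValueError("ligand selection is empty")
    top = system.topology
    st = top.states[0] if state_index is None else top.state(state_index)
    charges = np.array(st.charges)
    lig_set = set(ligand_indices)
    # explicit waters are part of the dielectric continuum this estimator
    # assumes, not of the screened environment — including them at ε_p would
    # double-count solvent screening
    water = set()
    if structure is not None:
        water = {i for i, a in enumerate(structure.atoms) if a.is_water}
    env_indices = np.array([i for i in range(top.n_atoms)
                            if i not in lig_set and i not in water])
    lig = np.array(sorted(ligand_indices))
    group_of, groups = _residue_groups(system, structure)
    gq = _group_net_charges(charges, groups)
    eps = _screen_matrix(charges, group_of, gq, dielectric, lig, env_indices)

    def sample(zero_ligand: bool) -> np.ndarray:
        vals = []
        for c in range(protocol.n_configurations):
            coords = np.array(system.coordinates)
            if protocol.steps_per_configuration > 0:
                run_top = top if not zero_ligand else _zero_charges(top, lig)
                sys_c = EVBSystem(run_top, coords, system.boundary,
                                  list(system.distance_restraints),
                                  list(system.position_restraints),
                                  system.mobile.copy())
                rng = np.random.Generator(np.random.Philox(
                    key=[int(protocol.seed), 0x17A + c + (1000 if zero_ligand else 0)]))
                lam = np.zeros(top.n_states)
                lam[0] = 1.0
                traj = run_langevin(
                    sys_c, LangevinParams(protocol.temperature, 1.0, 1.0,
                                          protocol.steps_per_configuration,
                                          protocol.seed),
                    lam, rng=rng)
                coords = traj.final_coords
            vals.append(_interaction(coords, charges, lig, env_indices, eps))
        return np.array(vals)

    on = sample(zero_ligand=False)
    off = sample(zero_ligand=True)
    # equilibration flag: compare configuration-half means
    def half_gap(v):
        h = len(v) // 2
        return abs(v[:h].mean() - v[h:].mean()) if h >= 1 and len(v) > 1 else 0.0
    equilibrated = max(half_gap(on), half_gap(off)) < max(2.0, 0.5 * abs(on.mean()) + 1e-9)
    delta = 0.5 * (float(on.mean()) + float(off.mean()))
    return BindingEstimate(delta_g=delta, mean_charged=float(on.mean()),
                           mean_uncharged=float(off.mean()), protocol=protocol,
                           equilibrated=bool(equilibrated))


def _zero_charges(top: EVBTopology, indices: np.ndarray) -> EVBTopology:
    states = []
    for s in top.states:
        q = np.array(s.charges)
        q[indices] = 0.0
        states.append(DiabaticState(s.index, s.bonds, s.angles, s.torsions, q, s.shift))
    return EVBTopology(atom_names=list(top.atom_names), atom_types=list(top.atom_types),
                       masses=np.array(top.masses), lj_a=dict(top.lj_a),
                       lj_b=dict(top.lj_b), states=states,
                       couplings=list(top.couplings), evb_region=list(top.evb_region),
                       scale14_elec=top.scale14_elec, scale14_lj=top.scale14_lj)


def group_binding_decomposition(coords: np.ndarray, charges: np.ndarray,
                                group_a: list[int], group_b: list[int],
                                dielectric: DielectricModel = DielectricModel()) -> float:
    """Screened electrostatic interaction between two disjoint groups at
    fixed coordinates (ε_eff screening throughout: this decomposition is
    defined for charged-group pairs). Additive over partitions of either
    group by construction."""
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    ia = np.array(sorted(group_a))
    ib = np.array(sorted(group_b))
    eps = np.full((len(ia), len(ib)), dielectric.effective)
    return _interaction(np.asarray(coords, dtype=float), np.asarray(charges, dtype=float),
                        ia, ib, eps)


# ---------------------------------------------------------------------------
# Monte Carlo protonation
# ---------------------------------------------------------------------------

@dataclass
class ProtonationModel:
    """Ionizable sites with intrinsic pKa and pairwise interactions.

    ``charge_protonated``/``charge_deprotonated`` give each site's charge in
    the two states (acids 0/−1, bases +1/0). ``w`` is the symmetric,
    zero-diagonal matrix of interaction energies per unit charge product
    (kcal/mol/e²), typically 332/(ε_eff·r_ij).
    """
    labels: list[str]
    pka: np.ndarray
    charge_protonated: np.ndarray
    charge_deprotonated: np.ndarray
    w: np.ndarray
    ph: float = 7.0
    temperature: float = 300.0

    def __post_init__(self):
        self.pka = np.asarray(self.pka, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.labels)
        if self.w.shape != (n, n) or not np.allclose(self.w, self.w.T):
            raise ValueError("interaction matrix must be symmetric n×n")
        if not np.allclose(np.diag(self.w), 0.0):
            raise ValueError("interaction matrix must have zero diagonal")

    def energy(self, s: np.ndarray) -> float:
        """Microstate energy; s is the 0/1 protonation vector."""
        kbt = KB * self.temperature
        q = np.where(s == 1, self.charge_protonated, self.charge_deprotonated)
        e_site = float(np.sum(LN10 * kbt * s * (self.ph - self.pka)))
        e_pair = 0.5 * float(q @ self.w @ q)
        return e_site + e_pair

    def enumerate_probabilities(self) -> np.ndarray:
        """Exhaustive Boltzmann average over all 2ⁿ microstates (n ≤ 20)."""
        n = len(self.labels)
        if n > 20:
            raise ValueError("enumeration limited to 20 sites")
        kbt = KB * self.temperature
        states = np.array(list(itertools.product((0, 1), repeat=n)))
        e = np.array([self.energy(s) for s in states])
        w = np.exp(-(e - e.min()) / kbt)
        w /= w.sum()
        return states.T @ w


@dataclass
class ProtonationResult:
    probabilities: np.ndarray
    best_state: np.ndarray
    best_energy: float
    n_sweeps: int
    seed: int


def mcpt_protonation(model: ProtonationModel, sweeps: int = 5000,
                     seed: int = 0, burn_in_fraction: float = 0.2) -> ProtonationResult:
    """Metropolis sampling over protonation microstates (single-site flips)."""
    n = len(model.labels)
    if n < 1:
        raise ValueError("need at least one ionizable site")
    rng = np.random.Generator(np.random.Philox(key=[int(seed), 0x9CA]))
    s = rng.integers(0, 2, size=n)
    kbt = KB * model.temperature
    e = model.energy(s)
    best_s, best_e = s.copy(), e
    counts = np.zeros(n)
    n_burn = int(burn_in_fraction * sweeps)
    kept = 0
    for sweep in range(sweeps):
        for _ in range(n):
            i = int(rng.integers(n))
            s2 = s.copy()
            s2[i] ^= 1
            e2 = model.energy(s2)
            if e2 < e or rng.random() < np.exp(-(e2 - e) / kbt):
                s, e = s2, e2
                if e < best_e:
                    best_s, best_e = s.copy(), e
        if sweep >= n_burn:
            counts += s
            kept += 1
    return ProtonationResult(probabilities=counts / max(kept, 1), best_state=best_s,
                             best_energy=best_e, n_sweeps=sweeps, seed=seed)


# ---------------------------------------------------------------------------
# Closed-form kinetics and pH energetics
# ---------------------------------------------------------------------------

def tst_convert(mode: str, value: float, temperature: float = 300.0) -> float:
    """Eyring transition-state theory: k = (k_B·T/h)·exp(−ΔG‡/RT).

    ``mode`` is ``"barrier_to_rate"`` (kcal/mol → 1/s) or
    ``"rate_to_barrier"`` (1/s → kcal/mol); the two are exact inverses.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    prefactor = KB_OVER_H * temperature
    if mode == "barrier_to_rate":
        if not np.isfinite(value):
            raise ValueError("barrier must be finite")
        return float(prefactor * np.exp(-value / (KB * temperature)))
    if mode == "rate_to_barrier":
        if value <= 0:
            raise ValueError("rate must be positive")
        return float(-KB * temperature * np.log(value / prefactor))
    raise ValueError(f"unknown mode {mode!r}")


def hydroxide_formation_energy(ph: float, temperature: float = ROOM_T) -> float:
    """Free energy to form OH⁻ from water at a given pH:
    ΔG = k_B·T·ln(10)·(15.7 − pH) kcal/mol (15.7 = pK_w + log[H₂O])."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB * temperature * LN10 * (15.7 - ph)
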
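"""Synthetic systems: analytic toys and a reduced two-metal active-site model.

Two kinds of fixtures live here.

*Analytic toys* — a Marcus two-parabola system and a harmonic force-constant
perturbation pair — have closed-form free energies and run through the same
topology/sampling machinery as everything else (each is one mobile particle
tethered to frozen anchor atoms, with the off-axis degrees of freedom frozen
so the closed 1-D forms apply exactly).

*The reduced active-site model* stands in for a full 10,000-atom protein
droplet at desk scale: an inorganic phosphate flanked by two octahedrally
coordinated Mg²⁺ ions, carboxylate (Asp), guanidinium (Arg) and hydroxyl
(Ser) side-chain analogs, a methylene-donor fragment of the folate substrate
and a pyridinium-acceptor fragment of the nicotinamide cofactor joined by a
transferring hydride, and a seeded shell of explicit waters. Every
interaction class of the full system (metal coordination, phosphate charge,
π-fragment charge redistribution, water reorganization) is present; the
absolute protein electrostatics are not, which is why published barriers
other than the packaged calibration target are treated as orderings only.

Variants: ``two_mg``, ``mg_a``, ``mg_b``, ``no_mg`` differ only in which
ions are present; ``reference`` is the same reacting solute in a pure water
droplet and is the calibration leg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .structure import Atom, Structure
from .topology import (AngleTerm, BondTerm, CouplingTerm, DiabaticState,
                       EVBTopology, TopologyError)
from .sampling import (DistanceRestraint, EVBSystem, PositionRestraint,
                       SphericalBoundary)

__all__ = [
    "MarcusSystem", "ActiveSiteFixture", "make_marcus_system",
    "make_harmonic_fep_pair", "make_active_site_fixture",
    "perturb_coordinates", "FIXTURE_VARIANTS",
]

FIXTURE_VARIANTS = ("two_mg", "mg_a", "mg_b", "no_mg", "reference")

# masses; hydrogens are mass-repartitioned to 3 amu so the stiff O–H and
# C–H stretches stay stable at the 1 fs timestep (equilibrium/configurational
# properties are mass-independent, so free energies are unaffected)
_M = {"H": 3.024, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "MG": 24.305}

# Lennard-Jones A/B (geometric convention), per atom type.
# OW matches the common 3-site water oxygen; MG is a small hard dication
# parameterized so Mg–O(water) pair minima land near 2.0 Å.
_LJ = {
    "CT": (952.0, 24.5),
    "N": (711.0, 23.5),
    "O": (480.0, 20.7),
    "OW": (762.9, 24.4),
    # small repulsive wall on water H (as in the CHARMM water variant):
    # prevents bare-proton collapse onto anionic oxygens in the droplet
    "HW": (2.0, 0.0),
    "H": (4.0, 0.0),
    "P": (2453.0, 46.8),
    "MG": (181.0, 6.0),
    "X": (0.0, 0.0),
}

_WATER_CHARGES = (-0.834, 0.417, 0.417)
_WATER_ROH = 0.9572
_WATER_THETA = 104.52


# ---------------------------------------------------------------------------
# Marcus toy
# ---------------------------------------------------------------------------

@dataclass
class MarcusSystem:
    """Two displaced equal-curvature harmonic diabats with constant coupling."""

    reorganization_energy: float
    reaction_free_energy: float
    coupling: float
    force_constant: float
    particle_mass: float
    system: EVBSystem
    diabatic_barrier: float
    adiabatic_barrier: float
    well_separation: float

    def ground_surface(self, x: np.ndarray) -> np.ndarray:
        """E_g along the particle coordinate (closed 2×2 form)."""
        e1 = 0.5 * self.force_constant * x ** 2
        e2 = (0.5 * self.force_constant * (x - self.well_separation) ** 2
              + self.reaction_free_energy)
        mean = 0.5 * (e1 + e2)
        half = 0.5 * (e1 - e2)
        return mean - np.sqrt(half ** 2 + self.coupling ** 2)


def make_marcus_system(lam: float, dg0: float = 0.0, h12: float = 0.0,
                       force_constant: float = 20.0,
                       particle_mass: float = 12.0) -> MarcusSystem:
    """Build the Marcus oracle system.

    The diabatic crossing barrier is (λ+ΔG⁰)²/4λ in closed form; the
    adiabatic barrier is found by a dense scan of the analytic ground
    surface (for the symmetric case it equals λ/4 − H₁₂).
    """
    if lam <= 0:
        raise ValueError("reorganization energy λ must be positive")
    if force_constant <= 0:
        raise ValueError("force constant must be positive")
    if h12 < 0:
        raise ValueError("coupling must be non-negative")
    d = np.sqrt(2.0 * lam / force_constant)
    top = _one_particle_topology(
        mass=particle_mass,
        state_bonds=[
            [BondTerm(0, 1, "harmonic", force_constant, 0.0)],
            [BondTerm(0, 2, "harmonic", force_constant, 0.0)],
        ],
        shifts=[0.0, dg0],
        h12=h12,
        anchor_positions=[(0.0, 0.0, 0.0), (d, 0.0, 0.0)],
    )
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    mobile = np.zeros((3, 3), dtype=bool)
    mobile[0, 0] = True  # particle moves along x only: exact 1-D reduction
    system = EVBSystem(top, coords, mobile=mobile)
    diabatic_barrier = (lam + dg0) ** 2 / (4.0 * lam)
    xs = np.linspace(-0.5 * d, 1.5 * d, 20001)
    ms = MarcusSystem(lam, dg0, h12, force_constant, particle_mass, system,
                      diabatic_barrier, 0.0, d)
    eg = ms.ground_surface(xs)
    # adiabatic barrier: maximum between the two surface minima
    i_r = np.argmin(eg[xs < 0.5 * d])
    i_p = len(xs[xs < 0.5 * d]) + np.argmin(eg[xs >= 0.5 * d])
    ms.adiabatic_barrier = float(eg[i_r:i_p + 1].max() - eg[i_r])
    return ms


def make_harmonic_fep_pair(k1: float, k2: float, temperature: float = 300.0):
    """Two harmonic wells sharing a minimum; ΔA = (k_BT/2)·ln(k₂/k₁).

    Returns ``(system, delta_a)``. The analytic value is the 1-D classical
    partition-function ratio; the off-axis degrees of freedom are frozen so
    sampling reproduces it directly.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("force constants must be positive")
    top = _one_particle_topology(
        mass=12.0,
        state_bonds=[
            [BondTerm(0, 1, "harmonic", k1, 0.0)],
            [BondTerm(0, 1, "harmonic", k2, 0.0)],
        ],
        shifts=[0.0, 0.0],
        h12=0.0,
        anchor_positions=[(0.0, 0.0, 0.0)],
    )
    coords = np.zeros((2, 3))
    mobile = np.zeros((2, 3), dtype=bool)
    mobile[0, 0] = True
    system = EVBSystem(top, coords, mobile=mobile)
    delta_a = 0.5 * KB * temperature * np.log(k2 / k1)
    return system, float(delta_a)


def _one_particle_topology(mass, state_bonds, shifts, h12, anchor_positions):
    n = 1 + len(anchor_positions)
    states = []
    for k, (bonds, shift) in enumerate(zip(state_bonds, shifts), start=1):
        states.append(DiabaticState(k, bonds, [], [], np.zeros(n), shift))
    couplings = [CouplingTerm(1, 2, h12)] if h12 > 0 else []
    return EVBTopology(
        atom_names=["PT"] + [f"AN{i}" for i in range(len(anchor_positions))],
        atom_types=["X"] * n,
        masses=np.array([mass] + [1.0e6] * len(anchor_positions)),
        lj_a={"X": 0.0}, lj_b={"X": 0.0},
        states=states, couplings=couplings, evb_region=[0],
    )


# ---------------------------------------------------------------------------
# Reduced active-site model
# ---------------------------------------------------------------------------

# Geometry anchors (Å). The reacting carbons sit 3.1 Å apart with the
# transferring hydride 1.10 Å from the donor / 2.1 Å from the acceptor.
_DONOR_C = np.array([0.0, 0.0, 0.0])
_ACCEPTOR_C = np.array([3.1, 0.0, 0.0])
_HYDRIDE = np.array([1.02, 0.40, 0.0])
_DROPLET_CENTER = 0.5 * (_DONOR_C + _ACCEPTOR_C)
_DROPLET_RADIUS = 8.5
_PHOSPHORUS = np.array([2.70, -5.8, 0.0])
_MG_OFFSET = 2.51       # P→Mg distance for bidentate coordination at 2.05 Å
_MG_LIG = 2.08          # completing-ligand distance
_RESTRAINT_K = 10.0     # kcal/mol/Å², the standard pair/position constraint

# per-state solute charges (state 3 relaxes the cation onto the ring nitrogens)
_SOLUTE = [
    # name  elem  frag     q1     q2     q3
    ("C11", "C", "THF", +0.10, +0.30, +0.45),
    ("HT",  "H", "THF", +0.10, +0.05, +0.05),
    ("H12", "H", "THF", +0.10, +0.15, +0.05),
    ("N5",  "N", "THF", -0.25, +0.10, +0.25),
    ("N10", "N", "THF", -0.25, +0.10, +0.25),
    ("C4A", "C", "THF", +0.10, +0.175, 0.0),
    ("C9",  "C", "THF", +0.10, +0.175, 0.0),
    ("C4N", "C", "NAD", +0.15, 0.00, 0.00),
    ("H4N", "H", "NAD", +0.10, +0.05, +0.05),
    ("C3N", "C", "NAD", +0.15, -0.05, -0.05),
    ("C5N", "C", "NAD", +0.15, -0.05, -0.05),
    ("N1N", "N", "NAD", +0.35, -0.05, -0.05),
    ("O7N", "O", "NAD", +0.10, +0.05, +0.05),
]

_SOLUTE_POS = {
    "C11": _DONOR_C,
    "HT": _HYDRIDE,
    "H12": np.array([0.35, -0.25, 1.00]),
    "N5": np.array([-0.75, 1.15, -0.10]),
    "N10": np.array([-0.75, -1.15, 0.10]),
    "C4A": np.array([-2.05, 0.70, -0.15]),
    "C9": np.array([-2.05, -0.70, 0.15]),
    "C4N": _ACCEPTOR_C,
    "H4N": np.array([3.25, -0.05, 1.08]),
    "C3N": np.array([3.85, 1.15, -0.25]),
    "C5N": np.array([3.85, -1.15, -0.25]),
    "N1N": np.array([5.10, 0.00, -0.50]),
    "O7N": np.array([3.00, 2.40, -0.60]),
}

_SOLUTE_BONDS = [
    ("C11", "N5"), ("C11", "N10"), ("N5", "C4A"), ("N10", "C9"),
    ("C4A", "C9"), ("C11", "H12"),
    ("C4N", "C3N"), ("C4N", "C5N"), ("C3N", "N1N"), ("C5N", "N1N"),
    ("C3N", "O7N"), ("C4N", "H4N"),
]

_MORSE_DE = 100.0
_MORSE_A = 1.5
_MORSE_R0 = 1.09


@dataclass
class ActiveSiteFixture:
    structure: Structure
    topology: EVBTopology
    system: EVBSystem
    seed: int
    variant: str
    n_waters: int
    donor_index: int
    acceptor_index: int
    hydride_index: int
    mg_a_index: int | None
    mg_b_index: int | None
    metadata: dict = field(default_factory=dict)

    @property
    def droplet_center(self) -> np.ndarray:
        return np.array(_DROPLET_CENTER)

    @property
    def reactive_midpoint(self) -> np.ndarray:
        c = self.system.coordinates
        return 0.5 * (c[self.donor_index] + c[self.acceptor_index])

    @property
    def phosphate_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.structure.atoms)
                if a.residue_name == "PO4"]

    def phosphate_drift_system(self) -> EVBSystem:
        """Droplet system with the phosphate, the ions, and every water
        unrestrained (protein analogs and the reacting solute stay held).
        This is the stability diagnostic: if the ions present cannot hold
        the anion, it leaves its pocket during plain dynamics."""
        free = set(self.phosphate_indices)
        for i, a in enumerate(self.structure.atoms):
            if a.residue_name == "MG" or a.is_water:
                free.add(i)
        pos = [p for p in self.system.position_restraints if p.index not in free]
        return EVBSystem(self.topology, np.array(self.system.coordinates),
                         self.system.boundary,
                         list(self.system.distance_restraints), pos,
                         self.system.mobile.copy())

    @property
    def pocket_structure(self) -> Structure:
        """Structure plus an uncharged steric wall shell standing in for the
        protein matrix that encloses the active site; used by cavity
        hydration, never by the dynamics. Walls carry no charge, so they
        only exclude volume."""
        return _add_pocket_wall(self.structure, self.reactive_midpoint)


class _Builder:
    def __init__(self):
        self.names: list[str] = []
        self.elements: list[str] = []
        self.types: list[str] = []
        self.positions: list[np.ndarray] = []
        self.charges: list[tuple[float, float, float]] = []
        self.residues: list[tuple[str, str, int]] = []  # chain, resname, resnum
        self.restrained: list[int] = []

    def add(self, name, element, type_, pos, q, residue, restrain=False) -> int:
        idx = len(self.names)
        self.names.append(name)
        self.elements.append(element)
        self.types.append(type_)
        self.positions.append(np.asarray(pos, dtype=float))
        q = (q, q, q) if np.isscalar(q) else tuple(q)
        self.charges.append(q)
        self.residues.append(residue)
        if restrain:
            self.restrained.append(idx)
        return idx

    def index(self, name: str) -> int:
        return self.names.index(name)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _perp(v):
    v = _unit(v)
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = np.cross(v, ref)
    return _unit(p)


def _outward_perp(away, at):
    """Perpendicular to ``away`` that points outward from the droplet center,
    so capping atoms extend into empty space instead of into the solute."""
    away = _unit(away)
    p0 = _perp(away)
    q0 = _unit(np.cross(away, p0))
    out = _unit(np.asarray(at, dtype=float) - _DROPLET_CENTER)
    cands = [p0, -p0, q0, -q0]
    return max(cands, key=lambda c: float(np.dot(c, out)))


def _add_water(b: _Builder, o_pos, orient, resnum, chain="W"):
    """3-site water with H's opened toward ``orient`` (away from an ion)."""
    o_pos = np.asarray(o_pos, dtype=float)
    u = _unit(orient)
    p = _perp(u)
    half = np.radians(_WATER_THETA / 2.0)
    h1 = o_pos + _WATER_ROH * (np.cos(half) * u + np.sin(half) * p)
    h2 = o_pos + _WATER_ROH * (np.cos(half) * u - np.sin(half) * p)
    qo, qh, _ = _WATER_CHARGES
    io = b.add("O", "O", "OW", o_pos, qo, (chain, "HOH", resnum))
    b.add("H1", "H", "HW", h1, qh, (chain, "HOH", resnum))
    b.add("H2", "H", "HW", h2, qh, (chain, "HOH", resnum))
    return io


def _add_carboxylate(b: _Builder, o1_pos, away, resnum, label="ASP"):
    """Acetate-like Asp analog: coordinating O, carbonyl C, second O, Cβ cap."""
    away = _unit(away)
    p = _outward_perp(away, o1_pos)
    cg = o1_pos + 1.25 * away
    o2 = cg + 1.25 * _unit(0.55 * away + p)
    cb = cg + 1.52 * _unit(0.8 * away - 0.4 * p)
    i1 = b.add("OD1", "O", "O", o1_pos, -0.80, ("P", label, resnum), restrain=True)
    ic = b.add("CG", "C", "CT", cg, +0.70, ("P", label, resnum), restrain=True)
    i2 = b.add("OD2", "O", "O", o2, -0.80, ("P", label, resnum), restrain=True)
    ib = b.add("CB", "C", "CT", cb, -0.10, ("P", label, resnum), restrain=True)
    return [(i1, ic), (ic, i2), (ic, ib)]


def _add_guanidinium(b: _Builder, n_pos, away, resnum):
    """Guanidinium stub of the Arg analog; the coordinating NH₂ nitrogen is
    the group's only negative site."""
    away = _unit(away)
    p = _outward_perp(away, n_pos)
    cz = n_pos + 1.33 * away
    nh1 = cz + 1.33 * _unit(0.55 * away + p)
    ne = cz + 1.33 * _unit(0.55 * away - 0.4 * p)
    i0 = b.add("NH2", "N", "N", n_pos, -0.30, ("P", "ARG", resnum), restrain=True)
    ic = b.add("CZ", "C", "CT", cz, +0.60, ("P", "ARG", resnum), restrain=True)
    i1 = b.add("NH1", "N", "N", nh1, +0.35, ("P", "ARG", resnum), restrain=True)
    i2 = b.add("NE", "N", "N", ne, +0.35, ("P", "ARG", resnum), restrain=True)
    return [(i0, ic), (ic, i1), (ic, i2)]


def make_active_site_fixture(seed: int, n_waters: int = 24,
                             variant: str = "two_mg") -> ActiveSiteFixture:
    """Deterministic reduced active-site model.

    ``n_waters`` counts all waters including the five metal-shell waters.
    Both Mg²⁺ shells are exact octahedra at construction (two phosphate
    oxygens, the side-chain analog atom(s), and shell waters, all within
    2.5 Å); the donor–acceptor carbons sit at 3.1 Å.
    """
    if variant not in FIXTURE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {FIXTURE_VARIANTS}")
    if n_waters < 5:
        raise ValueError("need at least 5 waters to build both metal shells")
    rng = np.random.Generator(np.random.Philox(key=[int(seed), 0xA57E]))
    b = _Builder()
    env = variant != "reference"

    # -- reacting solute ----------------------------------------------------
    for name, elem, frag, q1, q2, q3 in _SOLUTE:
        type_ = {"C": "CT", "N": "N", "O": "O", "H": "H"}[elem]
        resnum = 1 if frag == "THF" else 2
        restrain = elem != "H"
        b.add(name, elem, type_, _SOLUTE_POS[name], (q1, q2, q3),
              ("S", frag, resnum), restrain=restrain)

    bonds_common: list[tuple[int, int]] = [
        (b.index(i), b.index(j)) for i, j in _SOLUTE_BONDS]

    shell_water_specs = []  # (o_pos, orient, near_mg)
    mg_a_index = mg_b_index = None

    if env:
        # -- phosphate ------------------------------------------------------
        # tetrahedron oriented so the two O-pair bisectors lie along ±x (the
        # ion axis) and no oxygen points at the reacting fragments above
        ct, st_ = np.cos(np.radians(54.7356)), np.sin(np.radians(54.7356))
        t = np.array([[ct, 0.0, st_], [ct, 0.0, -st_],
                      [-ct, -st_, 0.0], [-ct, st_, 0.0]])
        p_idx = b.add("P", "P", "P", _PHOSPHORUS, +1.00, ("I", "PO4", 3), restrain=True)
        o_idx = []
        for k in range(4):
            o_idx.append(b.add(f"O{k+1}P", "O", "O", _PHOSPHORUS + 1.55 * t[k],
                               -1.00, ("I", "PO4", 3), restrain=True))
            bonds_common.append((p_idx, o_idx[k]))

        bis_b = _unit(t[0] + t[1])   # +x bisector: Mg_B side (cofactor side)
        bis_a = -bis_b               # Mg_A side (substrate side)
        mg_b_pos = _PHOSPHORUS + _MG_OFFSET * bis_b
        mg_a_pos = _PHOSPHORUS + _MG_OFFSET * bis_a

        def octahedral_frame(mg_pos, o_pair):
            # order the phosphate-oxygen pair so the trans ligand built along
            # -u1 (the carboxylate analog) extends away from the solute
            ua = _unit(b.positions[o_pair[0]] - mg_pos)
            ub = _unit(b.positions[o_pair[1]] - mg_pos)
            out = _unit(mg_pos - _DROPLET_CENTER)
            u1, u2 = (ua, ub) if np.dot(-ua, out) >= np.dot(-ub, out) else (ub, ua)
            e3 = _unit(np.cross(u1, u2))
            return u1, u2, e3

        # Mg_A: Asp225 O, Arg233 NH2, 2 waters, 2 phosphate O. The Arg stub
        # occupies an out-of-plane vertex so its charged guanidinium tips sit
        # roughly equidistant from the two reacting fragments.
        if variant in ("two_mg", "mg_a"):
            mg_a_index = b.add("MG", "MG", "MG", mg_a_pos, +2.00, ("I", "MG", 4),
                               restrain=True)
        u1, u2, e3 = octahedral_frame(mg_a_pos, (o_idx[2], o_idx[3]))
        bonds_common += _add_carboxylate(b, mg_a_pos - 2.05 * u1, -u1, 225)
        bonds_common += _add_guanidinium(b, mg_a_pos + 2.15 * e3, e3, 233)
        shell_water_specs.append((mg_a_pos - _MG_LIG * u2, -u2, "A"))
        shell_water_specs.append((mg_a_pos - _MG_LIG * e3, -e3, "A"))

        # Mg_B: Asp168 O, 3 waters, 2 phosphate O
        if variant in ("two_mg", "mg_b"):
            mg_b_index = b.add("MG", "MG", "MG", mg_b_pos, +2.00, ("I", "MG", 5),
                               restrain=True)
        u1, u2, e3 = octahedral_frame(mg_b_pos, (o_idx[0], o_idx[1]))
        bonds_common += _add_carboxylate(b, mg_b_pos - 2.05 * u1, -u1, 168)
        shell_water_specs.append((mg_b_pos - _MG_LIG * u2, -u2, "B"))
        shell_water_specs.append((mg_b_pos + _MG_LIG * e3, e3, "B"))
        shell_water_specs.append((mg_b_pos - _MG_LIG * e3, -e3, "B"))

        # Ser analog near the cofactor fragment (neutral spectator)
        og = np.array([5.6, 2.9, 1.4])
        cb = og + np.array([1.2, 0.8, 0.4])
        i_og = b.add("OG", "O", "O", og, -0.35, ("P", "SER", 197), restrain=True)
        i_cb = b.add("CB", "C", "CT", cb, +0.35, ("P", "SER", 197), restrain=True)
        bonds_common.append((i_og, i_cb))

    # -- waters -------------------------------------------------------------
    water_o_indices = []
    shell_o_indices = []
    resnum = 301
    for o_pos, orient, _tag in shell_water_specs:
        io = _add_water(b, o_pos, orient, resnum)
        water_o_indices.append(io)
        shell_o_indices.append(io)
        resnum += 1
    n_free = n_waters - len(shell_water_specs)
    heavy = np.array([b.positions[i] for i in range(len(b.positions))
                      if b.elements[i] != "H"])
    placed = [b.positions[i] for i in water_o_indices]
    attempts = 0
    while n_free > 0 and attempts < 200000:
        attempts += 1
        u = rng.normal(size=3)
        r = (_DROPLET_RADIUS - 1.2) * rng.random() ** (1.0 / 3.0)
        pos = _DROPLET_CENTER + r * _unit(u)
        d_heavy = np.min(np.linalg.norm(heavy - pos, axis=1)) if len(heavy) else 99.0
        d_wat = min((np.linalg.norm(p - pos) for p in placed), default=99.0)
        if d_heavy < 2.55 or d_wat < 2.75:
            continue
        orient = _unit(rng.normal(size=3))
        water_o_indices.append(_add_water(b, pos, orient, resnum))
        placed.append(pos)
        heavy = np.vstack([heavy, pos])
        resnum += 1
        n_free -= 1
    if n_free > 0:
        raise ValueError(f"could not place {n_free} waters without clashes")

    topology = _build_topology(b, bonds_common, water_o_indices)
    coords = np.array(b.positions)
    structure = _build_structure(b, coords, variant, seed)

    boundary = SphericalBoundary(tuple(_DROPLET_CENTER), _DROPLET_RADIUS,
                                 restraint_k=_RESTRAINT_K,
                                 frozen_beyond=_DROPLET_RADIUS + 40.0)
    donor = b.index("C11")
    acceptor = b.index("C4N")
    system = EVBSystem(
        topology, coords, boundary=boundary,
        distance_restraints=[DistanceRestraint(donor, acceptor, _RESTRAINT_K, 3.1)],
        # environment heavy atoms carry the standard pair-constraint strength;
        # the structural metal-shell waters get a weak tether that preserves
        # libration but suppresses slow shell-exchange multistability
        position_restraints=(
            [PositionRestraint(i, _RESTRAINT_K, tuple(b.positions[i]))
             for i in b.restrained]
            + [PositionRestraint(i + k, _RESTRAINT_K, tuple(b.positions[i + k]))
               for i in shell_o_indices for k in (0, 1, 2)]),
    )

    fixture = ActiveSiteFixture(
        structure=structure, topology=topology, system=system, seed=seed,
        variant=variant, n_waters=n_waters,
        donor_index=donor, acceptor_index=acceptor, hydride_index=b.index("HT"),
        mg_a_index=mg_a_index, mg_b_index=mg_b_index,
        metadata={"water_oxygens": water_o_indices,
                  "restrained": list(b.restrained)},
    )
    _validate_fixture(fixture)
    return fixture


_K_BOND_HEAVY = 350.0   # kcal/mol/Å²
_K_BOND_H = 340.0
_K_BOND_WATER = 450.0
_K_ANGLE = 50.0
_K_ANGLE_WATER = 55.0
_COUPLING_12 = 6.0      # placeholder before calibration (kcal/mol)
_COUPLING_23 = 2.0
_SHIFT_3 = 2.0          # intermediate→product relaxation offset, kcal/mol


def _build_topology(b: _Builder, bonds_common, water_o_indices) -> EVBTopology:
    """Three-state topology: framework bonds/angles are identical across
    states with r₀/θ₀ taken from the as-built geometry (the construction is
    its own minimum); only the hydride Morse bond and the charges differ."""
    n = len(b.names)
    pos = np.array(b.positions)

    def dist(i, j):
        return float(np.linalg.norm(pos[i] - pos[j]))

    common = []
    for i, j in bonds_common:
        k = _K_BOND_H if (b.elements[i] == "H" or b.elements[j] == "H") else _K_BOND_HEAVY
        common.append(BondTerm(i, j, "harmonic", k, dist(i, j)))
    for io in water_o_indices:
        common.append(BondTerm(io, io + 1, "harmonic", _K_BOND_WATER, _WATER_ROH))
        common.append(BondTerm(io, io + 2, "harmonic", _K_BOND_WATER, _WATER_ROH))

    # angles from the common connectivity; the hydride never carries angles
    # (its path is governed by the Morse bonds and electrostatics alone)
    ht = b.index("HT")
    neigh: dict[int, set[int]] = {i: set() for i in range(n)}
    for term in common:
        neigh[term.i].add(term.j)
        neigh[term.j].add(term.i)
    angles = []
    for j in range(n):
        nb = sorted(neigh[j])
        for a_i in range(len(nb)):
            for a_k in range(a_i + 1, len(nb)):
                i, k = nb[a_i], nb[a_k]
                if ht in (i, j, k):
                    continue
                v1 = pos[i] - pos[j]
                v2 = pos[k] - pos[j]
                cos_t = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                theta0 = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
                is_water = b.residues[j][1] == "HOH"
                angles.append(AngleTerm(i, j, k,
                                        _K_ANGLE_WATER if is_water else _K_ANGLE,
                                        _WATER_THETA if is_water else theta0))

    donor = b.index("C11")
    acceptor = b.index("C4N")
    morse_reactant = BondTerm(donor, ht, "morse", _MORSE_DE, _MORSE_A, _MORSE_R0)
    morse_product = BondTerm(acceptor, ht, "morse", _MORSE_DE, _MORSE_A, _MORSE_R0)

    charges = np.array(b.charges)  # (n, 3)
    states = [
        DiabaticState(1, common + [morse_reactant], angles, [], charges[:, 0], 0.0),
        DiabaticState(2, common + [morse_product], angles, [], charges[:, 1], 0.0),
        DiabaticState(3, common + [morse_product], angles, [], charges[:, 2], _SHIFT_3),
    ]
    couplings = [CouplingTerm(1, 2, _COUPLING_12), CouplingTerm(2, 3, _COUPLING_23)]
    solute_names = [s[0] for s in _SOLUTE]
    return EVBTopology(
        atom_names=list(b.names),
        atom_types=list(b.types),
        masses=np.array([_M[e] for e in b.elements]),
        lj_a={t: _LJ[t][0] for t in _LJ},
        lj_b={t: _LJ[t][1] for t in _LJ},
        states=states, couplings=couplings,
        evb_region=[b.index(nm) for nm in solute_names],
    )


def _validate_fixture(f: ActiveSiteFixture) -> None:
    from .hydration import coordination_shell

    feas, d = _donor_acceptor(f)
    if not feas:
        raise TopologyError(f"fixture donor–acceptor distance {d:.2f} Å exceeds 4.5 Å")
    for mg_idx, label in ((f.mg_a_index, "Mg_A"), (f.mg_b_index, "Mg_B")):
        if mg_idx is None:
            continue
        shell = coordination_shell(f.structure, mg_idx, cutoff=2.5)
        if shell.coordination_number != 6:
            raise TopologyError(
                f"{label} shell has {shell.coordination_number} ligands, expected 6")


def _donor_acceptor(f: ActiveSiteFixture):
    c = f.system.coordinates
    d = float(np.linalg.norm(c[f.donor_index] - c[f.acceptor_index]))
    return d <= 4.5, d


def _build_structure(b: _Builder, coords, variant, seed) -> Structure:
    atoms = []
    for i in range(len(b.names)):
        chain, resname, resnum = b.residues[i]
        atoms.append(Atom(
            serial=i + 1, name=b.names[i], element=b.elements[i],
            residue_name=resname, residue_number=resnum, chain_id=chain,
            position=tuple(coords[i]), occupancy=1.0,
            partial_charge=b.charges[i][0],
            record="HETATM" if chain in ("I", "W", "S") else "ATOM",
        ))
    return Structure(atoms, title=f"reduced active-site fixture ({variant}, seed {seed})",
                     source="fixture")


_WALL_RADIUS = 6.7      # Å, shell radius around the reactive midpoint
_WALL_SPACING = 600     # Fibonacci points (complete, unpruned shell)


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _add_pocket_wall(structure: Structure, center: np.ndarray) -> Structure:
    """Complete steric shell; overlap with solute atoms is harmless because
    the wall only ever interacts with flooding waters (any gap would instead
    let water leak between the shell and the hard MC boundary)."""
    center = np.asarray(center, dtype=float)
    pts = center + _WALL_RADIUS * _fibonacci_sphere(_WALL_SPACING)
    serial = max(a.serial for a in structure.atoms) + 1
    atoms = list(structure.atoms)
    for k, p in enumerate(pts):
        atoms.append(Atom(serial=serial + k, name="CW", element="C",
                          residue_name="WAL", residue_number=900 + k,
                          chain_id="X", position=tuple(p), partial_charge=0.0,
                          record="HETATM"))
    return Structure(atoms, title=structure.title, source=structure.source)


def perturb_coordinates(structure: Structure, sigma: float, seed: int) -> Structure:
    """I.i.d. Gaussian displacement of every coordinate; σ = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return structure
    rng = np.random.Generator(np.random.Philox(key=[int(seed), 0x9E37]))
    coords = structure.coordinates + sigma * rng.normal(size=(len(structure), 3))
    return structure.with_coordinates(coords)
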
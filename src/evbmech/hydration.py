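"""Metal-site coordination analysis and water-flooding Monte Carlo.

Water flooding answers "how many waters live in this buried cavity?": the
cavity is first over-saturated by random insertion, then pruned and
equilibrated by grand-canonical Metropolis moves (insertion / deletion /
displacement) against a hard spherical wall that forbids exchange across
the cavity boundary. The water activity z is calibrated so that a
solute-free cavity reproduces bulk water density (0.0334 Å⁻³) — that anchor
turns "keep the most likely configurations" into an observable criterion.

Mg²⁺ is placed by scanning a grid over the candidate region scored by the
ion's electrostatic + Lennard-Jones energy against the fixed structure,
followed by local minimization; coordination is purely nonbonded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BULK_WATER_DENSITY, COULOMB_K, KB
from .structure import Atom, Structure, StructureError

__all__ = [
    "IonSiteSpec", "CoordinationShell", "CavitySpec", "WaterFloodParams",
    "HydrationResult", "FloodingError", "PlacementError",
    "place_ion", "coordination_shell", "water_flood", "phosphate_drift",
    "calibrate_activity", "BULK_ACTIVITY",
]

# LJ (A, B) by element for ion placement and water-solute repulsion
_ELEM_LJ = {
    "C": (952.0, 24.5), "N": (711.0, 23.5), "O": (480.0, 20.7),
    "P": (2453.0, 46.8), "MG": (181.0, 6.0), "H": (4.0, 0.0),
}
_OW_LJ = (762.9, 24.4)
_HW_LJ = (2.0, 0.0)   # small repulsive wall, matches the droplet water model
# Water-water electrostatics in the hydration MC are screened by an
# effective dielectric: with bare charges a retained water binds its
# neighbours by 5-12 kcal/mol and grand-canonical insertion/deletion
# acceptance collapses to ~exp(-beta*10) — the water count then freezes at
# the over-saturation value instead of responding to the activity. The
# screened model keeps exchange ergodic so the bulk-density calibration is
# a real anchor. Water-solute interactions stay unscreened (they set which
# sites are worth occupying).
_WW_SCREEN = 2.0
_WATER_Q = (-0.834, 0.417, 0.417)
_ROH = 0.9572
_THETA = np.radians(104.52)

# Packaged bulk-calibrated water activity (Å⁻³) for this water model at
# 300 K in a 6 Å hard-wall cavity; reproduced by calibrate_activity().
BULK_ACTIVITY = 0.0386


class PlacementError(RuntimeError):
    pass


class FloodingError(RuntimeError):
    pass


@dataclass(frozen=True)
class IonSiteSpec:
    element: str
    candidate_ligand_indices: tuple[int, ...]
    center: tuple[float, float, float]
    radius: float
    target_coordination: int = 6
    charge: float = 2.0
    grid_spacing: float = 0.4

    def __post_init__(self):
        if len(self.candidate_ligand_indices) < 3:
            raise PlacementError("need at least 3 candidate ligand atoms")
        if self.radius <= 0:
            raise PlacementError("search radius must be positive")


@dataclass
class CoordinationShell:
    ion_index: int
    ligand_indices: list[int]
    ligand_names: list[str]
    distances: list[float]
    cutoff: float

    @property
    def coordination_number(self) -> int:
        return len(self.ligand_indices)


@dataclass(frozen=True)
class CavitySpec:
    center: tuple[float, float, float]
    hard_wall_radius: float = 6.0

    def __post_init__(self):
        if self.hard_wall_radius < 0:
            raise FloodingError("hard-wall radius must be non-negative")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.hard_wall_radius ** 3


@dataclass(frozen=True)
class WaterFloodParams:
    n_sweeps: int = 3000
    burn_in_fraction: float = 0.3
    temperature: float = 300.0
    activity: float = BULK_ACTIVITY
    seed: int = 0
    ideal_gas: bool = False
    keep_configurations: int = 5


@dataclass
class HydrationResult:
    occupancies: np.ndarray
    mean_occupancy: float
    configurations: list[np.ndarray]
    acceptance: dict
    seed: int

    def __post_init__(self):
        if len(self.occupancies):
            assert abs(self.mean_occupancy - float(np.mean(self.occupancies))) < 1e-9


# ---------------------------------------------------------------------------
# Coordination
# ---------------------------------------------------------------------------

def coordination_shell(structure: Structure, ion_index: int,
                       cutoff: float = 2.5) -> CoordinationShell:
    """O/N atoms within ``cutoff`` of the ion, sorted by distance."""
    try:
        ion = structure.atoms[ion_index]
    except IndexError:
        raise StructureError(f"ion index {ion_index} out of range") from None
    pos = np.asarray(ion.position)
    entries = []
    for i, a in enumerate(structure.atoms):
        if i == ion_index or a.element.upper() not in ("O", "N"):
            continue
        d = float(np.linalg.norm(np.asarray(a.position) - pos))
        if d <= cutoff:
            entries.append((d, i, a.name))
    entries.sort()
    return CoordinationShell(
        ion_index=ion_index,
        ligand_indices=[e[1] for e in entries],
        ligand_names=[e[2] for e in entries],
        distances=[e[0] for e in entries],
        cutoff=cutoff,
    )


def _ion_energy(pos, coords, charges, lj_a, lj_b, ion_q, ion_a, ion_b):
    d = coords - pos
    r = np.sqrt(np.sum(d * d, axis=1))
    r = np.maximum(r, 0.3)
    inv6 = 1.0 / r ** 6
    return float(np.sum(ion_a * lj_a * inv6 * inv6 - ion_b * lj_b * inv6
                        + COULOMB_K * ion_q * charges / r))


def place_ion(structure: Structure, spec: IonSiteSpec) -> tuple[Structure, CoordinationShell]:
    """Grid-scan + local minimization of the ion's nonbonded energy.

    Deterministic for a fixed grid. Fails if no grid point achieves at
    least 4 coordinating O/N atoms within 2.5 Å after minimization.
    """
    from scipy.optimize import minimize

    coords = structure.coordinates
    charges = np.array([a.partial_charge or 0.0 for a in structure.atoms])
    lj = np.array([_ELEM_LJ.get(a.element.upper(), (100.0, 10.0)) for a in structure.atoms])
    ion_a, ion_b = _ELEM_LJ[spec.element.upper()]
    center = np.asarray(spec.center)

    n = max(3, int(2 * spec.radius / spec.grid_spacing) + 1)
    axis = np.linspace(-spec.radius, spec.radius, n)
    best = None
    for x in axis:
        for y in axis:
            for z in axis:
                if x * x + y * y + z * z > spec.radius ** 2:
                    continue
                p = center + (x, y, z)
                e = _ion_energy(p, coords, charges, lj[:, 0], lj[:, 1],
                                spec.charge, ion_a, ion_b)
                if best is None or e < best[0]:
                    best = (e, p)
    if best is None:
        raise PlacementError("search sphere contains no grid points")

    res = minimize(lambda p: _ion_energy(p, coords, charges, lj[:, 0], lj[:, 1],
                                         spec.charge, ion_a, ion_b),
                   best[1], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000})
    pos = res.x
    serial = max(a.serial for a in structure.atoms) + 1
    ion_atom = Atom(serial=serial, name=spec.element.upper(), element=spec.element.upper(),
                    residue_name=spec.element.upper(), residue_number=serial,
                    chain_id="I", position=tuple(pos), partial_charge=spec.charge,
                    record="HETATM")
    new = Structure(structure.atoms + [ion_atom], title=structure.title,
                    source=structure.source)
    shell = coordination_shell(new, len(new.atoms) - 1, cutoff=2.5)
    if shell.coordination_number < 4:
        raise PlacementError(
            f"best site achieves only {shell.coordination_number} ligands; "
            f"nearest candidates: {shell.ligand_names}")
    return new, shell


# ---------------------------------------------------------------------------
# Water flooding
# ---------------------------------------------------------------------------

def _water_sites(o_pos, orient_u, orient_p):
    half = _THETA / 2.0
    h1 = o_pos + _ROH * (np.cos(half) * orient_u + np.sin(half) * orient_p)
    h2 = o_pos + _ROH * (np.cos(half) * orient_u - np.sin(half) * orient_p)
    return np.array([o_pos, h1, h2])


def _random_water(rng, center, radius):
    while True:
        p = rng.uniform(-1, 1, 3)
        if np.dot(p, p) <= 1.0:
            break
    o = center + radius * p
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(u, ref)
    perp /= np.linalg.norm(perp)
    return _water_sites(o, u, perp)


class _FloodState:
    """Mutable water set with incremental pairwise energies."""

    def __init__(self, solute_coords, solute_charges, solute_lj, beta, ideal):
        self.waters: list[np.ndarray] = []  # each (3, 3): O, H1, H2
        self.sol_xyz = solute_coords
        self.sol_q = solute_charges
        site_a = np.array([_OW_LJ[0], _HW_LJ[0], _HW_LJ[0]])
        site_b = np.array([_OW_LJ[1], _HW_LJ[1], _HW_LJ[1]])
        self.sol_a = solute_lj[:, 0][:, None] * site_a[None, :]
        self.sol_b = solute_lj[:, 1][:, None] * site_b[None, :]
        self.ww_a = site_a[:, None] * site_a[None, :]
        self.ww_b = site_b[:, None] * site_b[None, :]
        self.beta = beta
        self.ideal = ideal

    def water_energy(self, sites, skip: int | None = None) -> float:
        if self.ideal:
            return 0.0
        e = 0.0
        if len(self.sol_xyz):
            d = self.sol_xyz[:, None, :] - sites[None, :, :]
            r = np.sqrt(np.sum(d * d, axis=-1))
            r = np.maximum(r, 0.3)
            e += COULOMB_K * float(np.sum(self.sol_q[:, None] * np.array(_WATER_Q)[None, :] / r))
            inv6 = 1.0 / r ** 6
            e += float(np.sum(self.sol_a * inv6 * inv6 - self.sol_b * inv6))
        qw = np.array(_WATER_Q)
        for k, w in enumerate(self.waters):
            if skip is not None and k == skip:
                continue
            d = w[:, None, :] - sites[None, :, :]
            r = np.sqrt(np.sum(d * d, axis=-1))
            r = np.maximum(r, 0.3)
            e += COULOMB_K / _WW_SCREEN * float(np.sum(qw[:, None] * qw[None, :] / r))
            inv6 = 1.0 / r ** 6
            e += float(np.sum(self.ww_a * inv6 * inv6 - self.ww_b * inv6))
        return e


def water_flood(structure: Structure, cavity: CavitySpec,
                params: WaterFloodParams = WaterFloodParams()) -> HydrationResult:
    """Over-saturate the cavity, then prune by grand-canonical Metropolis MC.

    ``structure`` provides the fixed solute (all its non-water atoms); any
    waters already present are ignored so the method decides hydration
    itself. Occupancy is the number of water oxygens inside the hard wall,
    averaged over post-burn-in sweeps.
    """
    if cavity.hard_wall_radius == 0.0:
        return HydrationResult(np.zeros(1), 0.0, [], {"note": "zero-radius cavity"},
                               params.seed)
    rng = np.random.Generator(np.random.Philox(key=[int(params.seed), 0xF100D]))
    center = np.asarray(cavity.center)
    radius = cavity.hard_wall_radius
    solute = [a for a in structure.atoms if not a.is_water]
    sol_xyz = np.array([a.position for a in solute]) if solute else np.empty((0, 3))
    sol_q = np.array([a.partial_charge or 0.0 for a in solute])
    sol_lj = np.array([_ELEM_LJ.get(a.element.upper(), (100.0, 10.0)) for a in solute])
    beta = 1.0 / (KB * params.temperature)
    st = _FloodState(sol_xyz, sol_q, sol_lj, beta, params.ideal_gas)

    # stage 1: over-saturation with clash rejection only. The initial count
    # overshoots the probe-estimated accessible volume by 30% so the MC
    # prunes downward toward the most probable occupancy.
    probe_rng = np.random.Generator(np.random.Philox(key=[int(params.seed), 0xBE]))
    n_probe = 20000
    while True:
        p = probe_rng.uniform(-1, 1, (n_probe, 3))
        inside = np.sum(p * p, axis=1) <= 1.0
        if inside.sum() > 1000:
            break
    probes = center + radius * p[inside]
    if len(sol_xyz):
        dmin = np.min(np.linalg.norm(
            probes[:, None, :] - sol_xyz[None, :, :], axis=-1), axis=1)
        frac_free = float(np.mean(dmin >= 2.4))
    else:
        frac_free = 1.0
    target = int(1.3 * BULK_WATER_DENSITY * cavity.volume * frac_free) + 2
    for _ in range(200 * target):
        if len(st.waters) >= target:
            break
        sites = _random_water(rng, center, radius)
        o = sites[0]
        if len(sol_xyz) and np.min(np.linalg.norm(sol_xyz - o, axis=1)) < 2.25:
            continue
        if st.waters and min(np.linalg.norm(w[0] - o) for w in st.waters) < 2.35:
            continue
        st.waters.append(sites)
    if not st.waters:
        # genuinely occluded cavity only if even a bare grid fails
        probe = [center + radius * 0.5 * v for v in
                 np.array([[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0],
                           [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)]
        ok = any(len(sol_xyz) == 0 or np.min(np.linalg.norm(sol_xyz - p, axis=1)) >= 2.25
                 for p in probe)
        if not ok:
            raise FloodingError("cavity fully occluded: no insertion succeeded")

    # stage 2: GC Metropolis pruning/equilibration
    z_v = params.activity * cavity.volume
    att = {"insert": 0, "delete": 0, "move": 0, "rotate": 0}
    acc = {"insert": 0, "delete": 0, "move": 0, "rotate": 0}
    occupancies = []
    configs: list[np.ndarray] = []
    n_burn = int(params.burn_in_fraction * params.n_sweeps)
    for sweep in range(params.n_sweeps):
        n_moves = max(8, len(st.waters))
        for _ in range(n_moves):
            u = rng.random()
            n = len(st.waters)
            if u < 0.25:  # insertion
                att["insert"] += 1
                sites = _random_water(rng, center, radius)
                de = st.water_energy(sites)
                if rng.random() < min(1.0, z_v / (n + 1) * np.exp(-float(np.clip(beta * de, -500.0, 500.0)))):
                    st.waters.append(sites)
                    acc["insert"] += 1
            elif u < 0.50 and n > 0:  # deletion
                att["delete"] += 1
                k = int(rng.integers(n))
                de = -st.water_energy(st.waters[k], skip=k)
                if rng.random() < min(1.0, n / z_v * np.exp(-float(np.clip(beta * de, -500.0, 500.0)))):
                    st.waters.pop(k)
                    acc["delete"] += 1
            elif u < 0.80 and n > 0:  # rigid translation (orientation kept)
                att["move"] += 1
                k = int(rng.integers(n))
                old = st.waters[k]
                shift = rng.normal(scale=0.2, size=3)
                if np.linalg.norm(old[0] + shift - center) > radius:
                    continue  # hard wall: no exchange across the boundary
                new = old + shift
                de = st.water_energy(new, skip=k) - st.water_energy(old, skip=k)
                if rng.random() < min(1.0, np.exp(-float(np.clip(beta * de, -500.0, 500.0)))):
                    st.waters[k] = new
                    acc["move"] += 1
            elif n > 0:  # small rotation about the oxygen
                att["rotate"] += 1
                k = int(rng.integers(n))
                old = st.waters[k]
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = rng.normal(scale=0.5)
                c, s, o = np.cos(angle), np.sin(angle), old[0]
                kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                               [-axis[1], axis[0], 0]])
                rot = np.eye(3) + s * kx + (1 - c) * (kx @ kx)
                new = (old - o) @ rot.T + o
                de = st.water_energy(new, skip=k) - st.water_energy(old, skip=k)
                if rng.random() < min(1.0, np.exp(-float(np.clip(beta * de, -500.0, 500.0)))):
                    st.waters[k] = new
                    acc["rotate"] += 1
        if sweep >= n_burn:
            occupancies.append(len(st.waters))
            if len(configs) < params.keep_configurations and (sweep - n_burn) % max(
                    1, (params.n_sweeps - n_burn) // max(1, params.keep_configurations)) == 0:
                configs.append(np.array([w for w in st.waters]).reshape(-1, 3)
                               if st.waters else np.empty((0, 3)))
    occupancies = np.array(occupancies, dtype=float)
    rates = {k: (acc[k] / att[k] if att[k] else 0.0) for k in att}
    return HydrationResult(
        occupancies=occupancies,
        mean_occupancy=float(np.mean(occupancies)) if len(occupancies) else 0.0,
        configurations=configs,
        acceptance={"attempted": att, "accepted": acc, "rates": rates},
        seed=params.seed,
    )


def calibrate_activity(radius: float = 6.0, temperature: float = 300.0,
                       seed: int = 0, n_iterations: int = 6,
                       n_sweeps: int = 1200) -> float:
    """Activity z such that a solute-free cavity holds bulk-density water.

    Fixed-point iteration on ln z against the target ⟨N⟩ = ρ_bulk·V; the
    result for the packaged water model is shipped as ``BULK_ACTIVITY``.
    """
    cavity = CavitySpec((0.0, 0.0, 0.0), radius)
    # a single far-away uncharged dummy: effectively a solute-free cavity
    empty = Structure([Atom(1, "DU", "C", "DUM", 1, "X", (999.0, 999.0, 999.0),
                            partial_charge=0.0)], source="fixture")
    target = BULK_WATER_DENSITY * cavity.volume
    z = 0.05
    for it in range(n_iterations):
        res = water_flood(empty, cavity,
                          WaterFloodParams(n_sweeps=n_sweeps, activity=z,
                                           temperature=temperature,
                                           seed=seed + it))
        n_mean = max(res.mean_occupancy, 0.2)
        z *= (target / n_mean) ** 0.8
    return float(z)


# ---------------------------------------------------------------------------
# Phosphate drift
# ---------------------------------------------------------------------------

def phosphate_drift(frames: np.ndarray, reference_coords: np.ndarray,
                    selection: list[int], align_indices: list[int] | None = None) -> float:
    """Max centroid displacement (Å) of the selected atoms over a trajectory.

    ``frames`` is (n_frames, n_atoms, 3). If ``align_indices`` is given each
    frame is first superposed (Kabsch) onto the reference using those atoms.
    Zero frames → 0 Å by definition (no dynamics, no drift).
    """
    if not selection:
        raise StructureError("empty selection")
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0:
        return 0.0
    ref = np.asarray(reference_coords, dtype=float)
    ref_centroid = ref[selection].mean(axis=0)
    worst = 0.0
    for f in frames:
        if align_indices:
            f = _kabsch_superpose(f, ref, align_indices)
        d = float(np.linalg.norm(f[selection].mean(axis=0) - ref_centroid))
        worst = max(worst, d)
    return worst


def _kabsch_superpose(frame, ref, idx):
    p = frame[idx] - frame[idx].mean(axis=0)
    q = ref[idx] - ref[idx].mean(axis=0)
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    return (frame - frame[idx].mean(axis=0)) @ r + ref[idx].mean(axis=0)
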
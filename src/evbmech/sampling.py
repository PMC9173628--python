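"""Langevin dynamics in a restrained spherical droplet plus the FEP mapping protocol.

The droplet model: a mobile core inside ``inner_radius``, a harmonic radial
restraint pulling strays back toward the surface, and atoms that start
beyond ``frozen_beyond`` held fixed for the whole run. This replaces the
surface-constrained solvent + Langevin-dipole + continuum layering of
full-scale EVB packages with a deterministic desk-scale boundary; it is a
declared physics simplification, not an approximation of those layers.

Integration is BAOAB discretization of Langevin dynamics on the mapping
potential ε_λ = Σ λ_i ε_i. Window runs are seeded independently from the
master seed through a counter-based (Philox) generator, so results do not
depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB, KCAL_PER_MOL_TO_AMU_A2_FS2
from .energy import ground_state_batch, mapping_eval
from .topology import EVBTopology, TopologyError

__all__ = [
    "LangevinParams", "SphericalBoundary", "DistanceRestraint",
    "PositionRestraint", "EVBSystem", "MappingSchedule", "WindowSample",
    "Trajectory", "IntegrationError", "run_langevin", "run_mapping",
    "minimize_system",
]

_ENERGY_DIVERGENCE = 1.0e6


class IntegrationError(RuntimeError):
    def __init__(self, message: str, step: int | None = None):
        self.step = step
        if step is not None:
            message = f"step {step}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class LangevinParams:
    temperature: float = 300.0   # K
    friction: float = 1.0        # 1/ps
    timestep: float = 1.0        # fs
    n_steps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")


@dataclass(frozen=True)
class SphericalBoundary:
    center: tuple[float, float, float]
    inner_radius: float
    restraint_k: float = 10.0     # kcal/mol/Å²
    frozen_beyond: float = 1.0e9  # Å

    def __post_init__(self):
        if not 0 < self.inner_radius < self.frozen_beyond:
            raise ValueError("need 0 < inner_radius < frozen_beyond")


@dataclass(frozen=True)
class DistanceRestraint:
    i: int
    j: int
    force_constant: float = 10.0  # kcal/mol/Å² (standard pair-constraint strength)
    target: float = 0.0

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")


@dataclass(frozen=True)
class PositionRestraint:
    index: int
    k: float
    target: tuple[float, float, float]


@dataclass
class EVBSystem:
    """A topology bound to coordinates, restraints, and a droplet boundary."""

    topology: EVBTopology
    coordinates: np.ndarray
    boundary: SphericalBoundary | None = None
    distance_restraints: list[DistanceRestraint] = field(default_factory=list)
    position_restraints: list[PositionRestraint] = field(default_factory=list)
    mobile: np.ndarray | None = None  # (n, 3) bool; False = frozen dof

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.topology.n_atoms, 3):
            raise TopologyError("coordinates do not match topology atom count")
        if self.mobile is None:
            self.mobile = np.ones_like(self.coordinates, dtype=bool)
        else:
            self.mobile = np.asarray(self.mobile, dtype=bool)
        if self.boundary is not None:
            center = np.asarray(self.boundary.center)
            r = np.linalg.norm(self.coordinates - center, axis=1)
            self.mobile[r > self.boundary.frozen_beyond, :] = False

    def replace_coordinates(self, coords: np.ndarray) -> "EVBSystem":
        out = EVBSystem(self.topology, np.array(coords), self.boundary,
                        list(self.distance_restraints), list(self.position_restraints),
                        self.mobile.copy())
        return out

    # -- restraint terms ----------------------------------------------------

    def _restraint_arrays(self):
        if getattr(self, "_ra", None) is None:
            pr = self.position_restraints
            self._ra = {
                "pr_idx": np.array([p.index for p in pr], dtype=np.intp),
                "pr_k": np.array([p.k for p in pr]),
                "pr_t": np.array([p.target for p in pr]).reshape(len(pr), 3),
                "dr_i": np.array([r.i for r in self.distance_restraints], dtype=np.intp),
                "dr_j": np.array([r.j for r in self.distance_restraints], dtype=np.intp),
                "dr_k": np.array([r.force_constant for r in self.distance_restraints]),
                "dr_t": np.array([r.target for r in self.distance_restraints]),
            }
        return self._ra

    def restraint_energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        e = 0.0
        f = np.zeros_like(coords)
        ra = self._restraint_arrays()
        if self.boundary is not None and self.boundary.restraint_k > 0:
            center = np.asarray(self.boundary.center)
            d = coords - center
            r = np.linalg.norm(d, axis=1)
            out = r > self.boundary.inner_radius
            if np.any(out):
                dr = r[out] - self.boundary.inner_radius
                e += float(np.sum(0.5 * self.boundary.restraint_k * dr ** 2))
                f[out] -= (self.boundary.restraint_k * dr / r[out])[:, None] * d[out]
        if len(ra["dr_i"]):
            d = coords[ra["dr_j"]] - coords[ra["dr_i"]]
            r = np.maximum(np.linalg.norm(d, axis=1), 1e-9)
            dr = r - ra["dr_t"]
            e += float(np.sum(0.5 * ra["dr_k"] * dr ** 2))
            fv = (ra["dr_k"] * dr / r)[:, None] * d
            np.add.at(f, ra["dr_i"], fv)
            np.add.at(f, ra["dr_j"], -fv)
        if len(ra["pr_idx"]):
            d = coords[ra["pr_idx"]] - ra["pr_t"]
            e += float(np.sum(0.5 * ra["pr_k"] * np.sum(d * d, axis=1)))
            f[ra["pr_idx"]] -= ra["pr_k"][:, None] * d
        return e, f

    def mapping_energy_forces(self, coords: np.ndarray, lam: np.ndarray,
                              with_restraints: bool = True):
        """(ε_λ + restraints, force, per-state ε totals)."""
        lam = np.asarray(lam, dtype=float)
        eps, f = mapping_eval(self.topology, coords, lam)
        e = float(np.dot(lam, eps))
        if with_restraints:
            er, fr = self.restraint_energy_forces(coords)
            e += er
            f += fr
        return e, f, eps


@dataclass(frozen=True)
class MappingSchedule:
    """λ path between two diabatic states; 55 uniform windows by default."""

    n_windows: int = 55
    steps_per_window: int = 3000
    equilibration_fraction: float = 0.5
    state_from: int = 0  # positional index into topology.states
    state_to: int = 1
    sample_stride: int = 5

    def __post_init__(self):
        if self.n_windows < 2:
            raise ValueError("need at least 2 windows")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration fraction in [0, 1)")

    def lambdas(self, n_states: int) -> np.ndarray:
        lam = np.zeros((self.n_windows, n_states))
        x = np.linspace(0.0, 1.0, self.n_windows)
        lam[:, self.state_from] = 1.0 - x
        lam[:, self.state_to] = x
        return lam


@dataclass
class WindowSample:
    index: int
    lam: np.ndarray
    eps: np.ndarray       # (n_frames, n_states)
    e_ground: np.ndarray  # (n_frames,)
    gap: np.ndarray       # (n_frames,) Δε = ε_from − ε_to
    final_coords: np.ndarray | None = None


@dataclass
class Trajectory:
    coords: np.ndarray       # (n_frames, n_atoms, 3)
    energies: np.ndarray     # potential incl. restraints
    kinetic: np.ndarray
    eps: np.ndarray          # (n_frames, n_states)
    final_coords: np.ndarray
    final_velocities: np.ndarray


def _window_rng(master_seed: int, window_index: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[int(master_seed), int(window_index)]))


def run_langevin(system: EVBSystem, params: LangevinParams, lam: np.ndarray,
                 rng: np.random.Generator | None = None,
                 initial_velocities: np.ndarray | None = None,
                 sample_stride: int = 10, store_coords: bool = False) -> Trajectory:
    """BAOAB Langevin dynamics on the mapping potential ε_λ.

    Fixed seed ⇒ bitwise-reproducible trajectory; frozen degrees of freedom
    never move. Raises :class:`IntegrationError` if the potential diverges.
    """
    top = system.topology
    lam = np.asarray(lam, dtype=float)
    if rng is None:
        rng = np.random.Generator(np.random.Philox(key=[int(params.seed), 0]))
    x = np.array(system.coordinates)
    m = top.masses[:, None]
    mobile = system.mobile
    conv = KCAL_PER_MOL_TO_AMU_A2_FS2
    kbt = KB * params.temperature
    if initial_velocities is None:
        v = rng.normal(size=x.shape) * np.sqrt(kbt * conv / m)
    else:
        v = np.array(initial_velocities)
    v[~mobile] = 0.0
    dt = params.timestep
    gamma = params.friction * 1e-3  # 1/ps → 1/fs
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    e, f, eps = system.mapping_energy_forces(x, lam)
    if not np.isfinite(e) or abs(e) > _ENERGY_DIVERGENCE:
        raise IntegrationError(f"initial potential energy diverged ({e!r})", 0)
    frames_x, frames_e, frames_k, frames_eps = [], [], [], []
    sigma_v = np.sqrt(kbt * conv / m)
    for step in range(params.n_steps):
        v = np.where(mobile, v + 0.5 * dt * f * conv / m, 0.0)
        x = np.where(mobile, x + 0.5 * dt * v, x)
        if gamma > 0:
            noise = rng.normal(size=x.shape)
            v = np.where(mobile, c1 * v + c2 * sigma_v * noise, 0.0)
        elif params.friction == 0.0:
            pass  # deterministic (NVE) limit
        x = np.where(mobile, x + 0.5 * dt * v, x)
        e, f, eps = system.mapping_energy_forces(x, lam)
        if not np.isfinite(e) or abs(e) > _ENERGY_DIVERGENCE:
            raise IntegrationError(f"potential energy diverged ({e!r})", step)
        v = np.where(mobile, v + 0.5 * dt * f * conv / m, 0.0)
        if (step + 1) % sample_stride == 0:
            ke = 0.5 * float(np.sum(m * v * v)) / conv
            frames_e.append(e)
            frames_k.append(ke)
            frames_eps.append(eps.copy())
            if store_coords:
                frames_x.append(x.copy())
    return Trajectory(
        coords=np.array(frames_x) if store_coords else np.empty((0, top.n_atoms, 3)),
        energies=np.array(frames_e),
        kinetic=np.array(frames_k),
        eps=np.array(frames_eps) if frames_eps else np.empty((0, top.n_states)),
        final_coords=x,
        final_velocities=v,
    )


def run_mapping(system: EVBSystem, schedule: MappingSchedule, params: LangevinParams,
                store_coords: bool = False, progress: bool = False) -> list[WindowSample]:
    """Drag the system through the λ windows; one equilibrated sample set each.

    Each window starts from the previous window's final configuration and is
    integrated with its own counter-based stream derived from
    ``params.seed`` and the window index.
    """
    top = system.topology
    lam_path = schedule.lambdas(top.n_states)
    n_eq = int(schedule.equilibration_fraction * schedule.steps_per_window)
    h = top.coupling_matrix()
    h12 = h[schedule.state_from, schedule.state_to]
    coords = np.array(system.coordinates)
    windows: list[WindowSample] = []
    iterator = range(schedule.n_windows)
    for w in iterator:
        rng = _window_rng(params.seed, w)
        sys_w = system.replace_coordinates(coords)
        p = LangevinParams(params.temperature, params.friction, params.timestep,
                           schedule.steps_per_window, params.seed)
        try:
            traj = run_langevin(sys_w, p, lam_path[w], rng=rng,
                                sample_stride=schedule.sample_stride,
                                store_coords=store_coords)
        except IntegrationError as exc:
            raise IntegrationError(f"window {w}: {exc}") from exc
        coords = traj.final_coords
        n_skip = max(1, n_eq // schedule.sample_stride)
        eps = traj.eps[n_skip:]
        sub = eps[:, [schedule.state_from, schedule.state_to]]
        e_g = ground_state_batch(sub, h12)
        gap = sub[:, 0] - sub[:, 1]
        windows.append(WindowSample(index=w, lam=lam_path[w], eps=eps,
                                    e_ground=e_g, gap=gap,
                                    final_coords=coords.copy() if store_coords else None))
    return windows


def minimize_system(system: EVBSystem, lam: np.ndarray, max_iter: int = 500,
                    tol: float = 1e-6) -> np.ndarray:
    """L-BFGS minimization of the mapping potential over mobile coordinates."""
    from scipy.optimize import minimize

    x0 = np.array(system.coordinates)
    mobile = system.mobile
    idx = np.where(mobile.ravel())[0]

    def fun(z):
        x = x0.copy().ravel()
        x[idx] = z
        x = x.reshape(x0.shape)
        e, f, _ = system.mapping_energy_forces(x, lam)
        return e, -f.ravel()[idx]

    res = minimize(fun, x0.ravel()[idx], jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": tol})
    x = x0.copy().ravel()
    x[idx] = res.x
    return x.reshape(x0.shape)
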
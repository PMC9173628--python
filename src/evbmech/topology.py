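"""EVB topologies: diabatic states, couplings, and the plain-text parameter format.

A topology holds one shared atom list and 2–3 diabatic (valence-bond
resonance) states. Each state carries its own bonding pattern — reacting
bonds are Morse, framework bonds harmonic — its own partial charges, and a
gas-phase shift α that sets the state's asymptotic offset. Off-diagonal
coupling between states is a constant A by default (a distance-dependent
A·exp(−μ·r) form is parsed but off unless requested), since the coupling is
the calibrated quantity, not a measured one.

Lennard-Jones parameters follow the geometric A/B convention of classical
EVB packages: E_LJ(i,j) = A_i·A_j/r¹² − B_i·B_j/r⁶.

Nonbonded exclusions use the union of all states' connectivity (1-2 and 1-3
excluded, 1-4 scaled) so the pair list is state-independent; only the
charges differ between states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BondTerm", "AngleTerm", "TorsionTerm", "DiabaticState", "CouplingTerm",
    "EVBTopology", "EnergyBreakdown", "TopologyError", "TopologyParseError",
    "read_topology", "write_topology",
]


class TopologyError(ValueError):
    pass


class TopologyParseError(TopologyError):
    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class BondTerm:
    """Bonded pair. kind='morse' uses (d_e, a, r0) with E(r0) = −D_e and
    E(∞) = 0, so cleavage cost appears explicitly in the diabatic gap;
    kind='harmonic' uses (k, r0) with E = ½k(r−r0)²."""
    i: int
    j: int
    kind: str
    p1: float  # D_e or k
    p2: float  # a or r0
    p3: float = 0.0  # r0 (morse only)

    def __post_init__(self):
        if self.kind not in ("morse", "harmonic"):
            raise TopologyError(f"unknown bond kind {self.kind!r}")
        if self.kind == "morse" and self.p1 <= 0:
            raise TopologyError("Morse D_e must be positive")
        if self.i == self.j:
            raise TopologyError("bond endpoints must differ")

    @property
    def r0(self) -> float:
        return self.p3 if self.kind == "morse" else self.p2


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int  # vertex
    k: int
    k_theta: float  # kcal/mol/rad²
    theta0: float   # degrees


@dataclass(frozen=True)
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    v: float      # kcal/mol
    n: int
    phi0: float   # degrees


@dataclass
class DiabaticState:
    index: int
    bonds: list[BondTerm]
    angles: list[AngleTerm]
    torsions: list[TorsionTerm]
    charges: np.ndarray
    shift: float = 0.0  # gas-phase shift α, kcal/mol

    def net_charge(self) -> float:
        return float(np.sum(self.charges))


@dataclass(frozen=True)
class CouplingTerm:
    """H_ij between states i and j: A·exp(−μ·r_pair); μ = 0 gives constant A."""
    state_i: int
    state_j: int
    a: float
    mu: float = 0.0
    pair: tuple[int, int] | None = None

    def __post_init__(self):
        if self.a < 0:
            raise TopologyError("coupling amplitude A must be non-negative")
        if self.state_i == self.state_j:
            raise TopologyError("coupling requires two distinct states")
        if self.mu != 0.0 and self.pair is None:
            raise TopologyError("distance-dependent coupling needs an atom pair")

    def value(self, coords: np.ndarray | None = None) -> float:
        if self.mu == 0.0:
            return self.a
        i, j = self.pair
        r = float(np.linalg.norm(coords[i] - coords[j]))
        return self.a * np.exp(-self.mu * r)


@dataclass
class EVBTopology:
    atom_names: list[str]
    atom_types: list[str]
    masses: np.ndarray
    lj_a: dict[str, float]
    lj_b: dict[str, float]
    states: list[DiabaticState]
    couplings: list[CouplingTerm]
    evb_region: list[int] = field(default_factory=list)
    scale14_elec: float = 0.5
    scale14_lj: float = 0.5

    def __post_init__(self):
        n = len(self.atom_names)
        if len(self.states) < 2:
            raise TopologyError("an EVB topology needs at least 2 states")
        for st in self.states:
            if len(st.charges) != n:
                raise TopologyError(f"state {st.index}: charge count != atom count")
            for b in st.bonds:
                if not (0 <= b.i < n and 0 <= b.j < n):
                    raise TopologyError(f"state {st.index}: bond references missing atom")
        indices = {s.index for s in self.states}
        for c in self.couplings:
            if c.state_i not in indices or c.state_j not in indices:
                raise TopologyError("coupling references undeclared state")
        missing = [t for t in self.atom_types if t not in self.lj_a]
        if missing:
            raise TopologyError(f"no LJ parameters for atom type(s) {sorted(set(missing))!r}")
        self.masses = np.asarray(self.masses, dtype=float)
        self._compiled: dict[int, dict] = {}

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state(self, index: int) -> DiabaticState:
        for st in self.states:
            if st.index == index:
                return st
        raise TopologyError(f"no diabatic state with index {index}")

    def coupling_matrix(self, coords: np.ndarray | None = None) -> np.ndarray:
        h = np.zeros((self.n_states, self.n_states))
        order = {s.index: k for k, s in enumerate(self.states)}
        for c in self.couplings:
            i, j = order[c.state_i], order[c.state_j]
            h[i, j] = h[j, i] = c.value(coords)
        return h

    # ---- nonbonded pair list (state-independent) --------------------------

    def _connectivity(self) -> set[tuple[int, int]]:
        conn = set()
        for st in self.states:
            for b in st.bonds:
                conn.add((min(b.i, b.j), max(b.i, b.j)))
        return conn

    def compiled_pairs(self) -> dict:
        """Pair index arrays with exclusion/1-4 scaling, cached."""
        if "pairs" in self._compiled:
            return self._compiled["pairs"]
        n = self.n_atoms
        conn = self._connectivity()
        neigh: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j in conn:
            neigh[i].add(j)
            neigh[j].add(i)
        excluded = set(conn)  # 1-2
        one_four = set()
        for i, j in conn:  # 1-3 via each bond's neighbours
            for k in neigh[i]:
                if k != j:
                    excluded.add((min(k, j), max(k, j)))
            for k in neigh[j]:
                if k != i:
                    excluded.add((min(k, i), max(k, i)))
        # 1-4: walk three bonds
        for i, j in conn:
            for a in neigh[i]:
                if a == j:
                    continue
                for b in neigh[j]:
                    if b == i or b == a:
                        continue
                    p = (min(a, b), max(a, b))
                    if p not in excluded:
                        one_four.add(p)
        ii, jj, se, sl = [], [], [], []
        a_arr = np.array([self.lj_a[t] for t in self.atom_types])
        b_arr = np.array([self.lj_b[t] for t in self.atom_types])
        for i, j in itertools.combinations(range(n), 2):
            p = (i, j)
            if p in excluded:
                continue
            scale_e = self.scale14_elec if p in one_four else 1.0
            scale_l = self.scale14_lj if p in one_four else 1.0
            ii.append(i)
            jj.append(j)
            se.append(scale_e)
            sl.append(scale_l)
        ii = np.array(ii, dtype=np.intp)
        jj = np.array(jj, dtype=np.intp)
        out = {
            "i": ii, "j": jj,
            "scale_elec": np.array(se), "scale_lj": np.array(sl),
            "aij": a_arr[ii] * a_arr[jj], "bij": b_arr[ii] * b_arr[jj],
        }
        self._compiled["pairs"] = out
        return out


@dataclass
class EnergyBreakdown:
    bond: float
    angle: float
    torsion: float
    lj: float
    electrostatic: float
    shift: float
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.torsion + self.lj
                + self.electrostatic + self.shift + self.restraint)


# ---------------------------------------------------------------------------
# Plain-text topology format
# ---------------------------------------------------------------------------
#
#   [atoms]
#   <index> <name> <type> <mass>
#   [lj]
#   <type> <A> <B>
#   [evb_region]
#   <index> ...
#   [state <N>]
#   shift <alpha>
#   charge <index> <q>
#   bond <i> <j> morse <De> <a> <r0>
#   bond <i> <j> harmonic <k> <r0>
#   angle <i> <j> <k> <k_theta> <theta0>
#   torsion <i> <j> <k> <l> <V> <n> <phi0>
#   [couplings]
#   pair <i> <j> A <value> [mu <value> atoms <a> <b>]
#
# Indices are 0-based and never serialized anywhere else. '#' starts a comment.

def read_topology(path) -> EVBTopology:
    atoms: list[tuple[str, str, float]] = []
    lj_a: dict[str, float] = {}
    lj_b: dict[str, float] = {}
    evb_region: list[int] = []
    states: dict[int, dict] = {}
    couplings: list[CouplingTerm] = []
    section = None
    current_state: int | None = None

    def fail(msg, ln):
        raise TopologyParseError(msg, ln)

    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    fail("unterminated section header", ln)
                header = line[1:-1].strip().lower()
                if header.startswith("state"):
                    parts = header.split()
                    if len(parts) != 2 or not parts[1].isdigit():
                        fail("state section needs a numeric index", ln)
                    current_state = int(parts[1])
                    states[current_state] = {"shift": 0.0, "charges": {}, "bonds": [],
                                             "angles": [], "torsions": []}
                    section = "state"
                elif header in ("atoms", "lj", "evb_region", "couplings"):
                    section = header
                    current_state = None
                else:
                    fail(f"unknown section {header!r}", ln)
                continue
            tok = line.split()
            try:
                if section == "atoms":
                    idx, name, typ, mass = int(tok[0]), tok[1], tok[2], float(tok[3])
                    if idx != len(atoms):
                        fail(f"atom index {idx} out of order", ln)
                    atoms.append((name, typ, mass))
                elif section == "lj":
                    lj_a[tok[0]] = float(tok[1])
                    lj_b[tok[0]] = float(tok[2])
                elif section == "evb_region":
                    evb_region.extend(int(t) for t in tok)
                elif section == "state":
                    st = states[current_state]
                    if tok[0] == "shift":
                        st["shift"] = float(tok[1])
                    elif tok[0] == "charge":
                        st["charges"][int(tok[1])] = float(tok[2])
                    elif tok[0] == "bond":
                        i, j, kind = int(tok[1]), int(tok[2]), tok[3]
                        if kind == "morse":
                            st["bonds"].append(BondTerm(i, j, "morse", float(tok[4]), float(tok[5]), float(tok[6])))
                        elif kind == "harmonic":
                            st["bonds"].append(BondTerm(i, j, "harmonic", float(tok[4]), float(tok[5])))
                        else:
                            fail(f"unknown bond kind {kind!r}", ln)
                    elif tok[0] == "angle":
                        st["angles"].append(AngleTerm(int(tok[1]), int(tok[2]), int(tok[3]),
                                                      float(tok[4]), float(tok[5])))
                    elif tok[0] == "torsion":
                        st["torsions"].append(TorsionTerm(int(tok[1]), int(tok[2]), int(tok[3]),
                                                          int(tok[4]), float(tok[5]), int(tok[6]),
                                                          float(tok[7])))
                    else:
                        fail(f"unknown state record {tok[0]!r}", ln)
                elif section == "couplings":
                    if tok[0] != "pair":
                        fail(f"unknown coupling record {tok[0]!r}", ln)
                    si, sj = int(tok[1]), int(tok[2])
                    a = mu = None
                    pair = None
                    rest = tok[3:]
                    k = 0
                    while k < len(rest):
                        if rest[k] == "A":
                            a = float(rest[k + 1]); k += 2
                        elif rest[k] == "mu":
                            mu = float(rest[k + 1]); k += 2
                        elif rest[k] == "atoms":
                            pair = (int(rest[k + 1]), int(rest[k + 2])); k += 3
                        else:
                            fail(f"unknown coupling token {rest[k]!r}", ln)
                    if a is None:
                        fail("coupling needs an amplitude A", ln)
                    couplings.append(CouplingTerm(si, sj, a, mu or 0.0, pair))
                else:
                    fail("record outside any section", ln)
            except (IndexError, ValueError, KeyError) as exc:
                if isinstance(exc, TopologyParseError):
                    raise
                fail(f"malformed record: {line!r}", ln)
    if not atoms:
        raise TopologyParseError(f"{path}: no [atoms] section")
    n = len(atoms)
    state_objs = []
    for sidx in sorted(states):
        st = states[sidx]
        q = np.zeros(n)
        for i, qi in st["charges"].items():
            if not 0 <= i < n:
                raise TopologyError(f"state {sidx}: charge index {i} out of range")
            q[i] = qi
        state_objs.append(DiabaticState(sidx, st["bonds"], st["angles"], st["torsions"], q, st["shift"]))
    return EVBTopology(
        atom_names=[a[0] for a in atoms],
        atom_types=[a[1] for a in atoms],
        masses=np.array([a[2] for a in atoms]),
        lj_a=lj_a, lj_b=lj_b,
        states=state_objs, couplings=couplings, evb_region=evb_region,
    )


def write_topology(top: EVBTopology, path) -> str:
    lines = ["[atoms]"]
    for i, (name, typ, m) in enumerate(zip(top.atom_names, top.atom_types, top.masses)):
        lines.append(f"{i} {name} {typ} {m:.4f}")
    lines.append("[lj]")
    for t in sorted(top.lj_a):
        lines.append(f"{t} {top.lj_a[t]:.6f} {top.lj_b[t]:.6f}")
    if top.evb_region:
        lines.append("[evb_region]")
        lines.append(" ".join(str(i) for i in top.evb_region))
    for st in top.states:
        lines.append(f"[state {st.index}]")
        lines.append(f"shift {st.shift:.6f}")
        for i, q in enumerate(st.charges):
            if q != 0.0:
                lines.append(f"charge {i} {q:.6f}")
        for b in st.bonds:
            if b.kind == "morse":
                lines.append(f"bond {b.i} {b.j} morse {b.p1:.4f} {b.p2:.4f} {b.p3:.4f}")
            else:
                lines.append(f"bond {b.i} {b.j} harmonic {b.p1:.4f} {b.p2:.4f}")
        for a in st.angles:
            lines.append(f"angle {a.i} {a.j} {a.k} {a.k_theta:.4f} {a.theta0:.4f}")
        for t in st.torsions:
            lines.append(f"torsion {t.i} {t.j} {t.k} {t.l} {t.v:.4f} {t.n} {t.phi0:.4f}")
    if top.couplings:
        lines.append("[couplings]")
        for c in top.couplings:
            rec = f"pair {c.state_i} {c.state_j} A {c.a:.6f}"
            if c.mu != 0.0:
                rec += f" mu {c.mu:.6f} atoms {c.pair[0]} {c.pair[1]}"
            lines.append(rec)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)
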
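"""Inner-loop kernels for the mapping potential, JIT-compiled when numba is
available; the pure-numpy fallbacks compute identical quantities."""

from __future__ import annotations

import numpy as np

from .constants import COULOMB_K

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=False, fastmath=True)
def pair_eval(coords, ii, jj, aij, bij, qq, lam):
    """LJ (state-independent) + per-state Coulomb energies and mapping force.

    qq has shape (n_states, n_pairs); returns (e_lj, e_coul[n_states], f)."""
    n = coords.shape[0]
    npair = ii.shape[0]
    ns = qq.shape[0]
    e_lj = 0.0
    e_c = np.zeros(ns)
    f = np.zeros((n, 3))
    for p in range(npair):
        i = ii[p]
        j = jj[p]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        inv6 = 1.0 / (r2 * r2 * r2)
        a12 = aij[p] * inv6 * inv6
        b6 = bij[p] * inv6
        e_lj += a12 - b6
        qq_eff = 0.0
        for s in range(ns):
            e_c[s] += COULOMB_K * qq[s, p] / r
            qq_eff += lam[s] * qq[s, p]
        dedr = (-12.0 * a12 + 6.0 * b6) / r - COULOMB_K * qq_eff / r2
        g = dedr / r
        fx = g * dx
        fy = g * dy
        fz = g * dz
        f[i, 0] += fx
        f[i, 1] += fy
        f[i, 2] += fz
        f[j, 0] -= fx
        f[j, 1] -= fy
        f[j, 2] -= fz
    return e_lj, e_c, f


@njit(cache=False, fastmath=True)
def bonded_eval(coords, mi, mj, mde, ma, mr0, hi, hj, hk, hr0,
                ai, aj, ak, akt, at0, weight, f):
    """Morse + harmonic bonds + angles of one state. Accumulates
    weight·force into f in place and returns the state's bonded energy."""
    e = 0.0
    for b in range(mi.shape[0]):
        i = mi[b]
        j = mj[b]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-9:
            r = 1e-9
        ex = np.exp(-ma[b] * (r - mr0[b]))
        om = 1.0 - ex
        e += mde[b] * om * om - mde[b]
        g = 2.0 * mde[b] * ma[b] * om * ex / r * weight
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz
    for b in range(hi.shape[0]):
        i = hi[b]
        j = hj[b]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-9:
            r = 1e-9
        dr = r - hr0[b]
        e += 0.5 * hk[b] * dr * dr
        g = hk[b] * dr / r * weight
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz
    for b in range(ai.shape[0]):
        i = ai[b]
        j = aj[b]
        k = ak[b]
        rijx = coords[i, 0] - coords[j, 0]
        rijy = coords[i, 1] - coords[j, 1]
        rijz = coords[i, 2] - coords[j, 2]
        rkjx = coords[k, 0] - coords[j, 0]
        rkjy = coords[k, 1] - coords[j, 1]
        rkjz = coords[k, 2] - coords[j, 2]
        nij = np.sqrt(rijx * rijx + rijy * rijy + rijz * rijz)
        nkj = np.sqrt(rkjx * rkjx + rkjy * rkjy + rkjz * rkjz)
        ct = (rijx * rkjx + rijy * rkjy + rijz * rkjz) / (nij * nkj)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        dt = theta - at0[b]
        e += 0.5 * akt[b] * dt * dt
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-6:
            st = 1e-6
        dedt = akt[b] * dt * weight
        c1 = dedt / (nij * st)
        c2 = dedt / (nkj * st)
        fix = c1 * (rkjx / nkj - ct * rijx / nij)
        fiy = c1 * (rkjy / nkj - ct * rijy / nij)
        fiz = c1 * (rkjz / nkj - ct * rijz / nij)
        fkx = c2 * (rijx / nij - ct * rkjx / nkj)
        fky = c2 * (rijy / nij - ct * rkjy / nkj)
        fkz = c2 * (rijz / nij - ct * rkjz / nkj)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz
    return e
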
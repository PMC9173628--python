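"""Free energy perturbation over mapping windows and the energy-gap profile.

The reaction coordinate is the diabatic energy gap Δε = ε_reactant − ε_product,
the standard EVB choice: the diabatic crossing seam (Δε = 0) is the transition
state, the reactant basin lies at Δε ≪ 0 and the product basin at Δε ≫ 0.

Window free energies ΔG(λ_m) come from exponential averaging between adjacent
mapping potentials (both directions reported; the profile uses the mean of
forward and reverse increments). The ground-surface profile Δg(Δε) is then
assembled by umbrella-sampling reweighting of each window onto the gap bins:

    Δg(X) = ΔG(λ_m) − k_BT · ln ⟨ δ(Δε − X) · exp(−β(E_g − ε_λm)) ⟩_m

averaged over contributing windows with frame-count weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .sampling import WindowSample

__all__ = ["FEPResult", "FreeEnergyProfile", "ProfileError", "fep_delta_g",
           "us_profile", "extract_barrier"]


class ProfileError(RuntimeError):
    pass


@dataclass
class FEPResult:
    forward: float
    reverse: float
    increments_forward: np.ndarray
    increments_reverse: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def delta_g(self) -> float:
        """Mean of forward and reverse estimates."""
        return 0.5 * (self.forward + self.reverse)

    @property
    def hysteresis(self) -> float:
        return abs(self.forward - self.reverse)

    @property
    def cumulative(self) -> np.ndarray:
        """ΔG(λ_m) relative to window 0, mean of directions."""
        inc = 0.5 * (self.increments_forward + self.increments_reverse)
        return np.concatenate([[0.0], np.cumsum(inc)])


def _mapping_series(window: WindowSample, lam: np.ndarray) -> np.ndarray:
    return window.eps @ np.asarray(lam)


def fep_delta_g(windows: list[WindowSample], temperature: float = 300.0,
                min_ess_fraction: float = 0.05) -> FEPResult:
    """Exponential-averaging FEP over adjacent windows, both directions.

    ΔG_{m→m+1} = −k_BT ln ⟨exp(−β(ε_{λ_{m+1}} − ε_{λ_m}))⟩_m. A window pair
    whose effective sample size falls below ``min_ess_fraction`` of the frame
    count gets a warning attached (overlap diagnostic), not an error.
    """
    if len(windows) < 2:
        raise ProfileError("need at least 2 windows")
    beta = 1.0 / (KB * temperature)
    fwd, rev, warnings = [], [], []
    for m in range(len(windows) - 1):
        w0, w1 = windows[m], windows[m + 1]
        du_f = _mapping_series(w0, w1.lam) - _mapping_series(w0, w0.lam)
        du_r = _mapping_series(w1, w0.lam) - _mapping_series(w1, w1.lam)
        fwd.append(_exp_average(du_f, beta))
        rev.append(-_exp_average(du_r, beta))
        for tag, du in (("forward", du_f), ("reverse", du_r)):
            ess = _effective_sample_size(du, beta)
            if ess < min_ess_fraction * len(du):
                warnings.append(
                    f"windows {m}->{m + 1} ({tag}): effective sample size "
                    f"{ess:.1f} of {len(du)} frames — poor overlap")
    fwd = np.array(fwd)
    rev = np.array(rev)
    return FEPResult(forward=float(fwd.sum()), reverse=float(rev.sum()),
                     increments_forward=fwd, increments_reverse=rev,
                     warnings=warnings)


def _exp_average(du: np.ndarray, beta: float) -> float:
    # numerically stable −kT ln⟨exp(−β·δU)⟩
    z = -beta * du
    zmax = z.max()
    return float(-(zmax + np.log(np.mean(np.exp(z - zmax)))) / beta)


def _effective_sample_size(du: np.ndarray, beta: float) -> float:
    w = np.exp(-beta * (du - du.min()))
    return float(w.sum() ** 2 / np.sum(w * w))


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray
    dg: np.ndarray
    counts: np.ndarray
    barrier: float           # ΔG‡, kcal/mol, relative to the reactant minimum
    dg_rxn: float            # product minimum − reactant minimum
    barrier_se: float = float("nan")
    dg_rxn_se: float = float("nan")
    metadata: dict = field(default_factory=dict)


def us_profile(windows: list[WindowSample], temperature: float = 300.0,
               bin_width: float = 1.0, n_bootstrap: int = 0,
               rng: np.random.Generator | None = None) -> FreeEnergyProfile:
    """Assemble the ground-surface free energy along the gap coordinate."""
    if not windows or windows[0].e_ground.size == 0:
        raise ProfileError("windows carry no ground-surface samples")
    fep = fep_delta_g(windows, temperature)
    profile = _assemble(windows, fep.cumulative, temperature, bin_width)
    barrier_se = dg_se = float("nan")
    if n_bootstrap > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        bs_barrier, bs_dg = [], []
        for _ in range(n_bootstrap):
            resampled = _resample_windows(windows, rng)
            fep_b = fep_delta_g(resampled, temperature)
            try:
                p = _assemble(resampled, fep_b.cumulative, temperature, bin_width)
            except ProfileError:
                continue
            bs_barrier.append(p.barrier)
            bs_dg.append(p.dg_rxn)
        if len(bs_barrier) >= 2:
            barrier_se = float(np.std(bs_barrier, ddof=1))
            dg_se = float(np.std(bs_dg, ddof=1))
    profile.barrier_se = barrier_se
    profile.dg_rxn_se = dg_se
    profile.metadata.update({
        "temperature": temperature, "bin_width": bin_width,
        "fep_forward": fep.forward, "fep_reverse": fep.reverse,
        "fep_hysteresis": fep.hysteresis, "overlap_warnings": fep.warnings,
    })
    return profile


def _resample_windows(windows, rng):
    out = []
    for w in windows:
        n = len(w.gap)
        # block bootstrap (block ~ n/10) to respect autocorrelation
        block = max(1, n // 10)
        starts = rng.integers(0, max(1, n - block + 1), size=(n + block - 1) // block)
        idx = np.concatenate([np.arange(s, s + block) for s in starts])[:n]
        out.append(WindowSample(index=w.index, lam=w.lam, eps=w.eps[idx],
                                e_ground=w.e_ground[idx], gap=w.gap[idx]))
    return out


def _assemble(windows, cumulative, temperature, bin_width) -> FreeEnergyProfile:
    beta = 1.0 / (KB * temperature)
    all_gap = np.concatenate([w.gap for w in windows])
    lo, hi = all_gap.min(), all_gap.max()
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nbins = len(centers)
    # Each bin takes its value from the window that samples it best (most
    # frames in the bin). Averaging across windows instead lets rare
    # excursions from distant windows — whose exp(−β(E_g−ε_λ)) reweighting
    # factors are enormous — poison individual bins.
    best_cnt = np.zeros(nbins)
    dg_val = np.full(nbins, np.nan)
    cnt = np.zeros(nbins)
    for w, g_m in zip(windows, cumulative):
        em = _mapping_series(w, w.lam)
        wts = np.exp(-beta * np.clip(w.e_ground - em, -200 / beta, 200 / beta))
        which = np.digitize(w.gap, edges) - 1
        n_frames = len(w.gap)
        for b in np.unique(which):
            mask = which == b
            nb = int(mask.sum())
            cnt[b] += nb
            if nb > best_cnt[b]:
                best_cnt[b] = nb
                mean_w = wts[mask].mean()
                dg_val[b] = g_m - np.log(max(mean_w * nb / n_frames, 1e-300)) / beta
    # and drop bins whose best window still has only a handful of frames
    min_count = max(10.0, 2e-4 * float(cnt.sum()))
    filled = best_cnt >= min_count
    dg = dg_val
    centers = centers[filled]
    dg = dg[filled]
    counts = cnt[filled]
    react = centers < 0.0
    prod = centers > 0.0
    if not react.any() or not prod.any():
        raise ProfileError("profile does not resolve both basins "
                           "(single-basin gap range; add windows or length)")
    i_r = np.flatnonzero(react)[np.argmin(dg[react])]
    i_p = np.flatnonzero(prod)[np.argmin(dg[prod])]
    between = slice(min(i_r, i_p), max(i_r, i_p) + 1)
    i_ts = np.argmax(dg[between]) + between.start
    ref = dg[i_r]
    dg = dg - ref
    if np.isnan(dg[between]).any() or counts[between].min() == 0:
        raise ProfileError("empty bins span the barrier region; add windows")
    return FreeEnergyProfile(bin_centers=centers, dg=dg, counts=counts,
                             barrier=float(dg[i_ts]), dg_rxn=float(dg[i_p]))


def extract_barrier(profile: FreeEnergyProfile) -> tuple[float, float]:
    """(ΔG‡, ΔG_rxn) from a resolved two-basin profile."""
    if not np.isfinite(profile.barrier):
        raise ProfileError("profile has no resolved barrier")
    return profile.barrier, profile.dg_rxn
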
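"""Reaction coordinates, reweighting and folding-cooperativity measures.

The fraction of native contacts Q (optionally strength-weighted, Q*)
scores each contact with a smooth switching function of its distance and
rescales so the native structure maps to 1 and the fully broken chain to
0.  Multi-temperature runs are combined by WHAM (self-consistent
multi-histogram reweighting) into free-energy profiles along Q, heat
capacity curves Cv(T), the folding temperature T_f (the Cv peak), the
van't Hoff / calorimetric enthalpy ratio, and the "foldedness" of a
mutant relative to the wild type.  Statistical errors come from a
delete-one-block jackknife over contiguous trajectory blocks; error bars
downstream are twice the square root of the variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from cago.structure_io import Contact, ContactMap

Q_SWITCH_R0_FACTOR = 1.2   # switching midpoint at 1.2 sigma
FOLDED_Q = 0.7             # basin thresholds (basins sit near Q~0.8 / Q~0.2)
UNFOLDED_Q = 0.3
DEFAULT_BINS = 50
DEFAULT_BLOCKS = 10

__all__ = [
    "QSeries", "FreeEnergyProfile", "FES2D", "HeatCapacityCurve",
    "CooperativityReport", "FoldednessResult",
    "compute_q", "com_distance", "wham_reweight", "heat_capacity",
    "cooperativity_ratio", "foldedness", "detect_transitions",
    "jackknife_variance", "frame_table_tsv",
]


@dataclass(frozen=True)
class QSeries:
    values: np.ndarray
    subset: str = "all"
    strength_scaled: bool = False

    def __post_init__(self):
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)
        if np.any(v < -1e-9) or np.any(v > 1.0 + 1e-9):
            raise ValueError("Q values must lie in [0, 1]")


@dataclass(frozen=True)
class FreeEnergyProfile:
    """dG(RC) in units of k_B T_ref, zeroed at its lowest populated bin."""

    rc_grid: np.ndarray
    dG: np.ndarray
    variance: np.ndarray
    rc_name: str = "Q"
    T_ref: float = 1.0

    def interp(self, rc: float) -> float:
        """Linear interpolation of dG over populated bins."""
        ok = np.isfinite(self.dG)
        if not ok.any():
            raise ValueError("profile has no populated bins")
        lo, hi = self.rc_grid[ok].min(), self.rc_grid[ok].max()
        if not (lo - 1e-9 <= rc <= hi + 1e-9):
            raise ValueError(
                f"RC value {rc:g} outside populated range [{lo:g}, {hi:g}]"
            )
        return float(np.interp(rc, self.rc_grid[ok], self.dG[ok]))

    def to_tsv(self) -> str:
        """TSV grid: rc, dG (k_B T_ref), error (2 sqrt variance)."""
        lines = [f"# {self.rc_name}\tdG_kT\terr2sd\t(T_ref={self.T_ref:g})"]
        for rc, dg, var in zip(self.rc_grid, self.dG, self.variance):
            err = 2.0 * np.sqrt(var) if np.isfinite(var) else np.nan
            lines.append(f"{rc:.6g}\t{dg:.6g}\t{err:.6g}")
        return "\n".join(lines) + "\n"

    def variance_at(self, rc: float) -> float:
        ok = np.isfinite(self.dG) & np.isfinite(self.variance)
        if not ok.any():
            return float("nan")
        k = int(np.argmin(np.abs(self.rc_grid[ok] - rc)))
        return float(self.variance[ok][k])


@dataclass(frozen=True)
class FES2D:
    x_grid: np.ndarray
    y_grid: np.ndarray
    dG: np.ndarray           # (ny, nx), k_B T units, NaN where unpopulated
    rc_names: tuple[str, str] = ("Q_x", "Q_y")
    T_ref: float = 1.0


@dataclass(frozen=True)
class HeatCapacityCurve:
    T_grid: np.ndarray
    cv: np.ndarray
    T_f: float
    has_peak: bool


@dataclass(frozen=True)
class CooperativityReport:
    dH_vH: float
    dH_cal: float
    ratio: float
    variance: float = float("nan")


@dataclass(frozen=True)
class FoldednessResult:
    value: float
    uncertainty: float
    q_ref: float


# ---------------------------------------------------------------------------
# reaction coordinates


def _contact_list(contacts) -> list[Contact]:
    if isinstance(contacts, ContactMap):
        cs = list(contacts.contacts)
    else:
        cs = list(contacts)
    if not cs:
        raise ValueError("contact subset must be non-empty")
    return cs


def _switch(r: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Rational switching score per contact distance.

    s = [1 - (r/r0)^6] / [1 - (r/r0)^12] = 1 / (1 + (r/r0)^6) with
    r0 = 1.2 sigma, clamped to 1 for r <= sigma so the native structure
    scores exactly 1.
    """
    x6 = (r / (Q_SWITCH_R0_FACTOR * sigma)) ** 6
    s = 1.0 / (1.0 + x6)
    return np.where(r <= sigma * (1.0 + 1e-9), 1.0, s)


def compute_q(coords, contacts, strength_scaled: bool = False,
              subset: str = "all") -> QSeries:
    """Fraction of native contacts formed (Q, or strength-weighted Q*).

    ``coords`` may be one configuration (n, 3), a frame stack (F, n, 3)
    or a Trajectory.  Weights are 1 for Q and the contact strengths
    epsilon for Q*; the rescaled value is sum(w s) / sum(w) in [0, 1],
    equal to 1 at the native structure and 0 in the all-broken limit.
    """
    from cago.dynamics import Trajectory

    if isinstance(coords, Trajectory):
        coords = coords.frames
    x = np.asarray(coords, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    cs = _contact_list(contacts)
    idx_i = np.array([c.i - 1 for c in cs])
    idx_j = np.array([c.j - 1 for c in cs])
    sigma = np.array([c.sigma for c in cs])
    w = np.array([c.epsilon for c in cs]) if strength_scaled else np.ones(len(cs))
    r = np.linalg.norm(x[:, idx_i, :] - x[:, idx_j, :], axis=2)
    q = (_switch(r, sigma[None, :]) * w[None, :]).sum(axis=1) / w.sum()
    return QSeries(q[0] if single else q, subset=subset,
                   strength_scaled=strength_scaled)


def com_distance(coords: np.ndarray, group_a, group_b) -> float | np.ndarray:
    """Distance between the centroids of two disjoint residue groups
    (uniform masses; residues 1-based)."""
    ga = sorted(set(int(r) for r in group_a))
    gb = sorted(set(int(r) for r in group_b))
    if not ga or not gb:
        raise ValueError("groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    x = np.asarray(coords, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    ia = np.array(ga) - 1
    ib = np.array(gb) - 1
    d = np.linalg.norm(x[:, ia, :].mean(axis=1) - x[:, ib, :].mean(axis=1), axis=1)
    return float(d[0]) if single else d


# ---------------------------------------------------------------------------
# WHAM


def _normalize_runs(runs):
    """runs: list of (T, energies, rc) with rc a 1-D series or a pair of
    series for 2-D surfaces."""
    out = []
    for T, E, rc in runs:
        E = np.asarray(E, dtype=float)
        if isinstance(rc, tuple):
            rc = tuple(np.asarray(r, dtype=float) for r in rc)
            for r in rc:
                if len(r) != len(E):
                    raise ValueError("energy and RC series lengths differ")
        else:
            rc = np.asarray(rc, dtype=float)
            if len(rc) != len(E):
                raise ValueError("energy and RC series lengths differ")
        out.append((float(T), E, rc))
    return out


def _wham_log_denominator(temps, energies, tol=1e-12, max_iter=10_000):
    """Self-consistent WHAM denominator log Σ_k N_k exp(f_k − β_k E_n).

    Depends only on the runs, not on a target temperature, so it can be
    solved once and reused for reweighting to many temperatures.
    """
    betas = 1.0 / np.asarray(temps, dtype=float)
    E = np.concatenate(energies)
    N = np.array([len(e) for e in energies], dtype=float)
    logN = np.log(N)
    f = np.zeros(len(temps))
    if len(temps) > 1:
        mBE = -betas[:, None] * E[None, :]          # (K, M)
        for _ in range(max_iter):
            log_denom = logsumexp(logN[:, None] + f[:, None] + mBE, axis=0)
            f_new = -logsumexp(mBE - log_denom[None, :], axis=1)
            f_new -= f_new[0]
            if np.max(np.abs(f_new - f)) < tol:
                f = f_new
                break
            f = f_new
        log_denom = logsumexp(logN[:, None] + f[:, None] + mBE, axis=0)
    else:
        log_denom = logN[0] + f[0] - betas[0] * E
    return E, log_denom


def _wham_log_weights(temps, energies, target_T, tol=1e-12, max_iter=10_000):
    """Binless WHAM: per-sample log-weights at the target temperature
    (unnormalized)."""
    E, log_denom = _wham_log_denominator(temps, energies, tol, max_iter)
    return -E / target_T - log_denom


def _profile_from_weights(rc, logw, bins, rc_range):
    hist = np.zeros(bins)
    edges = np.linspace(rc_range[0], rc_range[1], bins + 1)
    w = np.exp(logw - logw.max())
    idx = np.clip(np.digitize(rc, edges) - 1, 0, bins - 1)
    np.add.at(hist, idx, w)
    with np.errstate(divide="ignore"):
        dG = -np.log(hist)
    dG[hist == 0] = np.nan
    dG -= np.nanmin(dG)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dG


def _check_overlap(temps, energies):
    """Warn (in-band, via returned string) when consecutive-temperature
    energy distributions do not overlap."""
    order = np.argsort(temps)
    msgs = []
    for a, b in zip(order, order[1:]):
        lo = max(energies[a].min(), energies[b].min())
        hi = min(energies[a].max(), energies[b].max())
        if hi < lo:
            msgs.append(
                f"energy ranges at T={temps[a]:g} and T={temps[b]:g} do not overlap"
            )
    return msgs


def wham_reweight(runs, target_T: float, n_bins: int = DEFAULT_BINS,
                  rc_range=(0.0, 1.0), rc_name: str = "Q",
                  n_jackknife: int = DEFAULT_BLOCKS):
    """Free-energy profile (or 2-D surface) at ``target_T`` from one or
    more constant-temperature runs.

    ``runs`` is a list of ``(T, energy_series, rc_series)``; a 2-tuple of
    RC series yields a FES2D.  A single run reweighted to its own
    temperature reduces exactly to -ln(histogram).  Jackknife variance
    uses ``n_jackknife`` contiguous blocks per run (1-D only).
    """
    runs = _normalize_runs(runs)
    temps = [r[0] for r in runs]
    energies = [r[1] for r in runs]
    for msg in _check_overlap(temps, energies):
        import warnings

        warnings.warn(msg, stacklevel=2)
    logw = _wham_log_weights(temps, energies, target_T)

    two_d = isinstance(runs[0][2], tuple)
    if two_d:
        rcx = np.concatenate([r[2][0] for r in runs])
        rcy = np.concatenate([r[2][1] for r in runs])
        edges_x = np.linspace(rc_range[0], rc_range[1], n_bins + 1)
        edges_y = np.linspace(rc_range[0], rc_range[1], n_bins + 1)
        w = np.exp(logw - logw.max())
        hist, _, _ = np.histogram2d(rcy, rcx, bins=[edges_y, edges_x], weights=w)
        with np.errstate(divide="ignore"):
            dG = -np.log(hist)
        dG[hist == 0] = np.nan
        dG -= np.nanmin(dG)
        cx = 0.5 * (edges_x[:-1] + edges_x[1:])
        cy = 0.5 * (edges_y[:-1] + edges_y[1:])
        names = (rc_name + "_x", rc_name + "_y") if isinstance(rc_name, str) else rc_name
        return FES2D(cx, cy, dG, names, target_T)

    rc = np.concatenate([r[2] for r in runs])
    centers, dG = _profile_from_weights(rc, logw, n_bins, rc_range)

    variance = np.full(n_bins, np.nan)
    if n_jackknife >= 2 and all(len(e) >= n_jackknife for e in energies):
        reps = []
        for b in range(n_jackknife):
            sub = []
            for T, E, r in runs:
                keep = np.ones(len(E), dtype=bool)
                edges = np.linspace(0, len(E), n_jackknife + 1).astype(int)
                keep[edges[b]:edges[b + 1]] = False
                sub.append((T, E[keep], r[keep]))
            lw = _wham_log_weights([s[0] for s in sub], [s[1] for s in sub], target_T)
            _, dg_b = _profile_from_weights(
                np.concatenate([s[2] for s in sub]), lw, n_bins, rc_range
            )
            reps.append(dg_b)
        reps = np.array(reps)
        ok = np.isfinite(reps).all(axis=0) & np.isfinite(dG)
        if ok.any():
            m = reps[:, ok].mean(axis=0)
            variance[ok] = ((n_jackknife - 1) / n_jackknife) * np.sum(
                (reps[:, ok] - m[None, :]) ** 2, axis=0
            )
    return FreeEnergyProfile(centers, dG, variance, rc_name, target_T)


# ---------------------------------------------------------------------------
# heat capacity, cooperativity, foldedness


def heat_capacity(runs, T_grid: np.ndarray | None = None,
                  grid_points: int = 200, pad: float = 0.10) -> HeatCapacityCurve:
    """Cv(T) = (<E^2>_T - <E>_T^2) / T^2 from WHAM-reweighted expectations.

    The default T grid spans the simulated temperatures padded by
    ``pad`` on each side.  ``has_peak`` is False when the maximum sits at
    a grid edge or the curve shows no prominent peak (e.g. a purely
    harmonic system).
    """
    runs = _normalize_runs(runs)
    temps = [r[0] for r in runs]
    energies = [r[1] for r in runs]
    if T_grid is None:
        lo, hi = min(temps) * (1 - pad), max(temps) * (1 + pad)
        T_grid = np.linspace(lo, hi, grid_points)
    T_grid = np.asarray(T_grid, dtype=float)
    E, log_denom = _wham_log_denominator(temps, energies)
    cv = np.empty_like(T_grid)
    for k, T in enumerate(T_grid):
        lw = -E / T - log_denom
        lw -= logsumexp(lw)
        w = np.exp(lw)
        e1 = float(np.sum(w * E))
        e2 = float(np.sum(w * E * E))
        cv[k] = max(e2 - e1 * e1, 0.0) / (T * T)
    imax = int(np.argmax(cv))
    interior = 0 < imax < len(T_grid) - 1
    edge = max(cv[0], cv[-1])
    prominent = cv[imax] > edge * 1.05 + 1e-12
    return HeatCapacityCurve(T_grid, cv, float(T_grid[imax]),
                             bool(interior and prominent))


def cooperativity_ratio(curve: HeatCapacityCurve,
                        window: str = "full") -> CooperativityReport:
    """Van't Hoff to calorimetric enthalpy ratio from a Cv curve.

    dH_vH = 2 T_f sqrt(Cv(T_f)); dH_cal integrates Cv over the window
    after subtracting a linear baseline through the window endpoints.
    ``window`` is "full" (whole T grid; robust when the transition splits
    into several peaks) or "flanking" (between the Cv minima flanking the
    peak).  A ratio of 1 indicates two-state cooperative folding.
    """
    if not curve.has_peak:
        raise ValueError("heat-capacity curve has no detected peak")
    T, cv = curve.T_grid, curve.cv
    imax = int(np.argmax(cv))
    if window == "flanking":
        left = int(np.argmin(cv[: imax + 1]))
        right = imax + int(np.argmin(cv[imax:]))
    elif window == "full":
        left, right = 0, len(T) - 1
    else:
        raise ValueError("window must be 'full' or 'flanking'")
    Tw, cw = T[left : right + 1], cv[left : right + 1]
    baseline = np.interp(Tw, [Tw[0], Tw[-1]], [cw[0], cw[-1]])
    excess = np.clip(cw - baseline, 0.0, None)
    # the non-transition (background) heat capacity is subtracted from
    # both enthalpies; noise excursions below the baseline carry no
    # transition enthalpy and are clipped
    dH_vH = 2.0 * curve.T_f * float(np.sqrt(excess.max()))
    dH_cal = float(np.trapezoid(excess, Tw))
    if dH_cal <= 0:
        raise ValueError("non-positive calorimetric enthalpy in window")
    return CooperativityReport(dH_vH, dH_cal, dH_vH / dH_cal)


def _folded_basin_min(fep: FreeEnergyProfile) -> float:
    """dG at the folded-basin minimum: the lowest populated bin beyond the
    main barrier (or beyond RC 0.5 for barrierless profiles)."""
    ok = np.isfinite(fep.dG)
    rc, dg = fep.rc_grid[ok], fep.dG[ok]
    interior = (rc > UNFOLDED_Q) & (rc < rc.max())
    if interior.any():
        barrier_rc = rc[interior][np.argmax(dg[interior])]
    else:
        barrier_rc = 0.5
    beyond = rc >= barrier_rc
    if not beyond.any():
        beyond = rc >= 0.5
    return float(dg[beyond].min()), float(rc[beyond][np.argmin(dg[beyond])])


def foldedness(fep_mut: FreeEnergyProfile, fep_wt: FreeEnergyProfile,
               q_ref: float | None = None) -> FoldednessResult:
    """Population of the mutant, relative to wild type, at the RC value
    where the wild type is folded.

    Both profiles are zeroed at their own folded-basin minima; with
    dG_wt(q_ref) = 0 by construction the value is exp(-dG_mut(q_ref)).
    Requires q_ref inside the mutant's populated range (the definition
    assumes the mutant folds at RC <= the wild type's).
    """
    wt_min, wt_mode = _folded_basin_min(fep_wt)
    if q_ref is None:
        q_ref = wt_mode
    mut_min, _ = _folded_basin_min(fep_mut)
    dg_mut = fep_mut.interp(q_ref) - mut_min
    dg_wt = fep_wt.interp(q_ref) - wt_min
    value = float(np.exp(-(dg_mut - dg_wt)))
    var = fep_mut.variance_at(q_ref)
    var_wt = fep_wt.variance_at(q_ref)
    sd = 0.0
    for v in (var, var_wt):
        if np.isfinite(v):
            sd += v
    return FoldednessResult(value, value * float(np.sqrt(sd)), float(q_ref))


# ---------------------------------------------------------------------------
# transitions and jackknife


def frame_table_tsv(traj, q_columns: dict[str, QSeries],
                    com_columns: dict[str, np.ndarray] | None = None) -> str:
    """Plain-text per-frame analysis table: step, E, Q columns, distances."""
    com_columns = com_columns or {}
    names = list(q_columns) + list(com_columns)
    lines = ["# step\tE\t" + "\t".join(names)]
    cols = [q.values for q in q_columns.values()] + list(com_columns.values())
    for k, (step, e) in enumerate(zip(traj.step_indices, traj.potential_energy)):
        vals = "\t".join(f"{c[k]:.6g}" for c in cols)
        lines.append(f"{int(step)}\t{e:.6g}\t{vals}")
    return "\n".join(lines) + "\n"


def detect_transitions(q: QSeries, folded_threshold: float = FOLDED_Q,
                       unfolded_threshold: float = UNFOLDED_Q):
    """Maximal folding/unfolding transition segments of a Q time series.

    Each segment runs from the last exit out of one basin to the first
    entry into the other, labelled "folding" or "unfolding".  Returns a
    list of (start_frame, end_frame, direction) with inclusive indices.
    """
    if not (0 <= unfolded_threshold < folded_threshold <= 1):
        raise ValueError("need 0 <= unfolded_threshold < folded_threshold <= 1")
    v = q.values
    segments = []
    state = 0  # 0 unknown, +1 folded, -1 unfolded
    last_in_basin = 0
    for t, qt in enumerate(v):
        here = 1 if qt >= folded_threshold else (-1 if qt <= unfolded_threshold else 0)
        if here == 0:
            continue
        if state == 0:
            state = here
        elif here == state:
            pass
        else:
            segments.append(
                (last_in_basin, t, "folding" if here == 1 else "unfolding")
            )
            state = here
        last_in_basin = t
    return segments


def jackknife_variance(values, n_blocks: int = DEFAULT_BLOCKS,
                       statistic=np.mean) -> float:
    """Delete-one-block jackknife variance of ``statistic`` over a
    per-frame stream split into contiguous blocks."""
    v = np.asarray(values, dtype=float)
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if len(v) < n_blocks:
        raise ValueError(f"stream of {len(v)} frames is shorter than {n_blocks} blocks")
    edges = np.linspace(0, len(v), n_blocks + 1).astype(int)
    reps = []
    for b in range(n_blocks):
        keep = np.ones(len(v), dtype=bool)
        keep[edges[b]:edges[b + 1]] = False
        reps.append(statistic(v[keep]))
    reps = np.asarray(reps, dtype=float)
    return float((n_blocks - 1) / n_blocks * np.sum((reps - reps.mean()) ** 2))
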
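"""Free-energy profiles from biased trajectories, with uncertainties and audits.

This module turns reweighted histograms of a biased collective-variable (CV)
series into one-dimensional free-energy profiles, extracts state-to-state
free-energy differences (RS -> TS1 / INT / TS2 / PS), and performs the
transition-state degeneracy audit: a check that the CV maps transition-state
configurations to a unique region, so that barrier heights read off the 1-D
profile are kinetically meaningful.

Reweighting uses the standard identity for an adaptive bias V with running
offset c(t): each frame carries weight w = exp((V(s_t) - c(t)) / kT), which
restores unbiased ensemble averages once the bias is quasi-static.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ArgumentError, DataError, ExtractionError

__all__ = [
    "FESProfile",
    "StateEnergies",
    "RationalVariable",
    "AuditReport",
    "detect_burn_in",
    "reweighted_fes",
    "extract_state_energies",
    "delta_delta_g",
    "degeneracy_audit",
]

#: labels of the Table-1-style free-energy entries, relative to the reactant state
STATE_TRANSITIONS = ("RS→TS1", "RS→INT", "RS→TS2", "RS→PS")

#: window labels treated as barriers (maxima); all others are basins (minima)
BARRIER_LABELS = frozenset({"TS1", "TS2"})


@dataclass
class FESProfile:
    """A gridded free-energy estimate, min-shifted to zero.

    Attributes
    ----------
    grid : bin centers along the CV, strictly increasing
    free_energy : free energy per bin (energy units); NaN where no replicate
        had occupancy (flagged unset, never silently zero)
    sem : per-bin standard error of the mean across replicates
    n_replicates : number of independent replicates averaged
    """

    grid: np.ndarray
    free_energy: np.ndarray
    sem: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ArgumentError("grid must be 1-D and strictly increasing")
        if self.grid.shape != self.free_energy.shape or self.grid.shape != self.sem.shape:
            raise ArgumentError("grid, free_energy and sem must share a shape")
        finite = np.isfinite(self.free_energy)
        if finite.any():
            # enforce the min-shift convention exactly
            self.free_energy = self.free_energy - np.nanmin(self.free_energy[finite])

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of bins with a defined estimate."""
        return np.isfinite(self.free_energy)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"cv": self.grid, "free_energy": self.free_energy, "sem": self.sem}
        )


@dataclass
class StateEnergies:
    """RS-anchored free-energy table: label -> (delta_g, sem)."""

    entries: dict

    def __post_init__(self) -> None:
        for label, (dg, sem) in self.entries.items():
            if label not in STATE_TRANSITIONS:
                raise ArgumentError(f"unknown transition label {label!r}")
            if not np.isfinite(dg):
                raise ArgumentError(f"non-finite free energy for {label!r}")
            if sem < 0:
                raise ArgumentError("sem must be >= 0")

    def __getitem__(self, label: str):
        return self.entries[label]


@dataclass
class RationalVariable:
    """A physically interpretable per-frame observable (e.g. a bond distance).

    ``ts_window`` is the value range this variable is expected to occupy at
    the transition state; the degeneracy audit checks the reweighted 2-D
    free-energy surface against it.
    """

    name: str
    values: np.ndarray
    ts_window: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.ts_window
        if not lo < hi:
            raise ArgumentError("ts_window must be an increasing interval")


@dataclass
class AuditReport:
    """Outcome of the TS-degeneracy audit.

    status is one of "pass", "fail", "inconclusive" (the TS window of the CV
    was never visited, so nothing can be concluded).
    """

    status: str
    fes2d: np.ndarray
    cv_edges: np.ndarray
    rational_edges: np.ndarray
    ts_free_energy: float
    undercut: float
    details: str = ""

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def detect_burn_in(
    rct_series: Sequence[float],
    fraction_cap: float = 0.25,
    slope_tol: float = 0.05,
    window: int | None = None,
) -> int:
    """First retained index of a bias run, from stabilization of c(t).

    The normalization offset c(t) of an adaptive bias rises while the bias is
    still being built and flattens once it stabilizes; frames before that
    point are discarded. The rule: compute forward-difference slopes over a
    trailing window and return the first index where |slope| falls below
    ``slope_tol`` times the maximum observed |slope|. The result is capped at
    ``fraction_cap`` of the series length; a series that never stabilizes
    returns the cap with a warning.

    A constant series returns 0 (nothing to discard).
    """
    r = np.asarray(rct_series, dtype=float)
    n = r.size
    if n < 10:
        raise DataError("rct series must have at least 10 entries")
    if not 0 < fraction_cap <= 1:
        raise ArgumentError("fraction_cap must be in (0, 1]")
    w = window if window is not None else max(2, n // 20)
    idx = np.arange(n - w)
    slopes = np.abs(r[idx + w] - r[idx]) / w
    smax = slopes.max()
    if smax == 0.0:
        return 0
    stable = np.nonzero(slopes <= slope_tol * smax)[0]
    cap = int(round(fraction_cap * n))
    if stable.size == 0:
        warnings.warn("rct series never stabilized; burn-in capped", RuntimeWarning)
        return cap
    return min(int(stable[0]), cap)


def _single_replicate_fes(
    s: np.ndarray,
    bias: np.ndarray,
    rct: np.ndarray,
    edges: np.ndarray,
    kT: float,
) -> np.ndarray:
    """Weighted histogram -> -kT log -> min shift; NaN for empty bins."""
    logw = (bias - rct) / kT
    logw -= logw.max()  # guard overflow; constant factors cancel after min-shift
    w = np.exp(logw)
    hist, _ = np.histogram(s, bins=edges, weights=w)
    f = np.full(hist.shape, np.nan)
    occ = hist > 0
    f[occ] = -kT * np.log(hist[occ])
    if occ.any():
        f -= np.nanmin(f)
    return f


def reweighted_fes(
    replicas: Sequence[tuple],
    grid: np.ndarray,
    kT: float = 1.0,
) -> FESProfile:
    """Build a free-energy profile with replicate SEM from biased runs.

    Parameters
    ----------
    replicas : sequence of (cv_series, bias_series, rct_series) triples, one
        per independent replicate, burn-in already removed. ``rct_series`` is
        the per-frame value of the reweighting offset c(t); pass zeros for an
        unbiased run together with zero bias.
    grid : bin centers (uniform spacing assumed for edge construction)
    kT : thermal energy in the same units as the bias

    Each replicate is histogrammed with weights exp((V - c)/kT), converted to
    -kT log and min-shifted; the profile is the per-bin mean across
    replicates with the standard error of that mean. Bins unoccupied in every
    replicate are flagged NaN rather than set to zero.
    """
    grid = np.asarray(grid, dtype=float)
    if len(replicas) == 0:
        raise DataError("at least one replicate required")
    dx = np.diff(grid)
    if grid.ndim != 1 or np.any(dx <= 0):
        raise ArgumentError("grid must be 1-D and strictly increasing")
    edges = np.concatenate(
        ([grid[0] - dx[0] / 2], grid[:-1] + dx / 2, [grid[-1] + dx[-1] / 2])
    )
    profiles = []
    for s, bias, rct in replicas:
        s = np.asarray(s, dtype=float).ravel()
        bias = np.asarray(bias, dtype=float).ravel()
        rct = np.asarray(rct, dtype=float).ravel()
        if not (s.size == bias.size == rct.size):
            raise ArgumentError("cv, bias and rct series must have equal length")
        profiles.append(_single_replicate_fes(s, bias, rct, edges, kT))
    stack = np.vstack(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(stack, axis=0)
        if stack.shape[0] >= 2:
            counts = np.sum(np.isfinite(stack), axis=0)
            std = np.nanstd(stack, axis=0, ddof=1)
            sem = np.where(counts >= 2, std / np.sqrt(np.maximum(counts, 1)), 0.0)
        else:
            sem = np.zeros_like(mean)
    sem = np.where(np.isfinite(mean), np.nan_to_num(sem), 0.0)
    return FESProfile(grid=grid, free_energy=mean, sem=sem, n_replicates=len(replicas))


def _window_slice(grid: np.ndarray, window: tuple) -> np.ndarray:
    lo, hi = window
    if not lo < hi:
        raise ArgumentError("window must be an increasing interval")
    if lo < grid[0] - 1e-12 or hi > grid[-1] + 1e-12:
        raise ArgumentError("window extends beyond the profile grid")
    return np.nonzero((grid >= lo) & (grid <= hi))[0]


def _interior_extremum(values: np.ndarray, kind: str, label: str) -> int:
    """Index of the interior min/max of a window; error when there is none."""
    finite = np.isfinite(values)
    if finite.sum() < 3:
        raise ExtractionError(f"window for {label!r} has too few occupied bins")
    v = np.where(finite, values, np.inf if kind == "min" else -np.inf)
    i = int(np.argmin(v)) if kind == "min" else int(np.argmax(v))
    if i in (0, len(values) - 1):
        raise ExtractionError(f"no interior extremum in window for {label!r}")
    edge = np.concatenate((values[:1], values[-1:]))
    edge = edge[np.isfinite(edge)]
    if edge.size and kind == "min" and not values[i] < edge.min() - 1e-12:
        raise ExtractionError(f"no interior minimum in window for {label!r}")
    if edge.size and kind == "max" and not values[i] > edge.max() + 1e-12:
        raise ExtractionError(f"no interior maximum in window for {label!r}")
    return i


def extract_state_energies(
    profile: FESProfile, state_windows: Mapping[str, tuple]
) -> StateEnergies:
    """Table-1-style RS-anchored free-energy differences from a 1-D profile.

    ``state_windows`` maps labels RS, TS1, INT, TS2, PS to CV intervals. The
    reactant-state (RS) window must be present. Basins contribute their
    interior minimum, barriers (TS1/TS2) their interior maximum; every value
    is reported relative to the RS minimum with the SEM propagated as the
    root-sum-square of the two bins' SEMs.
    """
    if "RS" not in state_windows:
        raise ArgumentError("an RS window is required as the anchor")
    located: dict[str, tuple[float, float]] = {}
    for label, window in state_windows.items():
        sl = _window_slice(profile.grid, window)
        vals = profile.free_energy[sl]
        kind = "max" if label in BARRIER_LABELS else "min"
        i = _interior_extremum(vals, kind, label)
        located[label] = (float(vals[i]), float(profile.sem[sl][i]))
    g_rs, sem_rs = located["RS"]
    entries = {}
    for label, (g, sem) in located.items():
        if label == "RS":
            continue
        entries[f"RS→{label}"] = (g - g_rs, float(np.hypot(sem, sem_rs)))
    return StateEnergies(entries=entries)


def delta_delta_g(perturbed: StateEnergies, reference: StateEnergies) -> dict:
    """Per-transition free-energy shift with pooled SEM.

    Returns label -> (ddg, pooled_sem) where ddg = dG_perturbed - dG_reference
    and the pooled SEM is the root-sum-square of the two runs' SEMs. Swapping
    the arguments negates every ddg exactly.
    """
    out = {}
    common = set(perturbed.entries) & set(reference.entries)
    for label in sorted(common):
        ga, sa = perturbed[label]
        gb, sb = reference[label]
        out[label] = (ga - gb, float(np.hypot(sa, sb)))
    return out


def degeneracy_audit(
    cv_series: np.ndarray,
    rational: RationalVariable,
    bias: np.ndarray,
    rct: np.ndarray,
    ts_cv_window: tuple,
    kT: float = 1.0,
    n_cv_bins: int = 60,
    n_rational_bins: int = 60,
    tolerance: float = 0.5,
) -> AuditReport:
    """Reweighted 2-D audit of transition-state nondegeneracy.

    Builds the reweighted free-energy surface over (CV, rational variable).
    Within the transition-state CV window, the audit passes when (a) the
    minimum-free-energy rational value lies inside the variable's expected
    ``ts_window``, and (b) no bin outside that window undercuts the in-window
    TS free energy by more than ``tolerance`` (energy units). A degenerate CV
    — one that maps a distinct, more stable configuration onto the TS region
    — fails (b). If the TS CV window was never visited the audit is
    "inconclusive", which is distinct from a failure.
    """
    s = np.asarray(cv_series, dtype=float).ravel()
    r = rational.values.ravel()
    bias = np.asarray(bias, dtype=float).ravel()
    rct = np.asarray(rct, dtype=float).ravel()
    if not (s.size == r.size == bias.size == rct.size):
        raise ArgumentError("cv, rational, bias and rct series must align")
    logw = (bias - rct) / kT
    logw -= logw.max()
    w = np.exp(logw)
    cv_edges = np.linspace(s.min(), s.max(), n_cv_bins + 1)
    r_edges = np.linspace(r.min(), r.max(), n_rational_bins + 1)
    hist, cv_edges, r_edges = np.histogram2d(s, r, bins=(cv_edges, r_edges), weights=w)
    fes2d = np.full(hist.shape, np.nan)
    occ = hist > 0
    fes2d[occ] = -kT * np.log(hist[occ])
    fes2d -= np.nanmin(fes2d)

    lo, hi = ts_cv_window
    cv_centers = 0.5 * (cv_edges[:-1] + cv_edges[1:])
    r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    in_ts = (cv_centers >= lo) & (cv_centers <= hi)
    block = fes2d[in_ts, :]
    if not in_ts.any() or not np.isfinite(block).any():
        return AuditReport(
            status="inconclusive",
            fes2d=fes2d,
            cv_edges=cv_edges,
            rational_edges=r_edges,
            ts_free_energy=np.nan,
            undercut=np.nan,
            details="TS CV window has no reweighted occupancy",
        )
    # free energy per rational bin, minimized over the TS CV slab
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f_of_r = np.nanmin(block, axis=0)
    rlo, rhi = rational.ts_window
    inside = (r_centers >= rlo) & (r_centers <= rhi)
    f_in = np.nanmin(f_of_r[inside]) if np.isfinite(f_of_r[inside]).any() else np.nan
    f_out = np.nanmin(f_of_r[~inside]) if np.isfinite(f_of_r[~inside]).any() else np.inf
    if not np.isfinite(f_in):
        return AuditReport(
            status="inconclusive",
            fes2d=fes2d,
            cv_edges=cv_edges,
            rational_edges=r_edges,
            ts_free_energy=np.nan,
            undercut=np.nan,
            details="expected TS window of the rational variable unoccupied",
        )
    undercut = float(f_in - f_out)  # positive when an outside bin is deeper
    argmin_inside = bool(inside[int(np.nanargmin(np.where(np.isfinite(f_of_r), f_of_r, np.inf)))])
    ok = argmin_inside and undercut <= tolerance
    details = (
        f"TS free energy inside expected window: {f_in:.3f}; deepest outside: "
        f"{f_out if np.isfinite(f_out) else float('inf'):.3f}; undercut {undercut:.3f}"
    )
    return AuditReport(
        status="pass" if ok else "fail",
        fes2d=fes2d,
        cv_edges=cv_edges,
        rational_edges=r_edges,
        ts_free_energy=float(f_in),
        undercut=undercut,
        details=details,
    )
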
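"""On-the-fly adaptive-bias enhanced sampling along a 1-D collective variable.

The sampler maintains a kernel-density estimate p(s) of the *sampled*
(biased) CV distribution — the exploration-oriented flavor of on-the-fly
probability-enhanced sampling: every ``pace`` steps each walker deposits one
unit-weight Gaussian kernel at its current CV value. Kernels closer than a
merge threshold are compressed (weighted mean center, pooled width), keeping
the kernel count bounded. The bias is

    V(s) = (gamma - 1) * kT * [ log(p(s)/Z + eps) - log(eps) ],

with gamma = barrier / kT the well-tempered bias factor and Z the running
supremum of the kernel estimate over the explored region, so that p/Z <= 1.
The fixed point of this update is the well-tempered target: the sampled
distribution converges toward exp(-F/(gamma kT)) and the bias toward
const - (1 - 1/gamma) F(s), flattening barriers by the factor gamma.
eps = 1/(e - 1) makes the bias exactly bounded in
[0, (gamma - 1) kT] = [0, (1 - 1/gamma) * barrier] with no clipping, since
(gamma-1) kT log((1+eps)/eps) = (gamma-1) kT. The baseline convention is
V = 0 for an empty kernel list (the bias is defined up to a constant).

Kernel widths adapt to the sampled spread (Silverman-style shrinkage) with a
hard floor ``sigma_min`` so the density estimate never becomes needle-like.
All walkers share one bias; deposits are synchronous at pace boundaries and
see every walker's current CV value.

Reweighting uses the running offset c(t) (the ``rct`` series): each frame's
unbiased weight is exp((V(s_t) - c(t)) / kT). c(t) is the log of the
bias-weighted average of the current probability estimate, recomputed at
every deposit on a fixed quadrature grid; its stabilization marks the end of
the burn-in (see :func:`preorg.fes.detect_burn_in`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ArgumentError, IntegrationError, SamplerError

__all__ = [
    "OPESConfig",
    "BiasState",
    "HarmonicWalls",
    "FeatureWalls",
    "OPESRun",
    "bias_energy",
    "bias_force",
    "deposit",
    "run_opes",
    "count_recrossings",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class OPESConfig:
    """Adaptive-bias settings.

    Defaults mirror the production sampling protocol transplanted to reduced
    units: deposits every 200 steps, a kernel-width floor of 0.3 CV units,
    8 parallel walkers, and a desk-scale budget of 1e5 steps per walker. The
    ``barrier`` parameter should exceed the highest barrier to be crossed
    (the bias saturates at (1 - 1/gamma) * barrier).
    """

    barrier: float
    kT: float = 1.0
    pace: int = 200
    sigma_min: float = 0.3
    n_walkers: int = 8
    n_steps: int = 100_000
    timestep: float = 0.005
    friction: float = 1.0
    merge_threshold: float | None = None
    adaptive_width: bool = True
    stride_out: int = 1

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise ArgumentError("barrier must be positive")
        if self.pace < 1:
            raise ArgumentError("pace must be >= 1")
        if self.sigma_min <= 0:
            raise ArgumentError("sigma_min must be positive")
        if self.n_walkers < 1:
            raise ArgumentError("n_walkers must be >= 1")
        if self.kT <= 0:
            raise ArgumentError("kT must be positive")

    @property
    def gamma(self) -> float:
        """Well-tempered bias factor barrier/kT."""
        return self.barrier / self.kT

    @property
    def epsilon(self) -> float:
        """Regularizer making the bias range exactly (1 - 1/gamma)*barrier."""
        return 1.0 / (np.e - 1.0)

    @property
    def prefactor(self) -> float:
        return (self.gamma - 1.0) * self.kT

    @property
    def max_bias(self) -> float:
        # (gamma - 1) kT == (1 - 1/gamma) * barrier, reached where p/Z = 1
        return (1.0 - 1.0 / self.gamma) * self.barrier


@dataclass
class BiasState:
    """Kernel list, normalization series and reweighting-offset series."""

    grid: np.ndarray
    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    widths: np.ndarray = field(default_factory=lambda: np.empty(0))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    z: float = 1.0
    z_series: list = field(default_factory=list)
    rct_series: list = field(default_factory=list)
    n_deposited: int = 0
    _s_sum: float = 0.0
    _s_sumsq: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ArgumentError("bias grid must be 1-D with at least 2 points")

    @property
    def n_kernels(self) -> int:
        return self.centers.size

    def kde(self, s) -> np.ndarray:
        """Kernel estimate of the sampled CV density (zero when empty)."""
        s = np.asarray(s, dtype=float)
        if self.n_kernels == 0:
            return np.zeros_like(s)
        z = (s[..., None] - self.centers) / self.widths
        dens = (self.weights / (self.widths * _SQRT2PI)) * np.exp(-0.5 * z * z)
        return dens.sum(axis=-1) / self.weights.sum()

    def kde_grad(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.n_kernels == 0:
            return np.zeros_like(s)
        z = (s[..., None] - self.centers) / self.widths
        dens = (self.weights / (self.widths * _SQRT2PI)) * np.exp(-0.5 * z * z)
        return (dens * (-z / self.widths)).sum(axis=-1) / self.weights.sum()

    def sampled_std(self) -> float:
        if self.n_deposited < 2:
            return 0.0
        mean = self._s_sum / self.n_deposited
        var = self._s_sumsq / self.n_deposited - mean * mean
        return float(np.sqrt(max(var, 0.0)))


def bias_energy(s, state: BiasState, config: OPESConfig):
    """Adaptive-bias energy at CV value(s) s; 0 for an empty kernel list.

    Bounded in [0, (1 - 1/gamma) * barrier] by the sup-normalization of the
    probability estimate together with the epsilon regularizer.
    """
    s = np.asarray(s, dtype=float)
    if state.n_kernels == 0:
        return np.zeros_like(s) if s.ndim else 0.0
    eps = config.epsilon
    v = config.prefactor * (np.log(state.kde(s) / state.z + eps) - np.log(eps))
    # the sup-normalization is evaluated on a finite probe set, so p/Z can
    # exceed 1 by a sliver between probe points; saturate at the exact cap
    v = np.minimum(v, config.max_bias)
    return v if v.ndim else float(v)


def bias_force(s, state: BiasState, config: OPESConfig):
    """-dV/ds; zero for an empty kernel list."""
    s = np.asarray(s, dtype=float)
    if state.n_kernels == 0:
        return np.zeros_like(s) if s.ndim else 0.0
    eps = config.epsilon
    p = state.kde(s)
    dv = config.prefactor * (state.kde_grad(s) / state.z) / (p / state.z + eps)
    f = -dv
    return f if f.ndim else float(f)


def _update_normalization(state: BiasState, config: OPESConfig) -> None:
    # running sup-normalization over the explored region, so that P/Z <= 1
    probe = np.concatenate((state.centers, state.grid))
    state.z = float(state.kde(probe).max())
    state.z_series.append(state.z)
    # reweighting offset c(t): log of the bias-weighted average of P over the grid
    p = state.kde(state.grid)
    v = config.prefactor * (np.log(p / state.z + config.epsilon) - np.log(config.epsilon))
    num = np.sum(p * np.exp(v / config.kT))
    den = np.sum(p)
    state.rct_series.append(float(config.kT * np.log(num / den)) if den > 0 else 0.0)


def deposit(s_values, state: BiasState, config: OPESConfig) -> BiasState:
    """Deposit one kernel per walker, with merging, width floor and Z update.

    Kernels carry unit weight (visit counts): the estimate tracks the
    sampled CV distribution, whose well-tempered fixed point encodes the
    free energy. The requested kernel width is the Silverman-shrunk running
    spread of all deposited CV values, floored at ``sigma_min``. A new
    kernel closer than the merge threshold (default: its own width) to an
    existing kernel is merged into it: weighted mean center, pooled width,
    summed weight. The normalization Z and the reweighting offset c(t) are
    recomputed once per deposit call, so ``rct_series`` has one entry per
    deposit.
    """
    s_values = np.atleast_1d(np.asarray(s_values, dtype=float))
    bad = np.nonzero(~np.isfinite(s_values))[0]
    if bad.size:
        raise SamplerError(f"non-finite CV value from walker {int(bad[0])}")
    centers = list(state.centers)
    widths = list(state.widths)
    weights = list(state.weights)
    for s in s_values:
        w_new = 1.0
        state.n_deposited += 1
        state._s_sum += s
        state._s_sumsq += s * s
        if config.adaptive_width and state.n_deposited > 1:
            sigma = state.sampled_std() * state.n_deposited ** (-0.2)
        else:
            sigma = 0.0
        sigma = max(sigma, config.sigma_min)
        thr = config.merge_threshold if config.merge_threshold is not None else sigma
        if centers:
            arr = np.asarray(centers)
            i = int(np.argmin(np.abs(arr - s)))
            if abs(arr[i] - s) < thr:
                w0, c0, s0 = weights[i], centers[i], widths[i]
                w = w0 + w_new
                c = (w0 * c0 + w_new * s) / w
                m2 = (w0 * (s0 * s0 + c0 * c0) + w_new * (sigma * sigma + s * s)) / w - c * c
                centers[i], widths[i], weights[i] = c, float(np.sqrt(max(m2, config.sigma_min**2))), w
                continue
        centers.append(float(s))
        widths.append(float(sigma))
        weights.append(float(w_new))
    state.centers = np.asarray(centers)
    state.widths = np.asarray(widths)
    state.weights = np.asarray(weights)
    _update_normalization(state, config)
    return state


class HarmonicWalls:
    """One-dimensional lower/upper harmonic walls on the biased coordinate."""

    def __init__(self, lower: float, upper: float, k: float = 20.0):
        if not lower < upper:
            raise ArgumentError("lower wall must lie below upper wall")
        if k <= 0:
            raise ArgumentError("force constant must be positive")
        self.lower, self.upper, self.k = lower, upper, k

    def energy(self, s):
        s = np.asarray(s, dtype=float)
        below = np.clip(self.lower - s, 0.0, None)
        above = np.clip(s - self.upper, 0.0, None)
        return 0.5 * self.k * (below**2 + above**2)

    def force(self, s):
        s = np.asarray(s, dtype=float)
        below = np.clip(self.lower - s, 0.0, None)
        above = np.clip(s - self.upper, 0.0, None)
        return self.k * (below - above)


class FeatureWalls:
    """Hull walls on raw distances, pulled back through a feature map.

    Composes a :class:`preorg.features.WallSet` (thresholds on raw
    distances) with a differentiable map x -> distances so the wall force
    acts on the 1-D surrogate coordinate.
    """

    def __init__(self, wallset, feature_map):
        self.wallset = wallset
        self.feature_map = feature_map

    def energy(self, x):
        return self.wallset.energy(self.feature_map(np.asarray(x, dtype=float)))

    def force(self, x):
        x = np.asarray(x, dtype=float)
        g = self.wallset.gradient(self.feature_map(x))
        df = self.feature_map.derivative(x)
        return -(g * df).sum(axis=-1)


@dataclass
class OPESRun:
    """Output of a biased multi-walker run: frames plus the shared bias state.

    Frame arrays have shape (n_frames, n_walkers). ``rct`` holds the
    reweighting offset current at each frame (one value per frame, shared by
    the walkers).
    """

    positions: np.ndarray
    cv_values: np.ndarray
    bias: np.ndarray
    wall: np.ndarray
    rct: np.ndarray
    state: BiasState
    config: OPESConfig
    seed: int

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def flat(self, burn_in: int = 0):
        """(cv, bias, rct) flattened over walkers, for reweighting."""
        s = self.cv_values[burn_in:].ravel()
        b = self.bias[burn_in:].ravel()
        c = np.repeat(self.rct[burn_in:], self.cv_values.shape[1])
        return s, b, c

    def to_frame(self):
        import pandas as pd

        n_f, n_w = self.positions.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_f), n_w),
                "walker": np.tile(np.arange(n_w), n_f),
                "position": self.positions.ravel(),
                "cv": self.cv_values.ravel(),
                "bias": self.bias.ravel(),
                "wall": self.wall.ravel(),
                "rct": np.repeat(self.rct, n_w),
            }
        )


def _identity_cv(x: np.ndarray):
    return x, np.ones_like(x)


def run_opes(
    potential,
    config: OPESConfig,
    cv: Callable[[np.ndarray], tuple] | None = None,
    walls=None,
    seed: int = 0,
    x0=None,
    bias_state: BiasState | None = None,
    recross_thresholds: tuple | None = None,
) -> OPESRun:
    """Biased multi-walker Langevin (BAOAB) run on a 1-D surrogate potential.

    ``cv`` maps walker coordinates to (s, ds/dx); by default the coordinate
    itself is the CV. All walkers share one :class:`BiasState`; every
    ``pace`` steps each walker deposits a kernel. ``walls`` (an object with
    ``energy``/``force`` on x) keeps the walkers inside the training hull.
    Walkers start at ``x0`` (scalar or per-walker array; defaults to the
    first basin center). If no recrossing of the main barrier occurs, a
    convergence warning is emitted and the outputs are still returned.
    """
    kT = potential.temperature
    if abs(kT - config.kT) > 1e-12:
        raise ArgumentError("potential temperature and config.kT disagree")
    cv_fun = cv if cv is not None else _identity_cv
    rng = np.random.default_rng(seed)
    nw = config.n_walkers
    if x0 is None:
        x = np.full(nw, float(np.asarray(potential.basin_centers)[0]))
    else:
        x = np.broadcast_to(np.asarray(x0, dtype=float), (nw,)).copy()
    v = rng.normal(0.0, np.sqrt(kT), size=nw)

    if bias_state is None:
        centers = np.asarray(potential.basin_centers, float)
        s_lo, s_hi = cv_fun(np.array([centers.min(), centers.max()]))[0]
        pad = 0.25 * (s_hi - s_lo) if s_hi > s_lo else 1.0
        bias_state = BiasState(grid=np.linspace(s_lo - pad, s_hi + pad, 201))
    state = bias_state

    dt, gamma_f = config.timestep, config.friction
    c1 = np.exp(-gamma_f * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    guard = 10.0 * max(float(np.abs(np.asarray(potential.basin_centers)).max()), 1.0)

    def forces(xx):
        s, dsdx = cv_fun(xx)
        f = potential.force(xx) + bias_force(s, state, config) * dsdx
        wall_e = np.zeros_like(xx)
        if walls is not None:
            f = f + walls.force(xx)
            wall_e = walls.energy(xx)
        return f, s, wall_e

    n_out = config.n_steps // config.stride_out
    positions = np.empty((n_out, nw))
    cv_out = np.empty((n_out, nw))
    bias_out = np.empty((n_out, nw))
    wall_out = np.empty((n_out, nw))
    rct_out = np.empty(n_out)

    f, s, wall_e = forces(x)
    j = 0
    for step in range(config.n_steps):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(nw)
        x += 0.5 * dt * v
        f, s, wall_e = forces(x)
        v += 0.5 * dt * f
        if np.any(np.abs(x) > guard):
            raise IntegrationError(f"walker diverged at step {step}")
        if (step + 1) % config.pace == 0:
            deposit(s, state, config)
            f, _, _ = forces(x)  # bias changed; refresh force
        if (step + 1) % config.stride_out == 0:
            positions[j] = x
            cv_out[j] = s
            bias_out[j] = bias_energy(s, state, config)
            wall_out[j] = wall_e
            rct_out[j] = state.rct_series[-1] if state.rct_series else 0.0
            j += 1

    run = OPESRun(
        positions=positions,
        cv_values=cv_out,
        bias=bias_out,
        wall=wall_out,
        rct=rct_out,
        state=state,
        config=config,
        seed=seed,
    )
    if recross_thresholds is None and np.asarray(potential.basin_centers).size >= 2:
        bc = np.asarray(potential.basin_centers, float)
        lo = bc[0] + (bc[-1] - bc[0]) / 3.0
        hi = bc[0] + 2.0 * (bc[-1] - bc[0]) / 3.0
        recross_thresholds = (lo, hi)
    if recross_thresholds is not None:
        n_cross = count_recrossings(positions, *recross_thresholds)
        if n_cross == 0:
            warnings.warn(
                "no barrier recrossing within the sampling budget; "
                "free-energy estimates may not be converged",
                RuntimeWarning,
            )
    return run


def count_recrossings(series: np.ndarray, lower: float, upper: float) -> int:
    """Total basin-to-basin transitions with hysteresis, summed over walkers.

    A walker is assigned to basin A below ``lower`` and basin B above
    ``upper``; values in between keep the previous assignment. Each change
    of assignment counts as one crossing.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    total = 0
    for w in range(arr.shape[1]):
        x = arr[:, w]
        sides = np.where(x < lower, -1, np.where(x > upper, 1, 0))
        sides = sides[sides != 0]  # frames inside the band keep the last side
        if sides.size:
            total += int(np.count_nonzero(np.diff(sides)))
    return total
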
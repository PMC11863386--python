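"""Synthetic surrogate for the reactive system.

The cluster-scale QM/MM engine is replaced by a desk-scale surrogate with an
exactly computable free-energy surface, so every downstream stage (CV
training, adaptive biasing, reweighting, state energetics) can be verified
against closed-form or quadrature oracles. The surrogate provides

* state-labeled feature ensembles (Gaussian "pairwise distance" tables per
  reaction state) that play the role of unbiased per-state sampling used to
  populate CV training sets;
* analytic one-dimensional multi-basin potentials with a spectator-charge
  coupling term q*phi(x), emulating the perturbation a remote net charge
  exerts on the barriers; and
* an underdamped Langevin (BAOAB) propagator whose stationary distribution
  is the Boltzmann density of the potential.

Reduced units are used throughout (kT = 1 unless stated otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ArgumentError,
    CoverageError,
    DimensionError,
    IntegrationError,
)
from .fes import FESProfile

__all__ = [
    "STATE_LABELS",
    "StateSpec",
    "SurrogatePotential",
    "QuarticDoubleWell",
    "LangevinConfig",
    "Trajectory",
    "generate_state_ensembles",
    "default_stage_specs",
    "langevin_sample",
    "exact_fes",
    "SurrogateFeatureMap",
]

#: the five states of a two-step reaction stage (reactant, first transition
#: state, tetrahedral-intermediate analogue, second transition state, product)
STATE_LABELS = ("RS", "TS1", "INT", "TS2", "PS")


@dataclass(frozen=True)
class StateSpec:
    """Per-state feature distribution used to emulate unbiased sampling.

    ``population_class`` is the integer class index used for CV training
    (0 reactant-like, 1 intermediate-like, 2 product-like). Across a stage's
    stable states the class indices must cover {0, 1, 2}, matching the three
    target centers of the discriminant CV.
    """

    label: str
    feature_means: np.ndarray
    feature_sds: np.ndarray
    population_class: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_means", np.atleast_1d(np.asarray(self.feature_means, float)))
        object.__setattr__(self, "feature_sds", np.atleast_1d(np.asarray(self.feature_sds, float)))
        if self.feature_means.shape != self.feature_sds.shape:
            raise DimensionError("feature_means and feature_sds must have identical length")
        if np.any(self.feature_sds < 0):
            raise ArgumentError("feature spreads must be non-negative")

    @property
    def n_features(self) -> int:
        return self.feature_means.size


def generate_state_ensembles(
    specs: Sequence[StateSpec],
    n_per_state: int,
    seed: int,
    mode: str = "pooled",
    n_replicas: int = 8,
) -> pd.DataFrame:
    """Draw labeled Gaussian feature ensembles, one block per state.

    Returns a DataFrame with columns ``feat_0 .. feat_{k-1}``, ``state``,
    ``class_index`` and, in ``mode="per_replica"``, a ``replica`` column.
    The per-replica mode splits each state's budget over ``n_replicas``
    independently seeded streams, emulating pooling of several short unbiased
    runs; the pooled mode draws each state from a single stream. Fixed seed
    and arguments give a byte-identical table.
    """
    if n_per_state < 2:
        raise ArgumentError("n_per_state must be at least 2")
    if not specs:
        raise ArgumentError("at least one StateSpec required")
    k = specs[0].n_features
    for spec in specs:
        if spec.n_features != k:
            raise DimensionError("all states must share feature dimensionality")
    if mode not in ("pooled", "per_replica"):
        raise ArgumentError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    blocks = []
    for spec in specs:
        if mode == "pooled":
            x = rng.normal(spec.feature_means, spec.feature_sds, size=(n_per_state, k))
            rep = None
        else:
            streams = rng.spawn(n_replicas)
            counts = np.full(n_replicas, n_per_state // n_replicas)
            counts[: n_per_state % n_replicas] += 1
            parts, rep_parts = [], []
            for r, (stream, c) in enumerate(zip(streams, counts)):
                if c:
                    parts.append(stream.normal(spec.feature_means, spec.feature_sds, size=(c, k)))
                    rep_parts.append(np.full(c, r))
            x = np.vstack(parts)
            rep = np.concatenate(rep_parts)
        df = pd.DataFrame(x, columns=[f"feat_{i}" for i in range(k)])
        df["state"] = spec.label
        df["class_index"] = spec.population_class
        if rep is not None:
            df["replica"] = rep
        blocks.append(df)
    return pd.concat(blocks, ignore_index=True)


def default_stage_specs(n_features: int = 36, separation: float = 0.8) -> list[StateSpec]:
    """Stable-state specs for a two-step stage with well-separated classes.

    Baseline "distances" span 2.5–8.0 Å across features; the three stable
    states (RS, INT, PS) are offset by ±``separation`` Å with an alternating
    sign pattern, emulating bonds that form and break along the reaction,
    with a per-state spread of 0.15 Å. These are the study conditions used by
    the CV-training verification: classes separable but overlapping feature
    ranges, as for real pre-reaction distance distributions.
    """
    base = np.linspace(2.5, 8.0, n_features)
    signs = (-1.0) ** np.arange(n_features)
    sds = np.full(n_features, 0.15)
    specs = []
    for cls, label in enumerate(("RS", "INT", "PS")):
        means = base + (cls - 1) * separation * signs
        specs.append(StateSpec(label=label, feature_means=means, feature_sds=sds, population_class=cls))
    return specs


# --------------------------------------------------------------------------
# analytic potentials


class _PotentialBase:
    """Shared spectator-charge machinery for 1-D surrogate potentials.

    The total potential is U(x) = U0(x) + q * phi(x) with phi a localized
    Gaussian coupling function centered on the main barrier; for a stiff
    system the induced barrier shift equals q * (phi(x_TS) - phi(x_RS)).
    """

    charge: float
    coupling_center: float
    coupling_width: float
    temperature: float

    def _coupling(self, x: np.ndarray) -> np.ndarray:
        if self.charge == 0.0:
            return np.zeros_like(x)
        z = (x - self.coupling_center) / self.coupling_width
        return self.charge * np.exp(-0.5 * z * z)

    def _coupling_force(self, x: np.ndarray) -> np.ndarray:
        if self.charge == 0.0:
            return np.zeros_like(x)
        z = (x - self.coupling_center) / self.coupling_width
        return self.charge * np.exp(-0.5 * z * z) * z / self.coupling_width

    def coupling_value(self, x) -> np.ndarray:
        """phi evaluated with unit charge (the coupling function itself)."""
        z = (np.asarray(x, float) - self.coupling_center) / self.coupling_width
        return np.exp(-0.5 * z * z)

    def with_charge(self, q: float):
        return replace(self, charge=q)


@dataclass(frozen=True)
class SurrogatePotential(_PotentialBase):
    """Multi-basin 1-D potential built from Gaussian wells and barriers.

    Basins sit at ``basin_centers`` with depths ``basin_depths`` below the
    baseline; a Gaussian barrier of height ``barrier_heights[j]`` rises at
    the midpoint between consecutive basins. A polynomial confinement term
    (height ``confinement`` at ``domain_halfwidth`` from the centroid) keeps
    trajectories bounded; set ``confinement=0`` for an exactly constructed
    potential with no extraneous terms. Smooth and bounded below throughout.
    """

    basin_centers: np.ndarray
    basin_depths: np.ndarray
    barrier_heights: np.ndarray
    basin_width: float = 0.25
    barrier_width: float = 0.15
    charge: float = 0.0
    coupling_center: float | None = None
    coupling_width: float = 0.3
    temperature: float = 1.0
    confinement: float = 30.0
    domain_halfwidth: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "basin_centers", np.atleast_1d(np.asarray(self.basin_centers, float)))
        object.__setattr__(self, "basin_depths", np.atleast_1d(np.asarray(self.basin_depths, float)))
        object.__setattr__(self, "barrier_heights", np.atleast_1d(np.asarray(self.barrier_heights, float)))
        n = self.basin_centers.size
        if self.basin_depths.size != n:
            raise DimensionError("one depth per basin required")
        if n > 1 and self.barrier_heights.size != n - 1:
            raise DimensionError("one barrier height per adjacent basin pair required")
        if np.any(np.diff(self.basin_centers) <= 0):
            raise ArgumentError("basin centers must be strictly increasing")
        if self.temperature <= 0:
            raise ArgumentError("temperature (kT) must be positive")
        if self.coupling_center is None:
            mids = self._midpoints()
            cc = float(mids[0]) if mids.size else float(self.basin_centers[0])
            object.__setattr__(self, "coupling_center", cc)
        if self.domain_halfwidth is None:
            span = self.basin_centers[-1] - self.basin_centers[0]
            object.__setattr__(self, "domain_halfwidth", 0.5 * span + 8 * self.basin_width)

    @property
    def n_basins(self) -> int:
        return self.basin_centers.size

    def _midpoints(self) -> np.ndarray:
        return 0.5 * (self.basin_centers[1:] + self.basin_centers[:-1])

    @property
    def _centroid(self) -> float:
        return float(self.basin_centers.mean())

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = np.zeros_like(x)
        for c, d in zip(self.basin_centers, self.basin_depths):
            u -= d * np.exp(-0.5 * ((x - c) / self.basin_width) ** 2)
        for m, b in zip(self._midpoints(), self.barrier_heights):
            u += b * np.exp(-0.5 * ((x - m) / self.barrier_width) ** 2)
        if self.confinement:
            u += self.confinement * ((x - self._centroid) / self.domain_halfwidth) ** 8
        return u + self._coupling(x)

    def force(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        f = np.zeros_like(x)
        for c, d in zip(self.basin_centers, self.basin_depths):
            z = (x - c) / self.basin_width
            f -= d * np.exp(-0.5 * z * z) * z / self.basin_width
        for m, b in zip(self._midpoints(), self.barrier_heights):
            z = (x - m) / self.barrier_width
            f += b * np.exp(-0.5 * z * z) * z / self.barrier_width
        if self.confinement:
            f -= 8 * self.confinement * ((x - self._centroid) ** 7) / self.domain_halfwidth**8
        return f + self._coupling_force(x)


@dataclass(frozen=True)
class QuarticDoubleWell(_PotentialBase):
    """U0(x) = barrier * ((x/a)^2 - 1)^2: minima at ±a, barrier at x = 0.

    The workhorse benchmark potential: the barrier height is exact by
    construction and the 1-D free energy along x equals U(x) up to a
    constant, so quadrature gives the ground truth directly.
    """

    barrier: float = 10.0
    half_separation: float = 1.0
    charge: float = 0.0
    coupling_center: float = 0.0
    coupling_width: float = 0.3
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.barrier <= 0 or self.half_separation <= 0:
            raise ArgumentError("barrier and half_separation must be positive")

    @property
    def basin_centers(self) -> np.ndarray:
        return np.array([-self.half_separation, self.half_separation])

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = (x / self.half_separation) ** 2 - 1.0
        return self.barrier * y * y + self._coupling(x)

    def force(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        a2 = self.half_separation**2
        y = x * x / a2 - 1.0
        return -4.0 * self.barrier * y * x / a2 + self._coupling_force(x)


@dataclass(frozen=True)
class LangevinConfig:
    """Propagator settings in reduced units (mass = 1)."""

    timestep: float = 0.005
    friction: float = 1.0
    n_steps: int = 100_000
    seed: int = 0
    initial_position: float = 0.0
    stride_out: int = 1

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ArgumentError("timestep must be positive")
        if self.friction <= 0:
            raise ArgumentError("friction must be positive")
        if self.n_steps < 1:
            raise ArgumentError("n_steps must be at least 1")
        if self.stride_out < 1:
            raise ArgumentError("stride_out must be at least 1")


@dataclass
class Trajectory:
    """Frames of a (possibly biased) Langevin run plus a config echo."""

    positions: np.ndarray
    potential_energy: np.ndarray
    bias_energy: np.ndarray
    config: LangevinConfig

    @property
    def n_frames(self) -> int:
        return self.positions.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "potential_energy": self.potential_energy,
                "bias_energy": self.bias_energy,
            }
        )


def _domain_guard(potential) -> float:
    centers = np.abs(np.asarray(potential.basin_centers, float))
    return 10.0 * max(float(centers.max()), 1.0)


def langevin_sample(
    potential,
    config: LangevinConfig,
    bias: Callable[[np.ndarray], tuple] | None = None,
) -> Trajectory:
    """Underdamped Langevin (BAOAB) trajectory on a 1-D surrogate potential.

    ``bias``, when given, is a callable x -> (energy, force) adding an
    external biasing potential. The stationary distribution of the unbiased
    integrator converges to the Boltzmann density of the potential at its
    ``temperature``. Trajectories leaving |x| > 10x the outermost basin
    center raise :class:`IntegrationError` naming the step.
    """
    kT = potential.temperature
    u0 = float(potential.energy(np.array(config.initial_position)))
    if not np.isfinite(u0):
        raise ArgumentError("potential must be finite at the initial position")
    dt, gamma = config.timestep, config.friction
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    guard = _domain_guard(potential)
    rng = np.random.default_rng(config.seed)

    x = float(config.initial_position)
    v = float(rng.normal(0.0, np.sqrt(kT)))

    def total_force(xx: float) -> tuple[float, float]:
        arr = np.array(xx)
        f = float(potential.force(arr))
        b = 0.0
        if bias is not None:
            be, bf = bias(arr)
            f += float(bf)
            b = float(be)
        return f, b

    n_out = config.n_steps // config.stride_out
    positions = np.empty(n_out)
    pot_e = np.empty(n_out)
    bias_e = np.empty(n_out)
    f, _ = total_force(x)
    noise = rng.standard_normal(config.n_steps)
    j = 0
    for step in range(config.n_steps):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * noise[step]
        x += 0.5 * dt * v
        f, b = total_force(x)
        v += 0.5 * dt * f
        if abs(x) > guard:
            raise IntegrationError(f"trajectory diverged at step {step}")
        if (step + 1) % config.stride_out == 0:
            positions[j] = x
            pot_e[j] = float(potential.energy(np.array(x)))
            bias_e[j] = b
            j += 1
    return Trajectory(positions=positions, potential_energy=pot_e, bias_energy=bias_e, config=config)


def exact_fes(potential, grid: np.ndarray, n_quad: int = 8) -> FESProfile:
    """Ground-truth free energy by per-bin Gauss–Legendre quadrature.

    Each bin's free energy is -kT log of the bin-averaged Boltzmann weight,
    min-shifted to zero. The grid (bin centers) must cover every basin
    center; otherwise a :class:`CoverageError` is raised.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ArgumentError("grid must be 1-D, strictly increasing, length >= 2")
    centers = np.asarray(potential.basin_centers, float)
    if centers.min() < grid[0] or centers.max() > grid[-1]:
        raise CoverageError("grid does not cover all basins")
    kT = potential.temperature
    dx = np.diff(grid)
    half = np.concatenate((dx[:1], dx)) / 2, np.concatenate((dx, dx[-1:])) / 2
    lo = grid - half[0]
    hi = grid + half[1]
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    # map nodes into every bin; (n_bins, n_quad)
    mid = 0.5 * (lo + hi)
    rad = 0.5 * (hi - lo)
    pts = mid[:, None] + rad[:, None] * nodes[None, :]
    u = potential.energy(pts)
    u0 = u.min()
    boltz = np.exp(-(u - u0) / kT)
    avg = (boltz * weights[None, :]).sum(axis=1) / 2.0  # mean over the bin
    f = -kT * np.log(avg) + u0
    f -= f.min()
    return FESProfile(grid=grid, free_energy=f, sem=np.zeros_like(f), n_replicates=1)


class SurrogateFeatureMap:
    """Deterministic map from the reaction coordinate to raw feature distances.

    Interpolates the per-state mean feature vectors along x with a monotone
    piecewise-cubic (PCHIP) through the state centers, giving a smooth
    surrogate "geometry" so a feature-based CV can be composed with the 1-D
    dynamics. Used by end-to-end pipeline checks.
    """

    def __init__(self, state_positions: Sequence[float], state_means: Sequence[np.ndarray]):
        from scipy.interpolate import PchipInterpolator

        xs = np.asarray(state_positions, dtype=float)
        ys = np.vstack([np.asarray(m, float) for m in state_means])
        if xs.size != ys.shape[0]:
            raise DimensionError("one mean vector per state position required")
        self._interp = PchipInterpolator(xs, ys, axis=0, extrapolate=True)
        self.n_features = ys.shape[1]

    def __call__(self, x) -> np.ndarray:
        return self._interp(np.asarray(x, dtype=float))

    def derivative(self, x) -> np.ndarray:
        return self._interp.derivative()(np.asarray(x, dtype=float))


def composite_cv(model, feature_map: SurrogateFeatureMap, switch_r0=4.0,
                 switch_n: int = 6, switch_m: int = 12):
    """Compose a trained CV model with the surrogate feature map.

    Returns a callable x -> (s, ds/dx) chaining reaction coordinate ->
    raw distances -> switch-normalized features -> network CV, with the
    derivative assembled by the chain rule (network input gradient x switch
    derivative x feature-map slope). Suitable as the ``cv`` argument of the
    adaptive-bias sampler.
    """
    from .features import switch_derivative, switch_normalize

    def cv(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        raw = np.atleast_2d(feature_map(x))
        feats = switch_normalize(raw, switch_r0, switch_n, switch_m)
        s = model.evaluate(feats)
        g = model.input_gradient(feats)
        dsw = switch_derivative(raw, switch_r0, switch_n, switch_m)
        dfdx = np.atleast_2d(feature_map.derivative(x))
        dsdx = np.sum(g * dsw * dfdx, axis=1)
        return s, dsdx

    return cv
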
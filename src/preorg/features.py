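"""Switch-normalized pairwise-distance features and training-hull walls.

The collective-variable input is the full set of pairwise distances between
a small group of reactive atoms (9 atoms -> 36 distances for the first
reaction stage, 8 -> 28 for the second, matching the CV networks' first
layer widths), each mapped to [0, 1] by a rational switching function

    s(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m),    m > n > 0,

with the removable singularity at r = r0 filled by its limit n/m. Because
neural networks extrapolate poorly, biased production sampling is confined
to the convex hull of the training data by harmonic wall potentials placed
at low/high percentiles of each raw-distance distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError, DimensionError

__all__ = [
    "FeatureSpec",
    "pairwise_distances",
    "switch_normalize",
    "featurize",
    "WallSet",
    "hull_walls",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Atom group and switching-function parameters for one reaction stage.

    ``switch_r0`` may be a scalar (shared by all pairs) or an array with one
    value per canonical pair. Defaults (n, m) = (6, 12) follow the common
    rational-switch convention; r0 defaults to 4 A and is configuration, to
    be matched to the system at hand.
    """

    atom_ids: tuple
    switch_r0: float | np.ndarray = 4.0
    switch_n: int = 6
    switch_m: int = 12

    def __post_init__(self) -> None:
        ids = tuple(self.atom_ids)
        if len(set(ids)) != len(ids):
            raise ArgumentError("atom_ids must be unique")
        if len(ids) < 2:
            raise ArgumentError("at least two atoms required")
        if not (self.switch_m > self.switch_n > 0):
            raise ArgumentError("switch exponents must satisfy m > n > 0")
        object.__setattr__(self, "atom_ids", ids)
        r0 = np.asarray(self.switch_r0, dtype=float)
        if np.any(r0 <= 0):
            raise ArgumentError("switch_r0 must be positive")
        if r0.ndim not in (0, 1) or (r0.ndim == 1 and r0.size != self.n_features):
            raise DimensionError("switch_r0 must be scalar or one value per pair")
        object.__setattr__(self, "switch_r0", r0)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def n_features(self) -> int:
        k = len(self.atom_ids)
        return k * (k - 1) // 2

    @property
    def pair_index(self) -> list[tuple]:
        """Canonical (i < j) ordering of atom-id pairs."""
        return list(combinations(self.atom_ids, 2))


def pairwise_distances(positions: Mapping | np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """All C(k,2) interatomic distances in canonical (i < j) pair order.

    ``positions`` is either a mapping atom_id -> xyz or an (n_atoms, 3)
    array ordered like ``spec.atom_ids``. Translation- and
    rotation-invariant by construction.
    """
    if isinstance(positions, Mapping):
        try:
            coords = np.asarray([positions[i] for i in spec.atom_ids], dtype=float)
        except KeyError as exc:
            raise ArgumentError(f"atom {exc.args[0]!r} missing from frame") from exc
    else:
        coords = np.asarray(positions, dtype=float)
        if coords.shape != (spec.n_atoms, 3):
            raise DimensionError(
                f"expected positions of shape {(spec.n_atoms, 3)}, got {coords.shape}"
            )
    i, j = np.triu_indices(spec.n_atoms, k=1)
    return np.linalg.norm(coords[i] - coords[j], axis=1)


def switch_normalize(r, r0=4.0, n: int = 6, m: int = 12):
    """Rational switching function s(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m).

    Continuous on [0, inf), strictly decreasing for m > n, s(0) = 1,
    s(r0) = n/m (the L'Hopital limit of the 0/0 form), s -> 0 as r -> inf.
    Negative distances raise :class:`ArgumentError`.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ArgumentError("distances must be non-negative")
    if not m > n > 0:
        raise ArgumentError("switch exponents must satisfy m > n > 0")
    y = r / np.asarray(r0, dtype=float)
    near_one = np.abs(y - 1.0) < 1e-8
    y_safe = np.where(near_one, 2.0, y)
    direct = (1.0 - y_safe**n) / (1.0 - y_safe**m)
    # first-order expansion around the removable singularity at y = 1
    limit = (n / m) * (1.0 + 0.5 * (n - m) * (y - 1.0))
    out = np.where(near_one, limit, direct)
    return out if out.ndim else float(out)


def featurize(positions, spec: FeatureSpec) -> np.ndarray:
    """Switch-normalized feature vector for one frame."""
    r = pairwise_distances(positions, spec)
    return switch_normalize(r, spec.switch_r0, spec.switch_n, spec.switch_m)


def switch_derivative(r, r0=4.0, n: int = 6, m: int = 12):
    """ds/dr of the rational switch (analytic away from r = r0)."""
    r = np.asarray(r, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    y = r / r0
    near_one = np.abs(y - 1.0) < 1e-8
    y_safe = np.where(near_one, 2.0, y)
    num = 1.0 - y_safe**n
    den = 1.0 - y_safe**m
    d = (-n * y_safe ** (n - 1) * den + m * y_safe ** (m - 1) * num) / (den * den) / r0
    d_limit = (n * (n - m)) / (2.0 * m) / r0 * np.ones_like(y)
    out = np.where(near_one, d_limit, d)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class WallSet:
    """Harmonic lower/upper walls per raw-distance feature.

    Energy of a frame's raw distance vector d:
        sum_i (k/2) [ (lower_i - d_i)_+^2 + (d_i - upper_i)_+^2 ].
    Inside the hull the energy and force vanish identically.
    """

    lower: np.ndarray
    upper: np.ndarray
    k: float

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, float))
        upper = np.atleast_1d(np.asarray(self.upper, float))
        if lower.shape != upper.shape:
            raise DimensionError("lower and upper thresholds must align")
        if np.any(upper < lower):
            raise ArgumentError("upper thresholds must be >= lower thresholds")
        if self.k <= 0:
            raise ArgumentError("force constant must be positive")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    def energy(self, d) -> float | np.ndarray:
        d = np.asarray(d, dtype=float)
        below = np.clip(self.lower - d, 0.0, None)
        above = np.clip(d - self.upper, 0.0, None)
        e = 0.5 * self.k * (below**2 + above**2)
        return e.sum(axis=-1)

    def gradient(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        below = np.clip(self.lower - d, 0.0, None)
        above = np.clip(d - self.upper, 0.0, None)
        return self.k * (above - below)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lower": self.lower, "upper": self.upper, "k": self.k})


def hull_walls(
    training_features,
    low: float = 0.005,
    high: float = 0.995,
    k: float = 20.0,
) -> WallSet:
    """Percentile walls confining sampling to the training-data hull.

    Defaults follow the production protocol: walls with k = 20 kcal/mol/A^2
    on raw distances below the 0.5% and above the 99.5% percentiles of the
    training-set distributions. A degenerate (constant) feature yields
    coinciding walls; both are kept and a warning is emitted.
    """
    x = np.asarray(training_features, dtype=float)
    if x.size == 0:
        raise DataError("training feature table is empty")
    if x.ndim == 1:
        x = x[:, None]
    if not 0 < low < high < 1:
        raise ArgumentError("need 0 < low < high < 1")
    lower = np.quantile(x, low, axis=0, method="linear")
    upper = np.quantile(x, high, axis=0, method="linear")
    degenerate = np.nonzero(upper == lower)[0]
    if degenerate.size:
        warnings.warn(
            f"degenerate (constant) features at indices {degenerate.tolist()}: "
            "lower and upper walls coincide",
            RuntimeWarning,
        )
    return WallSet(lower=lower, upper=upper, k=k)
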
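"""Charge-neutralization schemes and restraint builders.

The charge-decoupling intervention removes a residue's *net* charge while
leaving everything else intact. Two schemes operate on a residue topology:

* **polar** — backbone charges are replaced by the neutral-form reference
  values, side-chain charges are halved and then shifted by one uniform
  per-atom constant so the whole residue sums to exactly zero. The residue
  stays polar; the relative ordering of side-chain charges is preserved.
* **apolar** — backbone charges are replaced by the neutral-form values and
  side-chain charges are rescaled by one common factor chosen to zero the
  residue sum; when the required side-chain sum is zero the charges are set
  to zero (the limiting case), effectively an apolar substitution.

Restraint builders keep the perturbed system in the reference configuration:
positional restraints on backbone atoms beyond a cutoff radius from the
active-site center, and one-sided harmonic "upper wall" restraints on
hydrogen-bond distances placed at a percentile of their unbiased
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError, GeometryError, SchemeError

__all__ = [
    "BACKBONE_ATOMS",
    "AtomRecord",
    "ResidueTopology",
    "RestraintSpec",
    "apply_polar_scheme",
    "apply_apolar_scheme",
    "build_positional_restraints",
    "build_hbond_walls",
    "wall_energy",
    "read_topology_table",
    "write_topology_table",
]

#: standard protein backbone atom names (partition used when a topology does
#: not carry explicit backbone flags)
BACKBONE_ATOMS = frozenset({"N", "H", "CA", "HA", "C", "O"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a residue topology or structure."""

    atom_name: str
    residue_id: int
    residue_name: str
    partial_charge: float = 0.0
    is_backbone: bool = False
    position: tuple | None = None

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ArgumentError("atom_name must be nonempty")
        if self.position is not None:
            pos = tuple(float(v) for v in self.position)
            if len(pos) != 3:
                raise GeometryError("position must be a 3-D coordinate")
            object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class ResidueTopology:
    """Ordered atoms of one residue plus neutral-form backbone reference charges."""

    atoms: tuple
    neutral_form_backbone_charges: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if not self.atoms:
            raise ArgumentError("residue must contain at least one atom")

    @property
    def net_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    @property
    def backbone_atoms(self) -> tuple:
        return tuple(a for a in self.atoms if a.is_backbone)

    @property
    def side_chain_atoms(self) -> tuple:
        return tuple(a for a in self.atoms if not a.is_backbone)


def _neutral_backbone(residue: ResidueTopology) -> list[AtomRecord]:
    out = []
    for a in residue.atoms:
        if a.is_backbone:
            try:
                q = residue.neutral_form_backbone_charges[a.atom_name]
            except KeyError as exc:
                raise SchemeError(
                    f"no neutral-form reference charge for backbone atom {a.atom_name!r}"
                ) from exc
            out.append(replace(a, partial_charge=float(q)))
        else:
            out.append(a)
    return out


def apply_polar_scheme(residue: ResidueTopology) -> ResidueTopology:
    """Halve-and-shift neutralization preserving side-chain polarity.

    Backbone charges become the neutral-form reference values; each
    side-chain charge q becomes q/2 + delta with one uniform additive shift
    delta chosen so the residue sums to zero (|sum| < 1e-12 e). Raises
    :class:`SchemeError` when the residue has no side-chain atoms or a
    backbone atom lacks a reference charge.
    """
    side = residue.side_chain_atoms
    if not side:
        raise SchemeError("polar scheme requires at least one side-chain atom")
    atoms = _neutral_backbone(residue)
    backbone_sum = sum(a.partial_charge for a in atoms if a.is_backbone)
    halved_sum = sum(a.partial_charge / 2.0 for a in side)
    delta = -(backbone_sum + halved_sum) / len(side)
    new_atoms = [
        a if a.is_backbone else replace(a, partial_charge=a.partial_charge / 2.0 + delta)
        for a in atoms
    ]
    return replace(residue, atoms=tuple(new_atoms))


def apply_apolar_scheme(residue: ResidueTopology) -> ResidueTopology:
    """Rescale side-chain charges by one common factor to zero the residue.

    The target side-chain sum is minus the neutral-form backbone sum; each
    side-chain charge is multiplied by target/current. When the target is
    zero the side-chain charges are set exactly to zero (limit convention).
    A zero current side-chain sum with a nonzero target is infeasible.
    """
    side = residue.side_chain_atoms
    if not side:
        raise SchemeError("apolar scheme requires at least one side-chain atom")
    atoms = _neutral_backbone(residue)
    backbone_sum = sum(a.partial_charge for a in atoms if a.is_backbone)
    target = -backbone_sum
    current = sum(a.partial_charge for a in side)
    if target == 0.0:
        scale = 0.0
    elif current == 0.0:
        raise SchemeError("side-chain sum is zero but a nonzero target is required")
    else:
        scale = target / current
    new_atoms = [
        a if a.is_backbone else replace(a, partial_charge=a.partial_charge * scale)
        for a in atoms
    ]
    return replace(residue, atoms=tuple(new_atoms))


@dataclass(frozen=True)
class RestraintSpec:
    """Positional restraints and one-sided upper-wall distance restraints.

    ``positional``: tuples (atom_index, reference xyz, k [kcal/mol/A^2]).
    ``upper_walls``: tuples (pair, threshold d0 [A], k [kcal/mol/A^2]); the
    energy is (k/2)(d - d0)^2 for d > d0 and 0 otherwise.
    """

    positional: tuple = ()
    upper_walls: tuple = ()

    def __post_init__(self) -> None:
        for _, _, k in self.positional:
            if k <= 0:
                raise ArgumentError("force constants must be positive")
        for _, d0, k in self.upper_walls:
            if k <= 0 or d0 <= 0:
                raise ArgumentError("thresholds and force constants must be positive")

    # -- interoperability -------------------------------------------------
    def to_plumed(self) -> str:
        """Emit a PLUMED-dialect text block for cross-checking."""
        lines = []
        for i, (idx, ref, k) in enumerate(self.positional):
            x, y, z = ref
            lines.append(
                f"p{i}: POSITION ATOM={idx + 1}\n"
                f"RESTRAINT ARG=p{i}.x,p{i}.y,p{i}.z AT={x:.4f},{y:.4f},{z:.4f} "
                f"KAPPA={k:.3f},{k:.3f},{k:.3f}"
            )
        for i, (pair, d0, k) in enumerate(self.upper_walls):
            a, b = pair
            lines.append(
                f"d{i}: DISTANCE ATOMS={a},{b}\n"
                f"UPPER_WALLS ARG=d{i} AT={d0:.4f} KAPPA={k:.3f}"
            )
        return "\n".join(lines) + ("\n" if lines else "")

    def to_yaml(self) -> str:
        import yaml

        doc = {
            "positional": [
                {"atom_index": int(i), "reference": [float(v) for v in ref], "k": float(k)}
                for i, ref, k in self.positional
            ],
            "upper_walls": [
                {"pair": list(pair), "threshold": float(d0), "k": float(k)}
                for pair, d0, k in self.upper_walls
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RestraintSpec":
        import yaml

        doc = yaml.safe_load(text)
        positional = tuple(
            (entry["atom_index"], tuple(entry["reference"]), entry["k"])
            for entry in doc.get("positional", [])
        )
        upper = tuple(
            (tuple(entry["pair"]), entry["threshold"], entry["k"])
            for entry in doc.get("upper_walls", [])
        )
        return cls(positional=positional, upper_walls=upper)


def build_positional_restraints(
    structure: Sequence[AtomRecord],
    center: Sequence[float],
    radius: float = 7.0,
    k: float = 10.0,
) -> RestraintSpec:
    """Restrain backbone atoms farther than ``radius`` from ``center``.

    Defaults follow the reference-positioning protocol: 10 kcal/mol/A^2 on
    all backbone atoms more than 7 A from the active-site center (the
    catalytic His imidazole centroid), referenced to their current position.
    Side-chain atoms are never restrained.
    """
    if radius <= 0:
        raise ArgumentError("radius must be positive")
    center = np.asarray(center, dtype=float)
    entries = []
    for i, atom in enumerate(structure):
        if not atom.is_backbone:
            continue
        if atom.position is None:
            raise GeometryError(f"atom {atom.atom_name!r} (index {i}) has no position")
        pos = np.asarray(atom.position)
        if np.linalg.norm(pos - center) > radius:
            entries.append((i, tuple(pos), k))
    return RestraintSpec(positional=tuple(entries))


def build_hbond_walls(
    distance_samples: Mapping[tuple, Sequence[float]],
    percentile: float = 0.90,
    k: float = 20.0,
) -> RestraintSpec:
    """One upper wall per atom pair at a percentile of its pooled distances.

    Defaults follow the hydrogen-bond preservation protocol: the wall starts
    at the 90th percentile of the unbiased distance distribution pooled
    across all reaction stages, with k = 20 kcal/mol/A^2. Percentiles use
    linear interpolation between order statistics.
    """
    if not 0 < percentile < 1:
        raise ArgumentError("percentile must lie strictly between 0 and 1")
    walls = []
    for pair, series in distance_samples.items():
        arr = np.asarray(series, dtype=float)
        if arr.size == 0:
            raise DataError(f"empty distance series for pair {pair!r}")
        d0 = float(np.quantile(arr, percentile, method="linear"))
        walls.append((tuple(pair), d0, k))
    return RestraintSpec(upper_walls=tuple(walls))


def wall_energy(d, d0: float, k: float):
    """Upper-wall energy (k/2)(d - d0)^2 beyond d0, zero inside."""
    d = np.asarray(d, dtype=float)
    excess = np.clip(d - d0, 0.0, None)
    return 0.5 * k * excess**2


# --------------------------------------------------------------------------
# tab-separated topology table I/O

_TOPOLOGY_COLUMNS = ["atom_name", "residue_id", "residue_name", "charge", "backbone_flag"]


def write_topology_table(atoms: Sequence[AtomRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "atom_name": a.atom_name,
                "residue_id": a.residue_id,
                "residue_name": a.residue_name,
                "charge": a.partial_charge,
                "backbone_flag": int(a.is_backbone),
            }
            for a in atoms
        ],
        columns=_TOPOLOGY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_topology_table(path) -> list[AtomRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TOPOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"topology table missing columns: {sorted(missing)}")
    return [
        AtomRecord(
            atom_name=str(row.atom_name),
            residue_id=int(row.residue_id),
            residue_name=str(row.residue_name),
            partial_charge=float(row.charge),
            is_backbone=bool(row.backbone_flag),
        )
        for row in df.itertuples()
    ]
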
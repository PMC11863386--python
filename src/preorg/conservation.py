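"""Conserved-charge-location mapping around a catalytic triad.

The bioinformatic stage of the charge-decoupling analysis: a set of related
enzyme structures is rigidly superposed onto a reference using the catalytic
His side chain as the anchor, each charged residue is reduced to a single
charge-proxy atom (Lys NZ / Arg CZ for positive, Asp CG / Glu CD for
negative), proxies are clustered into conserved spatial sites, and a
multiple sequence alignment supplies per-position residue conservation
frequencies (e.g. how often an aspartate occupies a given reference
position across a family).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .charges import BACKBONE_ATOMS, AtomRecord
from .errors import ArgumentError, CorrespondenceError, GeometryError, MappingError

__all__ = [
    "PROXY_ATOMS",
    "HIS_SIDECHAIN_ATOMS",
    "StructureEntry",
    "ChargeProxy",
    "ConservedSite",
    "load_structure",
    "superpose",
    "collect_proxies",
    "cluster_sites",
    "column_conservation",
    "filter_redundant",
]

#: residue -> (proxy atom name, charge sign); a single atom stands in for the
#: spatial location of the residue's formal charge
PROXY_ATOMS = {
    "LYS": ("NZ", "+"),
    "ARG": ("CZ", "+"),
    "ASP": ("CG", "-"),
    "GLU": ("CD", "-"),
}

#: default anchor: the full His side chain (imidazole ring plus CB); which
#: atoms anchor the alignment is configuration, not contract
HIS_SIDECHAIN_ATOMS = ("CB", "CG", "ND1", "CD2", "CE1", "NE2")


@dataclass
class StructureEntry:
    """One structure: atoms with positions plus the triad-anchor atom indices."""

    id: str
    atoms: list
    triad_anchor: list

    def __post_init__(self) -> None:
        for i in self.triad_anchor:
            a = self.atoms[i]
            if a.position is None or not np.all(np.isfinite(a.position)):
                raise GeometryError(
                    f"anchor atom {a.atom_name!r} of {self.id!r} lacks finite coordinates"
                )

    @property
    def anchor_coords(self) -> np.ndarray:
        return np.asarray([self.atoms[i].position for i in self.triad_anchor], dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return np.asarray([a.position for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureEntry":
        new_atoms = [
            replace(a, position=tuple(rotation @ np.asarray(a.position) + translation))
            for a in self.atoms
        ]
        return StructureEntry(id=self.id, atoms=new_atoms, triad_anchor=list(self.triad_anchor))


@dataclass(frozen=True)
class ChargeProxy:
    """Spatial proxy for one charged residue's formal charge."""

    structure_id: str
    residue_id: int
    residue_name: str
    sign: str
    position: tuple
    proxy_atom: str

    def __post_init__(self) -> None:
        expected = {"NZ": "+", "CZ": "+", "CG": "-", "CD": "-"}
        if expected.get(self.proxy_atom) != self.sign:
            raise ArgumentError(
                f"sign {self.sign!r} inconsistent with proxy atom {self.proxy_atom!r}"
            )


@dataclass(frozen=True)
class ConservedSite:
    """A spatial cluster of same-sign charge proxies across structures."""

    centroid: tuple
    sign: str
    member_count: int
    occupancy: float

    def __post_init__(self) -> None:
        if not 0 < self.occupancy <= 1:
            raise ArgumentError("occupancy must lie in (0, 1]")


def load_structure(
    path,
    structure_id: str | None = None,
    anchor_residue_id: int | None = None,
    anchor_atoms: Sequence[str] = HIS_SIDECHAIN_ATOMS,
    model: int = 1,
) -> StructureEntry:
    """Read a PDB file into a :class:`StructureEntry`.

    ``anchor_residue_id`` selects the catalytic His; when omitted, the first
    histidine in the file is used. ``anchor_atoms`` names the side-chain
    atoms (in order) that define the superposition anchor.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=model)
    atoms: list[AtomRecord] = []
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                atom_name=str(arr.atom_name[i]),
                residue_id=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                partial_charge=0.0,
                is_backbone=str(arr.atom_name[i]) in BACKBONE_ATOMS,
                position=tuple(float(v) for v in arr.coord[i]),
            )
        )
    if anchor_residue_id is None:
        his = [a.residue_id for a in atoms if a.residue_name == "HIS"]
        if not his:
            raise ArgumentError(f"no histidine found in {path}")
        anchor_residue_id = his[0]
    index = {
        (a.residue_id, a.atom_name): i
        for i, a in enumerate(atoms)
        if a.residue_id == anchor_residue_id
    }
    try:
        anchor = [index[(anchor_residue_id, name)] for name in anchor_atoms]
    except KeyError as exc:
        raise CorrespondenceError(
            f"anchor atom {exc.args[0][1]!r} missing from residue {anchor_residue_id}"
        ) from exc
    return StructureEntry(
        id=structure_id or str(path), atoms=atoms, triad_anchor=anchor
    )


def superpose(mobile: StructureEntry, reference: StructureEntry):
    """Least-squares rigid superposition of anchor atoms (Kabsch).

    Returns (transformed mobile structure, anchor RMSD in Angstrom). The
    rotation is always proper (det = +1). Anchors must correspond atom by
    atom: equal count, matching atom names in order.
    """
    a = mobile.anchor_coords
    b = reference.anchor_coords
    if a.shape != b.shape:
        raise CorrespondenceError(
            f"anchor atom counts differ: {a.shape[0]} vs {b.shape[0]}"
        )
    names_m = [mobile.atoms[i].atom_name for i in mobile.triad_anchor]
    names_r = [reference.atoms[i].atom_name for i in reference.triad_anchor]
    if names_m != names_r:
        raise CorrespondenceError(f"anchor atom names differ: {names_m} vs {names_r}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    # Kabsch: SVD of the covariance, with the determinant correction that
    # guarantees a proper rotation (det = +1)
    h = (a - cen_a).T @ (b - cen_b)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rmat = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (a - cen_a) @ rmat.T + cen_b
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    translation = cen_b - rmat @ cen_a
    return mobile.transformed(rmat, translation), rmsd


def collect_proxies(
    structures: Sequence[StructureEntry],
    exclusions: Iterable[tuple] = (),
) -> list[ChargeProxy]:
    """One charge proxy per qualifying charged residue, catalytic ones excluded.

    ``exclusions`` holds (structure_id, residue_id) pairs — normally the
    catalytic triad and any other residues whose charge is part of the
    mechanism rather than the surrounding field. Structures are assumed to
    be already superposed into one frame.
    """
    excl = set(exclusions)
    proxies: list[ChargeProxy] = []
    for entry in structures:
        seen: set[int] = set()
        for atom in entry.atoms:
            mapping = PROXY_ATOMS.get(atom.residue_name)
            if mapping is None or atom.residue_id in seen:
                continue
            proxy_name, sign = mapping
            if atom.atom_name != proxy_name:
                continue
            if (entry.id, atom.residue_id) in excl:
                continue
            if atom.position is None:
                raise GeometryError(
                    f"proxy atom {proxy_name!r} of {entry.id}:{atom.residue_id} has no position"
                )
            seen.add(atom.residue_id)
            proxies.append(
                ChargeProxy(
                    structure_id=entry.id,
                    residue_id=atom.residue_id,
                    residue_name=atom.residue_name,
                    sign=sign,
                    position=atom.position,
                    proxy_atom=proxy_name,
                )
            )
    return proxies


def cluster_sites(
    proxies: Sequence[ChargeProxy],
    radius: float = 2.5,
    min_occupancy: float = 0.0,
    n_structures: int | None = None,
    query_point=None,
) -> list[ConservedSite]:
    """Single-linkage radius clustering of charge proxies, per sign.

    Two proxies of the same sign are linked when closer than ``radius``;
    clusters are the connected components of that graph. Each site reports
    its centroid, member count and occupancy (fraction of distinct
    structures contributing). Sites below ``min_occupancy`` are dropped;
    the result is sorted by distance to ``query_point`` when given (e.g.
    the triad centroid), otherwise by descending occupancy.
    """
    if radius <= 0:
        raise ArgumentError("radius must be positive")
    if not proxies:
        return []
    if n_structures is None:
        n_structures = len({p.structure_id for p in proxies})
    sites: list[ConservedSite] = []
    for sign in ("+", "-"):
        group = [p for p in proxies if p.sign == sign]
        if not group:
            continue
        coords = np.asarray([p.position for p in group])
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        adj = coo_matrix(d < radius)
        n_comp, labels = connected_components(adj, directed=False)
        for c in range(n_comp):
            members = np.nonzero(labels == c)[0]
            contributing = {group[i].structure_id for i in members}
            occupancy = len(contributing) / n_structures
            if occupancy < min_occupancy:
                continue
            sites.append(
                ConservedSite(
                    centroid=tuple(coords[members].mean(axis=0)),
                    sign=sign,
                    member_count=int(members.size),
                    occupancy=occupancy,
                )
            )
    if query_point is not None:
        q = np.asarray(query_point, dtype=float)
        sites.sort(key=lambda s: float(np.linalg.norm(np.asarray(s.centroid) - q)))
    else:
        sites.sort(key=lambda s: -s.occupancy)
    return sites


def _read_alignment(alignment):
    from Bio import AlignIO

    if hasattr(alignment, "__iter__") and not isinstance(alignment, (str, bytes)):
        try:
            _ = alignment[0].seq  # already a MultipleSeqAlignment
            return alignment
        except (AttributeError, TypeError):
            pass
    return AlignIO.read(str(alignment), "fasta")


def column_conservation(
    alignment,
    reference_seq_id: str,
    reference_positions: Sequence[int],
    count_gaps: bool = False,
    min_support: int = 2,
) -> pd.DataFrame:
    """Residue frequencies (%) at alignment columns named by reference numbering.

    ``reference_positions`` are 1-based positions in the *ungapped* reference
    sequence; each is mapped gap-aware to its alignment column. Frequencies
    are percentages over non-gap rows of that column (or over all rows when
    ``count_gaps`` is true, with '-' counted as a residue class). Columns
    supported by fewer than ``min_support`` counted rows carry a
    ``low_support`` flag.

    Returns a long-format DataFrame: position, column, residue, percent,
    n_counted, low_support.
    """
    msa = _read_alignment(alignment)
    ref_row = None
    for rec in msa:
        if rec.id == reference_seq_id:
            ref_row = str(rec.seq)
            break
    if ref_row is None:
        raise MappingError(f"reference sequence {reference_seq_id!r} not in alignment")
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_row):
        if ch != "-":
            pos += 1
            pos_to_col[pos] = col
    rows = []
    for p in reference_positions:
        if p not in pos_to_col:
            raise MappingError(
                f"reference position {p} maps to a gap or lies outside the sequence"
            )
        col = pos_to_col[p]
        column = [str(rec.seq)[col] for rec in msa]
        counted = column if count_gaps else [c for c in column if c != "-"]
        n = len(counted)
        low_support = n < min_support
        freqs: dict[str, int] = {}
        for c in counted:
            freqs[c] = freqs.get(c, 0) + 1
        for residue, cnt in sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                {
                    "position": p,
                    "column": col,
                    "residue": residue,
                    "percent": 100.0 * cnt / n,
                    "n_counted": n,
                    "low_support": low_support,
                }
            )
    return pd.DataFrame(rows)


def _pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical non-double-gap columns of two aligned rows."""
    pairs = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


def filter_redundant(alignment, threshold: float = 0.90) -> list[str]:
    """Greedy identity-threshold redundancy filter on aligned sequences.

    Keeps a sequence when its identity to every already-kept sequence is
    below ``threshold``; returns the kept record ids in input order. A
    deliberately simple stand-in for external clustering servers, preserving
    the pipeline stage without network dependence.
    """
    if not 0 < threshold <= 1:
        raise ArgumentError("threshold must lie in (0, 1]")
    msa = _read_alignment(alignment)
    kept: list = []
    for rec in msa:
        seq = str(rec.seq)
        if all(_pairwise_identity(seq, str(k.seq)) < threshold for k in kept):
            kept.append(rec)
    return [rec.id for rec in kept]
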
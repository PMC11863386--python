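"""Map conserved charge locations across a family of toy structures.

Superposes three fake enzyme structures on their catalytic-His side chain,
collects one charge-proxy atom per charged residue, clusters the proxies
into conserved spatial sites, and computes residue conservation percentages
at chosen positions of a toy family alignment.
"""

import numpy as np

from preorg.charges import AtomRecord
from preorg.conservation import (
    StructureEntry,
    cluster_sites,
    collect_proxies,
    column_conservation,
    superpose,
)

rng = np.random.default_rng(3)
his_anchor = rng.normal(size=(6, 3))  # CB, CG, ND1, CD2, CE1, NE2 of the His


def make_structure(structure_id, rotation, shift):
    """A His anchor plus a Lys and an Asp at conserved relative positions."""
    anchor = his_anchor @ rotation.T + shift
    lys = np.array([6.0, 1.0, 0.0]) @ rotation.T + shift + rng.normal(0, 0.3, 3)
    asp = np.array([-4.0, 3.0, 1.0]) @ rotation.T + shift + rng.normal(0, 0.3, 3)
    names = ["CB", "CG", "ND1", "CD2", "CE1", "NE2"]
    atoms = [AtomRecord(n, 64, "HIS", position=tuple(c)) for n, c in zip(names, anchor)]
    atoms.append(AtomRecord("NZ", 94, "LYS", position=tuple(lys)))
    atoms.append(AtomRecord("CG", 60, "ASP", position=tuple(asp)))
    return StructureEntry(id=structure_id, atoms=atoms, triad_anchor=[0, 1, 2, 3, 4, 5])


from scipy.spatial.transform import Rotation

reference = make_structure("ref", np.eye(3), np.zeros(3))
aligned = [reference]
for i in range(1, 3):
    rot = Rotation.random(random_state=i).as_matrix()
    mobile = make_structure(f"s{i}", rot, np.array([10.0 * i, -5.0, 2.0]))
    moved, rmsd = superpose(mobile, reference)
    print(f"{mobile.id}: anchor RMSD after superposition = {rmsd:.3f} A")
    aligned.append(moved)

proxies = collect_proxies(aligned)
sites = cluster_sites(proxies, radius=2.5, n_structures=len(aligned))
for site in sites:
    print(f"conserved {site.sign} site at {np.round(site.centroid, 1)}, "
          f"{site.member_count} members, occupancy {site.occupancy:.0%}")
# every structure contributes one positive (Lys NZ) and one negative
# (Asp CG) proxy at conserved locations -> two 100%-occupancy sites

import tempfile, pathlib

alignment = ">ref\nMKD-AT\n" + "".join(f">s{i}\nMKDGAT\n" for i in range(7)) \
    + ">s8\nMKEGAT\n>s9\nMKEG-T\n"
with tempfile.TemporaryDirectory() as tmp:
    path = pathlib.Path(tmp) / "family.fasta"
    path.write_text(alignment)
    table = column_conservation(path, "ref", [3])
print(table[["position", "residue", "percent", "n_counted"]].to_string(index=False))
# position 3 of the reference maps gap-aware to its alignment column;
# an aspartate occupies it in 80% of the family members
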
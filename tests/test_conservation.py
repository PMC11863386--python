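"""Superposition, charge proxies, site clustering and alignment conservation."""

import textwrap

import numpy as np
import pytest

from preorg.charges import AtomRecord
from preorg.conservation import (
    ChargeProxy,
    StructureEntry,
    cluster_sites,
    collect_proxies,
    column_conservation,
    filter_redundant,
    load_structure,
    superpose,
)
from preorg.errors import ArgumentError, CorrespondenceError, MappingError


def make_entry(coords, entry_id="s", names=None, residue_name="HIS", residue_id=64):
    names = names or [f"A{i}" for i in range(len(coords))]
    atoms = [
        AtomRecord(atom_name=n, residue_id=residue_id, residue_name=residue_name,
                   position=tuple(map(float, c)))
        for n, c in zip(names, coords)
    ]
    return StructureEntry(id=entry_id, atoms=atoms, triad_anchor=list(range(len(coords))))


def _quaternion_superpose(mobile, reference):
    """Independent oracle: Horn's closed-form quaternion superposition."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(k)
    q = v[:, -1]
    qw, qx, qy, qz = q
    rot = np.array(
        [
            [1 - 2 * (qy**2 + qz**2), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
            [2 * (qx * qy + qz * qw), 1 - 2 * (qx**2 + qz**2), 2 * (qy * qz - qx * qw)],
            [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx**2 + qy**2)],
        ]
    )
    rmsd = np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, axis=1)))
    return rot, rmsd


class TestSuperpose:
    def test_self_superposition_identity(self, rng):
        entry = make_entry(rng.normal(size=(6, 3)))
        moved, rmsd = superpose(entry, entry)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(moved.coords, entry.coords, atol=1e-12)

    def test_known_rigid_motion_recovered(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(size=(6, 3))
        ref = make_entry(coords, "ref")
        rot = Rotation.random(random_state=7).as_matrix()
        mob = make_entry(coords @ rot.T + np.array([1.0, -2.0, 3.0]), "mob")
        moved, rmsd = superpose(mob, ref)
        assert rmsd < 1e-8
        assert np.allclose(moved.coords, ref.coords, atol=1e-7)

    def test_noisy_copy_matches_quaternion_oracle(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(size=(10, 3)) * 3
        noisy = coords + rng.normal(0, 0.1, size=coords.shape)
        rot = Rotation.random(random_state=1).as_matrix()
        ref = make_entry(coords, "ref")
        mob = make_entry(noisy @ rot.T + 5.0, "mob")
        _, rmsd = superpose(mob, ref)
        _, rmsd_oracle = _quaternion_superpose(
            np.asarray(mob.anchor_coords), np.asarray(ref.anchor_coords)
        )
        assert rmsd == pytest.approx(rmsd_oracle, rel=1e-6)

    def test_rmsd_invariant_under_global_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(size=(8, 3))
        noisy = coords + rng.normal(0, 0.2, size=coords.shape)
        _, rmsd0 = superpose(make_entry(noisy), make_entry(coords))
        rot = Rotation.random(random_state=3).as_matrix()
        shift = np.array([4.0, 4.0, -1.0])
        _, rmsd1 = superpose(
            make_entry(noisy @ rot.T + shift), make_entry(coords @ rot.T + shift)
        )
        assert rmsd0 == pytest.approx(rmsd1, rel=1e-9)

    def test_anchor_mismatch(self, rng):
        a = make_entry(rng.normal(size=(5, 3)))
        b = make_entry(rng.normal(size=(6, 3)))
        with pytest.raises(CorrespondenceError):
            superpose(a, b)


def _charged_structure(entry_id, offset=0.0):
    atoms = [
        AtomRecord("NZ", 10, "LYS", position=(1.0 + offset, 0.0, 0.0)),
        AtomRecord("CB", 10, "LYS", position=(1.5, 0.0, 0.0)),
        AtomRecord("CG", 20, "ASP", position=(5.0 + offset, 5.0, 0.0)),
        AtomRecord("CD", 30, "GLU", position=(5.2 + offset, 5.1, 0.0)),
        AtomRecord("CG", 40, "ASP", position=(-9.0, 0.0, 0.0)),  # catalytic
        AtomRecord("NE2", 64, "HIS", position=(0.0, 0.0, 0.0)),
    ]
    return StructureEntry(id=entry_id, atoms=atoms, triad_anchor=[5])


class TestProxies:
    def test_one_proxy_per_charged_residue_with_signs(self):
        proxies = collect_proxies([_charged_structure("a")])
        by_res = {p.residue_id: p for p in proxies}
        assert set(by_res) == {10, 20, 30, 40}
        assert by_res[10].sign == "+" and by_res[10].proxy_atom == "NZ"
        assert by_res[20].sign == "-" and by_res[20].proxy_atom == "CG"
        assert by_res[30].sign == "-" and by_res[30].proxy_atom == "CD"

    def test_catalytic_exclusion(self):
        proxies = collect_proxies([_charged_structure("a")], exclusions=[("a", 40)])
        assert all(p.residue_id != 40 for p in proxies)

    def test_sign_consistency_enforced(self):
        with pytest.raises(ArgumentError):
            ChargeProxy("s", 1, "LYS", "-", (0, 0, 0), "NZ")


class TestClusterSites:
    def test_tight_group_single_site(self, rng):
        proxies = [
            ChargeProxy(f"s{i}", 1, "LYS", "+",
                        tuple(rng.normal(0, 0.3, 3)), "NZ")
            for i in range(10)
        ]
        sites = cluster_sites(proxies, radius=2.5)
        assert len(sites) == 1
        assert sites[0].member_count == 10
        assert sites[0].occupancy == 1.0

    def test_distant_groups_two_sites(self, rng):
        proxies = [
            ChargeProxy(f"s{i}", 1, "ASP", "-", (float(i % 2) * 20.0, 0.0, 0.0), "CG")
            for i in range(6)
        ]
        sites = cluster_sites(proxies, radius=2.5)
        assert len(sites) == 2

    def test_matches_graph_component_oracle(self, rng):
        import networkx as nx

        pts = rng.uniform(0, 10, size=(40, 3))
        proxies = [
            ChargeProxy(f"s{i}", 1, "LYS", "+", tuple(p), "NZ")
            for i, p in enumerate(pts)
        ]
        radius = 2.0
        sites = cluster_sites(proxies, radius=radius)
        g = nx.Graph()
        g.add_nodes_from(range(len(pts)))
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm(pts[i] - pts[j]) < radius:
                    g.add_edge(i, j)
        expected = sorted(len(c) for c in nx.connected_components(g))
        assert sorted(s.member_count for s in sites) == expected

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(0, 5, size=(15, 3))
        proxies = [
            ChargeProxy(f"s{i}", 1, "LYS", "+", tuple(p), "NZ")
            for i, p in enumerate(pts)
        ]
        a = cluster_sites(proxies, radius=1.5)
        b = cluster_sites(list(reversed(proxies)), radius=1.5)
        assert sorted(s.member_count for s in a) == sorted(s.member_count for s in b)
        ca = sorted(tuple(np.round(s.centroid, 9)) for s in a)
        cb = sorted(tuple(np.round(s.centroid, 9)) for s in b)
        assert ca == cb

    def test_empty_input(self):
        assert cluster_sites([], radius=1.0) == []


TOY_ALIGNMENT = textwrap.dedent(
    """\
    >ref
    MKD-AT
    >s1
    MKDGAT
    >s2
    MKDGAT
    >s3
    MKDGAT
    >s4
    MKDGAT
    >s5
    MKDGAT
    >s6
    MKDGAT
    >s7
    MKDGAT
    >s8
    MKEGAT
    >s9
    MKEG-T
    """
)


@pytest.fixture
def toy_alignment(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(TOY_ALIGNMENT)
    return path


class TestColumnConservation:
    def test_forced_percentages(self, toy_alignment):
        # column 3 of the alignment (position 3 of ref): 8 D of 10 -> 80%
        table = column_conservation(toy_alignment, "ref", [3])
        d_row = table[table["residue"] == "D"].iloc[0]
        assert d_row["percent"] == pytest.approx(80.0)
        e_row = table[table["residue"] == "E"].iloc[0]
        assert e_row["percent"] == pytest.approx(20.0)

    def test_frequencies_sum_to_100(self, toy_alignment):
        table = column_conservation(toy_alignment, "ref", [1, 2, 3, 4, 5])
        for _, block in table.groupby("position"):
            assert block["percent"].sum() == pytest.approx(100.0)

    def test_gap_aware_mapping(self, toy_alignment):
        # reference position 4 is 'A', which sits in alignment column 4
        table = column_conservation(toy_alignment, "ref", [4])
        assert set(table["column"]) == {4}
        top = table.iloc[0]
        assert top["residue"] == "A" and top["percent"] == pytest.approx(100.0)

    def test_mostly_gap_column_low_support(self, tmp_path):
        path = tmp_path / "gap.fasta"
        path.write_text(">ref\nAD\n>s1\nA-\n>s2\nA-\n")
        table = column_conservation(path, "ref", [2])
        row = table.iloc[0]
        assert row["percent"] == pytest.approx(100.0)
        assert row["n_counted"] == 1
        assert bool(row["low_support"])

    def test_order_invariance(self, tmp_path, toy_alignment):
        records = TOY_ALIGNMENT.strip().split("\n")
        pairs = [(records[i], records[i + 1]) for i in range(0, len(records), 2)]
        reordered = [pairs[0]] + pairs[1:][::-1]
        path = tmp_path / "reordered.fasta"
        path.write_text("\n".join("\n".join(p) for p in reordered) + "\n")
        a = column_conservation(toy_alignment, "ref", [3]).set_index("residue")["percent"]
        b = column_conservation(path, "ref", [3]).set_index("residue")["percent"]
        assert a.to_dict() == b.to_dict()

    def test_missing_reference_and_gap_position(self, toy_alignment):
        with pytest.raises(MappingError):
            column_conservation(toy_alignment, "nope", [1])
        with pytest.raises(MappingError):
            column_conservation(toy_alignment, "ref", [99])


def test_filter_redundant_greedy(tmp_path):
    path = tmp_path / "red.fasta"
    path.write_text(">a\nAAAAAAAAAA\n>b\nAAAAAAAAAC\n>c\nCCCCCCCCCC\n")
    kept = filter_redundant(path, threshold=0.85)
    assert kept == ["a", "c"]
    assert filter_redundant(path, threshold=1.0) == ["a", "b", "c"]


PDB_TEXT = """\
ATOM      1  N   HIS A  64      11.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  HIS A  64      12.000  10.000  10.000  1.00  0.00           C
ATOM      3  CB  HIS A  64      12.500  11.000  10.000  1.00  0.00           C
ATOM      4  CG  HIS A  64      13.000  12.000  10.000  1.00  0.00           C
ATOM      5  ND1 HIS A  64      14.000  12.200  10.000  1.00  0.00           N
ATOM      6  CD2 HIS A  64      12.500  13.100  10.000  1.00  0.00           C
ATOM      7  CE1 HIS A  64      14.200  13.500  10.000  1.00  0.00           C
ATOM      8  NE2 HIS A  64      13.300  14.000  10.000  1.00  0.00           N
ATOM      9  NZ  LYS A  94      18.000  14.000  10.000  1.00  0.00           N
ATOM     10  CG  ASP A  60       8.000  14.000  12.000  1.00  0.00           C
END
"""


def test_load_structure_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(PDB_TEXT)
    entry = load_structure(path, "toy")
    assert len(entry.atoms) == 10
    anchor_names = [entry.atoms[i].atom_name for i in entry.triad_anchor]
    assert anchor_names == ["CB", "CG", "ND1", "CD2", "CE1", "NE2"]
    moved, rmsd = superpose(entry, entry)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    proxies = collect_proxies([entry])
    assert {(p.residue_name, p.sign) for p in proxies} == {("LYS", "+"), ("ASP", "-")}
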
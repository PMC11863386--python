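"""Shared fixtures: small residues, structures and alignments built in memory."""

import numpy as np
import pytest

from preorg.charges import AtomRecord, ResidueTopology


def make_residue(
    backbone_charges,
    side_charges,
    neutral_backbone=None,
    residue_name="ASP",
    residue_id=60,
):
    """Residue topology from plain charge lists (backbone first)."""
    backbone_names = ["N", "H", "CA", "HA", "C", "O"][: len(backbone_charges)]
    atoms = [
        AtomRecord(atom_name=n, residue_id=residue_id, residue_name=residue_name,
                   partial_charge=q, is_backbone=True)
        for n, q in zip(backbone_names, backbone_charges)
    ]
    atoms += [
        AtomRecord(atom_name=f"S{i}", residue_id=residue_id, residue_name=residue_name,
                   partial_charge=q, is_backbone=False)
        for i, q in enumerate(side_charges)
    ]
    if neutral_backbone is None:
        neutral_backbone = {n: q for n, q in zip(backbone_names, backbone_charges)}
    return ResidueTopology(atoms=tuple(atoms), neutral_form_backbone_charges=neutral_backbone)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_residue(rng, n_backbone=None, n_side=None):
    """Randomized residue with a random neutral-form backbone reference."""
    n_b = n_backbone or int(rng.integers(1, 7))
    n_s = n_side or int(rng.integers(1, 9))
    backbone = rng.uniform(-0.8, 0.8, n_b).tolist()
    side = rng.uniform(-0.9, 0.9, n_s).tolist()
    names = ["N", "H", "CA", "HA", "C", "O"][:n_b]
    neutral = {n: float(rng.uniform(-0.6, 0.6)) for n in names}
    return make_residue(backbone, side, neutral_backbone=neutral)
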
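"""Neutralize a charged residue's net charge while preserving its polarity.

Builds a small aspartate-like topology, applies both neutralization schemes
and builds the restraints that keep the perturbed system in its reference
configuration, printing the resulting charges and restraint thresholds.
"""

import numpy as np

from preorg.charges import (
    AtomRecord,
    ResidueTopology,
    apply_apolar_scheme,
    apply_polar_scheme,
    build_hbond_walls,
    build_positional_restraints,
)

# a toy carboxylate side chain on a standard backbone (charges illustrative)
backbone = {"N": -0.35, "H": 0.25, "CA": 0.05, "C": 0.55, "O": -0.45}
side = {"CB": -0.03, "HB1": 0.05, "HB2": 0.05, "CG": 0.80, "OD1": -0.80, "OD2": -0.80}
atoms = [
    AtomRecord(name, 60, "ASP", q, is_backbone=True) for name, q in backbone.items()
] + [
    AtomRecord(name, 60, "ASP", q, is_backbone=False) for name, q in side.items()
]
residue = ResidueTopology(atoms=tuple(atoms), neutral_form_backbone_charges=backbone)
print(f"original residue net charge: {residue.net_charge:+.3f} e")

for label, scheme in (("polar (halve+shift)", apply_polar_scheme),
                      ("apolar (rescale)", apply_apolar_scheme)):
    out = scheme(residue)
    charges = ", ".join(f"{a.atom_name}:{a.partial_charge:+.3f}" for a in out.side_chain_atoms)
    print(f"{label}: net {out.net_charge:+.1e} e | side chain {charges}")
# both schemes remove the net charge exactly; the polar one keeps the
# carboxylate dipolar, the apolar one nearly zeroes the side chain

# restraints that pin the perturbed residue's interactions to the reference
rng = np.random.default_rng(0)
samples = {("OD1", "H-donor1"): rng.normal(2.9, 0.15, 500),
           ("OD2", "H-donor2"): rng.normal(3.1, 0.20, 500)}
walls = build_hbond_walls(samples, percentile=0.90, k=20.0)
for pair, d0, k in walls.upper_walls:
    print(f"upper wall {pair[0]}-{pair[1]}: starts at {d0:.2f} A (90th pct), k = {k} kcal/mol/A^2")
print(walls.to_plumed().rstrip())
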
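"""Measure the barrier shift caused by a spectator charge.

The desk-scale analogue of asking what a conserved outer-shell charge does
to a reaction barrier: a charge q couples to the double well through a
localized function peaked at the transition state, shifting the barrier by
~q without touching the wells. Biased runs with and without the charge are
reweighted, the RS->TS free energies are differenced, and the recovered
shift is compared with the quadrature truth.

(Reduced-budget demonstration: 2 replicates per system; the full protocol in
the test suite uses 5.)
"""

import numpy as np

from preorg.fes import delta_delta_g, detect_burn_in, extract_state_energies, reweighted_fes
from preorg.opes import HarmonicWalls, OPESConfig, run_opes
from preorg.surrogate import QuarticDoubleWell, exact_fes

GRID = np.linspace(-1.6, 1.6, 200)
WINDOWS = {"RS": (-1.5, -0.45), "TS2": (-0.45, 0.45)}


def measure(charge, seeds):
    pot = QuarticDoubleWell(barrier=10.0, charge=charge, coupling_width=0.3)
    cfg = OPESConfig(barrier=40.0, n_steps=100_000, n_walkers=8)
    reps = []
    for seed in seeds:
        run = run_opes(pot, cfg, walls=HarmonicWalls(-1.6, 1.6, 20.0), seed=seed, x0=-1.0)
        reps.append(run.flat(detect_burn_in(run.rct)))
    estimate = extract_state_energies(reweighted_fes(reps, GRID, 1.0), WINDOWS)
    truth = extract_state_energies(exact_fes(pot, GRID), WINDOWS)
    return estimate, truth


est0, true0 = measure(0.0, seeds=[101, 102])
for q in (+2.3, -0.8):
    estq, trueq = measure(q, seeds=[201, 202] if q > 0 else [301, 302])
    ddg, sem = delta_delta_g(estq, est0)["RS→TS2"]
    ddg_true = trueq["RS→TS2"][0] - true0["RS→TS2"][0]
    print(f"charge q = {q:+.1f}: recovered ddG(RS->TS) = {ddg:+.2f} +/- {sem:.2f} kT "
          f"(quadrature truth {ddg_true:+.2f} kT)")
# a positive spectator charge near the TS raises the barrier, a negative one
# lowers it; with only 2 replicates the SEM is itself poorly estimated —
# the 5-replicate protocol in the test suite recovers both shifts within
# 2 pooled SEM of the quadrature truth
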
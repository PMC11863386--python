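# preorg

Tools for decoupling the **net-charge (electrostatic field) effect** of
conserved outer-shell residues in enzyme active sites from their **local
interaction** effects — the question behind electrostatic preorganization:
does a conserved charge near a catalytic site speed the reaction because of
its charge, or because of the contacts it makes?

The experimental answer is hard (any substitution changes both), so the
pipeline is computational: rescale a residue's partial charges to remove its
net charge while restraining its positioning and hydrogen bonds, then
measure the change in the reaction's free-energy barriers with
machine-learned collective variables and adaptive-bias enhanced sampling.
This package implements that pipeline at desk scale, replacing the
cluster-scale QM/MM engine with a **surrogate reactive system** — analytic
multi-basin potentials with exactly computable free-energy surfaces — so
every stage is verifiable against closed-form or quadrature oracles.

## What's inside

| module | role |
|---|---|
| `preorg.charges` | charge-neutralization schemes (polar: halve + uniform shift; apolar: common rescale), positional restraints beyond a cutoff radius, percentile hydrogen-bond upper walls |
| `preorg.features` | switch-normalized pairwise-distance features, s(r) = (1−(r/r₀)ⁿ)/(1−(r/r₀)ᵐ), and 0.5%/99.5%-percentile training-hull walls |
| `preorg.tda` | discriminant CV: an MLP trained so each state's CV distribution matches a Gaussian target — L = Σ_c (μ_c−μ̃_c)² + α(σ_c−σ̃_c)², targets (−10, 0, 10) / (0.4, 0.3, 0.4) |
| `preorg.opes` | on-the-fly adaptive-bias sampler along the CV: kernel estimate of the sampled distribution, well-tempered target with γ = barrier/kT, multi-walker sharing, kernel-width floor, c(t) reweighting offset |
| `preorg.fes` | reweighted free-energy profiles with replicate SEM, RS→TS/INT/PS energetics tables, ΔΔG with pooled SEM, TS-degeneracy audit on a reweighted 2-D surface |
| `preorg.surrogate` | the synthetic system: state-labeled feature ensembles, Langevin (BAOAB) propagator, quadrature ground truth, spectator-charge coupling q·φ(x) |
| `preorg.conservation` | triad-anchored Kabsch superposition, charge-proxy atoms (Lys NZ, Arg CZ, Asp CG, Glu CD), radius clustering of conserved sites, alignment-column conservation |

The package is a library: the importable API plus the narrative scripts in
`examples/` (one per capability) are the interface.

## Worked example

`examples/double_well_sampling.py` runs the sampler on a 10 kT quartic
double well (8 walkers × 10⁵ steps, barrier parameter 40 kT) and verifies
the reweighted profile against quadrature:

```
recrossings of the 10 kT barrier: 548
burn-in: first 199 of 100000 frames discarded (c(t) stabilization)
reweighted vs quadrature FES RMSE (bins < 8 kT): 0.085 kT
estimated barrier RS->TS: 10.02 kT (true 10.00)
```

An unbiased run of this length essentially never crosses 10 kT; the shared
adaptive bias flattens the landscape (548 recrossings) and reweighting
recovers the profile to better than 0.1 kT.

`examples/spectator_charge_shift.py` adds a charge q coupled through a
Gaussian φ(x) peaked at the transition state — the surrogate analogue of
neutralizing a conserved outer-shell charge — and recovers the imposed
barrier shifts (+2.3 and −0.8 reduced units) by differencing reweighted
RS→TS free energies against the quadrature truth.

The other examples cover charge neutralization with restraint emission
(`charge_neutralization.py`), discriminant-CV training
(`train_discriminant_cv.py`), and conserved-charge mapping with alignment
conservation (`conservation_mapping.py`).

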
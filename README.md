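# dropletmd

Residue-level coarse-grained molecular dynamics for biomolecular
condensates — liquid–liquid phase-separated protein droplets, optionally
with DNA — with the spatial machinery that makes highly *inhomogeneous*
systems tractable: a unified multi-cutoff neighbor-list scheme and a
cell-based kd-tree domain decomposition with dynamic load balancing.

It is aimed at method developers and students who want a compact, fully
tested reference for how a condensate-capable CG engine fits together:
every energy term has analytic forces checked against numeric gradients,
every spatial data structure is verified against brute force, and the
domain decomposition is validated through energy identities rather than
wall-clock claims.

## Models

* **Disordered proteins** (one bead per residue): harmonic bonds
  E_b = k_b(b − b₀)² with k_b = 2.39 kcal/mol/Å², b₀ = 3.8 Å, and the
  hydropathy-scale pair potential — E_LJ(r) + (1 − λ_ij)ε for
  r ≤ 2^{1/6}σ_ij, λ_ij E_LJ(r) beyond — with ε = 0.2 kcal/mol.
* **Folded domains**: statistical angle/dihedral potentials, a 12–10
  native-contact term ε_Gō[5(σ/r)¹² − 6(σ/r)¹⁰] (contacts at heavy-atom
  distance < 4.5 Å), and shifted r⁻¹² excluded volume.
* **dsDNA** (phosphate/sugar/base sites, 3n − 1 per strand): quartic
  bonds, harmonic angles, periodic + Gaussian dihedrals, and Morse-based
  stacking/pairing/cross-stacking gated by bell-shaped angular modulations.
* **Electrostatics**: Debye–Hückel with ε_r(T, C) = e(T)·a(C) — 74.911 at
  300 K, 150 mM — and λ_D = sqrt(k_B T ε₀ ε_r / 2 N_A e² I).
* **Protein–DNA recognition**: Gaussian distance well × three angular
  gates per (base, binding-Cα, PWM column), depths supplied as a table.
* **Dynamics**: Langevin BAOAB, Δt = 10 fs, γ = 0.01 ps⁻¹ defaults.
* **Analysis**: chain-level DBSCAN (contact or center-of-mass
  neighborhoods), droplet count n_d and sizes s_d, the mixing coordinate
  m = sqrt(D₁₁D₂₂)/D₁₂ and shape coordinate η (3 = sphere).

Per-residue σ/λ tables and the statistical angle tables are inputs;
`dropletmd.synthetic` generates seeded, physically plausible stand-ins so
everything runs out of the box.  See `docs/methods.md` for the full model
account.

## Worked example: two droplets fusing

```python
import numpy as np
from dropletmd.synthetic import GeneratorSpec, gen_test_parameters, \
    gen_two_droplet_system
from dropletmd.topology import build_protein_topology, \
    identity_placements, replicate_system
from dropletmd.dynamics import Schedule, initial_state, minimize, \
    run_simulation
from dropletmd import analysis

params = gen_test_parameters(seed=1)
for r in params.hps.lam:        # uniformly sticky 10-mer chains
    params.hps.lam[r] = 1.0
for r in params.hps.sigma:
    params.hps.sigma[r] = 6.0

spec = GeneratorSpec(seed=1, n_chains=40, chain_length=10, radius=30.0,
                     gap=6.0, box=(120.0, 120.0, 160.0), min_sep=4.0)
coords, labels = gen_two_droplet_system(spec)

chain = build_protein_topology("G" * 10, [((1, 10), "HPS")], params)
top = replicate_system(chain, 40, identity_placements(40))
state = initial_state(top, coords, np.array(spec.box),
                      temperature=150.0, seed=1)
minimize(top, state, params)
result = run_simulation(top, state, params,
                        Schedule(steps=200_000, temperature=150.0,
                                 output_stride=2000))

box = np.array(spec.box)
chains = top.chains()
for frame, step in zip(result.frames[::25], result.frame_steps[::25]):
    m = analysis.mixing_metrics(frame, chains, labels, box).m
    print(f"step {step:>7d}  m = {m:.2f}")
```

Output from this exact script:

```
step       0  m = 0.50
step   50000  m = 0.76
step  100000  m = 0.87
step  150000  m = 0.95
step  200000  m = 0.96
```

The mixing coordinate m compares intra- to inter-droplet mean chain
distances: ~0.5 for two separate droplets in contact range, rising toward
1.0 as the droplets merge and their chains interdiffuse — the signature of
liquid-like fusion.  Clustering the final frame with the contact-metric
DBSCAN finds a single droplet where the initial frame had two.

The same machinery is scriptable from the shell:

```bash
dropletmd build two-droplet --out sys --seed 1
dropletmd run --config sys.toml --coords sys.pdb --out traj
dropletmd partition --coords sys.pdb --n-subdomains 8
dropletmd analyze --trajectory traj.xyz --out metrics.tsv
```

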
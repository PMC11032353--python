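# Methods

`dropletmd` is a residue-level coarse-grained (CG) molecular dynamics engine
for biomolecular condensates, built around three ingredients: (i) CG force
fields for disordered proteins (a hydropathy-scale model), folded domains
(a structure-based Gō-type model) and double-stranded DNA (a
three-site-per-nucleotide model), with Debye–Hückel electrostatics and an
optional sequence-specific protein–DNA recognition term; (ii) a unified
multi-cutoff neighbor-list scheme on a periodic cell grid; and (iii) a
cell-based kd-tree domain decomposition with dynamic load balancing,
emulated in-process and verified against serial results.  This note records
the models, the numerical choices, and what the synthetic test systems do
and do not demonstrate.

## Units and constants

Internal units are Å, kcal/mol, Da, fs, elementary charges and kelvin.
k_B = 0.0019872041 kcal/mol/K; the Coulomb factor is 332.0716
kcal·Å/(mol·e²); 1 kcal/mol = 4.184×10⁻⁴ Da·Å²/fs².

## Force field

**Disordered protein regions (hydropathy-scale model).**  One bead per
residue.  Bonds are harmonic, E_b = k_b (b − b₀)² with k_b = 2.39
kcal/mol/Å² and b₀ = 3.8 Å.  Nonbonded pairs interact through an
Ashbaugh–Hatch-style λ-weighted Lennard–Jones potential: below the LJ
minimum 2^{1/6}σ the energy is E_LJ + (1 − λ)ε, beyond it λ·E_LJ, with
ε = 0.2 kcal/mol and arithmetic combination of the per-residue σ_i and
hydropathies λ_i.  The per-residue tables are model inputs (the values used
in publications come from their own parameterizations); the synthetic
generator draws physically plausible tables, σ ∈ [4, 7] Å, λ ∈ [0, 1].

**Folded regions (structure-based model).**  Bonds are stiff harmonic;
local flexibility uses statistical potentials: −k_B T ln(P_θ(θ|r)/sin θ)
for angles and −k_B T ln P_d(φ|r) for dihedrals, with a Gaussian well on
the 1–3 distance and a Gaussian dihedral well.  Native contacts (residue
pairs with any heavy-atom pair within 4.5 Å in a reference structure,
sequence separation ≥ 3) get a 12–10 potential
ε_Gō[5(σ/r)¹² − 6(σ/r)¹⁰]; non-native pairs a repulsive excluded volume
ε_exv(σ/r)¹² − (1/2)¹²ε_exv, zero beyond 2σ, with ε_exv = 0.6 kcal/mol.
The repulsive sign follows from the shift construction (the potential must
vanish at its 2σ cutoff from above).

**Electrostatics.**  Charged pairs (D/E = −1, K/R = +1, H = 0 by default;
DNA phosphates −1; all configurable) interact through the Debye–Hückel
potential q_i q_j e^{−r/λ_D}/(4πε₀ε_r r).  The solution permittivity is
ε_r = e(T)·a(C) with e(T) = 249.4 − 0.788 T + 7.20×10⁻⁴ T² and
a(C) = 1 − 0.2551 C + 5.151×10⁻² C² − 6.889×10⁻³ C³ (T in K, C in mol/L);
at 300 K and 0.15 M this gives 74.911.  The screening length is
λ_D = sqrt(k_B T ε₀ ε_r / 2 N_A e² I) with the ionic strength I defaulting
to C (1:1 salt).

**DNA (three sites per nucleotide).**  Phosphate–sugar–base sites, with the
5′-terminal phosphate of each strand omitted, so an n-nt strand has 3n − 1
sites (a 200-bp duplex has 1198).  Bonds are quadratic + quartic; angles
harmonic; every bonded 4-path carries a periodic dihedral and backbone
(P/S-only) paths an additional Gaussian well.  Base stacking, base pairing
and cross-stacking use a repulsive/attractive split of the Morse potential
(the full Morse restricted to r < r₀ plus its flat/attractive complement)
gated by the bell-shaped angular modulation f(Δθ): 1 inside γ,
1 − cos²(πΔθ/2γ) between γ and 2γ, 0 beyond.  Pairing additionally carries
the ½(1 + cos Δφ) dihedral gate on the attraction only (the repulsive core
is ungated).  DNA excluded volume is ε[(σ/r)¹² − 2(σ/r)⁶] + ε below σ.

The geometry conventions for the multi-body terms are: stacking distance
between consecutive intra-strand bases, modulated by the sugar–base–base
angle; pairing distance between complementary bases, modulated by the two
sugar–base–base angles and the sugar–base–base–sugar dihedral;
cross-stacking between a base and the diagonal neighbor of its partner,
modulated by the two flanking angles.  Reference distances, angles and
dihedrals are *measured on a generated idealized helix* (rise 3.38 Å,
twist 36°, 154° glycosidic opening), which therefore sits exactly at the
minimum of every local and base-interaction term — a convenient, verifiable
convention given that published parameter tables are not part of this
package.  Morse depths/widths and modulation half-widths come from the
parameter set (synthetic defaults: stack 3.5, A·T 4.0, G·C 5.0, cross 0.8
kcal/mol; γ ≈ 18°).

**Protein–DNA recognition.**  Each recognition term couples one base to one
DNA-binding Cα through a Gaussian in the base–Cα distance times three
angular gates f(Δθ₁)f(Δθ₂)f(Δθ₃): θ₁ is the sugar–base–Cα angle, θ₂ the
angle between the 5′→3′ neighbor-base axis and the base→Cα vector, θ₃ the
angle between the Cα chain axis (prev→next) and the base→Cα vector.  The
Gaussian depth ε_G is an input per (base letter, PWM column) — how a PWM
maps onto depths is the caller's choice.  Complementary-base partner terms
are generated as additional site entries.  This pair class is bookkept
without i < j symmetrization because base and Cα play asymmetric roles.

**Cross-model pairs.**  HPS covers protein pairs with at least one
disordered partner; folded–folded pairs (outside the native-contact list)
and protein–DNA pairs use the aicg excluded-volume form; DNA–DNA pairs the
DNA form.  The published models do not print a cross-combination rule; this
routing keeps disordered-region thermodynamics identical to the pure HPS
model while every other pair remains at minimum sterically protected.

## Neighbor lists and cell grid

Cutoffs are per interaction class, ascending: r_c,exv ≤ r_c,dna ≤ r_c,hps ≤
r_c,ele (defaults 12, 18, 20, 35 Å).  Generation thresholds are r_p = r_c +
r_buffer with r_buffer = 3 Å.  The cell edge is at least r_p,ele/2 (cell
count per axis = ⌊box/(r_p,ele/2)⌋), and the candidate search spans
⌈r_p/edge⌉ cell shells per class — one sweep at the longest range feeds all
classes.  A pair within r_p,exv enters the exv, dna and hps lists; between
r_p,exv and r_p,dna the dna and hps lists; beyond that only hps.  The
electrostatic list is built separately over charged particles.  Bonded 1–2
and 1–3 pairs are excluded from every class (1–4 included); pairs carried
by dedicated terms (native contacts, stacking/pairing/cross partners) are
excluded from the exv, dna and hps lists, which keeps the class-nesting
property exv ⊆ dna ⊆ hps intact.  The search is skipped until some particle
has moved r_buffer/2 since the last build; under that rule no pair can
enter any cutoff unseen, which the tests verify against O(N²) scans.

## Domain decomposition

The cell grid is bisected recursively at cell boundaries so the two sides
carry nearly equal particle counts; on a given axis the split index
minimizes |W_left − (⌈n/2⌉/n)·W|, and the axis is chosen by recursive
lookahead — the axis whose balanced split leads to the smallest final
maximum subdomain load (ties x→y→z).  The result matches an exhaustive
enumeration of all axis-aligned recursive bisections on small grids (the
test oracle).  Non-power-of-two subdomain counts use ⌈n/2⌉:⌊n/2⌋ child
targets.  Halo plans collect, per subdomain, the foreign cells within the
class shell range (periodic), grouped by owner; send/receive lists are
symmetric by construction.  Pair ownership follows the midpoint-cell rule
(minimum-image midpoint, floor binning breaking boundary ties toward the
lower cell).  Rebalancing re-partitions on the current per-cell counts at a
fixed step period, never changing the cell size, and keeps the old
partition when the fresh one would not improve the imbalance (max/mean
load).  Everything runs in one process: the correctness surface standing in
for message passing is the identity between per-subdomain owned-pair energy
sums and the serial totals, plus halo coverage of every in-range pair.

## Dynamics

Langevin NVT with the BAOAB splitting: half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity refresh (variance k_B T(1 − e^{−2γΔt})/m),
half-drift, half-kick with the force at the new positions (one force
evaluation per step in the driver).  Defaults: Δt = 10 fs, γ = 0.01 ps⁻¹,
velocities initialized Maxwell–Boltzmann from the recorded seed.  At γ = 0
the scheme reduces to velocity Verlet (tested: < 10⁻⁴ relative energy
drift over 10⁴ steps on a bonded dimer).  Forces are always summed in
global term/pair order, so the domain partition cannot change trajectories
— asserted bit-exactly for rebalance period 10 vs ∞.  A displacement-capped
steepest-descent minimizer is provided to relieve the generator's packing
contacts (down to 2 Å, far inside the LJ core at σ ≈ 6 Å) before dynamics.

## Droplet analysis

Chains are clustered with a deterministic DBSCAN (index-order BFS; border
chains join the first cluster that reaches them; a chain is core when its
neighborhood, itself included, has ≥ min_pts members — the scikit-learn
convention, against which the tests cross-check).  Two neighborhood
definitions mirror the two analysis regimes: chain–chain *contact* (any
inter-chain residue pair within 10 Å; ε = 0.5, min_pts = 20,
min_cluster_size = 100) for two-droplet systems, and *COM distance*
(ε = 50 Å, min_pts = 5, min_cluster_size = 50) for multi-droplet systems.
min_cluster_size is a post-filter relabeling small clusters as noise.

Mixing between two droplets uses D_IJ, the mean COM distance over chain
pairs drawn from initial droplets I and J, and m = sqrt(D₁₁D₂₂)/D₁₂ → 1 at
complete mixing.  The shape coordinate is η = max(d_x/d_y, d_y/d_x) +
max(d_y/d_z, d_z/d_y) + max(d_z/d_x, d_x/d_z) with d_a the per-axis
standard deviations about the droplet COM — this choice (extents are not
pinned down by the defining formula) makes η = 3 exact for any
axis-symmetric cloud; a min–max extent variant sits behind a flag, and box
axes (not principal axes) are used.  COMs under periodic boundaries use the
circular-mean construction, which is wrap-free for objects smaller than
half the box.  Density profiles are slab-volume-normalized histograms along
a box axis, time-averaged.

## Synthetic systems

The generators replace expensive shrink-and-equilibrate preparation with
direct geometric packing: self-avoiding random walks with exact 3.8 Å
bonds, chain COMs uniform in a ball, global non-bonded clearance ≥ 2 Å
(raised to 4 Å where the configuration feeds dynamics).  Two-droplet
systems stack two such droplets along z with a surface gap; multi-droplet
systems rejection-sample non-overlapping spheres (volume fraction < 0.3)
and fill each.  Packing is refused above ~0.01 beads/Å³ (scaled by
(2 Å/min_sep)³), reporting the smallest workable radius.

The scaled-down fusion demonstration uses 40 chains × 10 residues of a
uniform maximally sticky sequence (λ = 1, σ = 6 Å) in two 30 Å droplets
with a 6 Å gap, run 2×10⁵ steps at 150 K.  150 K is where k_B T ≈ 0.3
kcal/mol sits comfortably below the cohesive energy per bead of a λ = 1
droplet, so the condensed phase is stable on this short run; the published
systems use real sequences at 280–300 K with orders of magnitude more
chains and steps.  What the passing test shows is that the engine's
force/thermostat/neighbor-list machinery reproduces the qualitative
condensate physics — droplets in contact merge and their contents mix
(m rises between the first and last trajectory quarter in ≥ 2 of 3 seeds);
it does not validate quantitative kinetics, droplet-size distributions, or
sequence-specific phase behavior, which require the real parameter tables
and production-scale sampling.

## Numerical choices and degenerate inputs

Statistical tables are interpolated as cubic splines of the tabulated
*energies* (clamped for angles, periodic for dihedrals), so a table with
P_θ ∝ sin θ yields an exactly constant energy and zero force; angles
outside the table support are clamped with a logged warning rather than
aborting.  Torsions use the IUPAC atan2 convention with Blondel–Karplus
gradients; angle gradients guard sin θ ≥ 10⁻⁶ (collinear multi-body
geometry zeroes the modulation force).  Gaussian dihedral differences use
the minimum-image angular convention.  All piecewise forms (HPS switch,
Morse split, modulation knots, both excluded-volume cutoffs) are continuous
to < 10⁻¹⁰, verified in tests.  Nonbonded truncation is sharp at r_c; force
tests avoid placing pairs exactly on a cutoff, where −∂E/∂x is undefined.
Pair kernels are numba-compiled; bonded and multi-body terms are
vectorized numpy.

## Problem sizes used in the checks

Brute-force neighbor-list comparisons run at 150–500 particles; decomposed
energy identities at 160–200 particles with 2–8 subdomains; the partition
oracle at 6×4×4 cells with 8 subdomains (the brute-force enumeration is
exponential); thermostat calibration on single particles and 64-particle
ideal gases over 10⁵ and 2×10⁴ steps; the fusion demonstration at 400
particles × 2×10⁵ steps × 3 seeds.  The replication and DNA builders are
exercised at the full published particle counts (300,146; 2,565,178; 1198),
which are cheap because no forces are evaluated.

## Known limitations

Single-process execution only (halo plans and ownership are computed and
verified, not communicated); no NPT or slab-geometry pressure analysis; no
RNA or lipid models; no sequence-nonspecific protein–DNA hydrogen-bond
term; PWM-to-ε_G calibration is external; per-residue tables are synthetic
stand-ins unless supplied by the user; performance is desk-scale (hundreds
of particles for long runs, millions only for topology construction).
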
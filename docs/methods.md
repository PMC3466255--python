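# Methods

This note documents the models behind `qmdmd`: what is simulated, which
knobs matter, which numerical choices were made where the design was
genuinely open, and what the synthetic test systems do and do not show.

## Units and conventions

Lengths in Å, masses in amu, energies in kcal/mol.  The dynamics uses the
natural derived time unit √(amu·Å²/(kcal/mol)) ≈ 48.9 fs, written t.u.;
no separate conversion factor appears anywhere in the propagator, and the
nominal "1 t.u. ≈ 50 fs" is reporting convenience only.  Temperature is
the reduced θ in kcal/mol defined by ⟨KE⟩ = (3 N_free/2)·θ; the thermostat
set-points 0.20 (annealing peak) and 0.10 (production) are values of θ.
Vibrational frequencies come out in cycles/t.u.; the zero-point energy is
½·Σhν over real modes with h expressed in kcal/mol·t.u. (≈ 1.951).

## Domain partitioning and capping

Three domains: the *core* (metal plus every heavy atom within the
coordination cutoff, default 2.6 Å, recomputed at the start of each
iteration), the *shared active-site region* (selected side-chain fragments
cut at named truncation bonds, plus substrate, water and the cofactor
fragment), and the *remainder*.  The breathing boundary is realized as two
static masks applied at different phases — the sampler freezes the core;
the energy backend sees the extracted cluster with cap hydrogens and their
bond partners frozen — rather than a dynamic re-partition per step, whose
frequency would otherwise be an arbitrary extra parameter.

Every bond crossing the cluster boundary is saturated by a hydrogen placed
along the original bond at 0.7052 × the current bond length from the inner
atom.  The factor is applied uniformly; severing a bond whose atoms are not
C/N draws a warning.  Because the analytic surrogate has no basis functions,
the saturating role of a cap is realized energetically by retaining the
frame terms of each severed bond with the outer partner held at its frame
position; the cap hydrogens themselves are geometric markers carried for
I/O and bookkeeping.

Constraint windows transfer optimized geometry into the sampler: each
listed pair becomes a hard interval `optimized distance ± 0.01 Å`.  The
constraint set is refreshed from the freshly optimized cluster whenever an
iteration's output is accepted; when the input is carried, the previous
(still-consistent) windows stay.

## The event-driven sampler

Stepwise potentials only; exact event processing (energy and momentum
conserved to rounding at each shell crossing, reflection when the radial
kinetic energy cannot pay a step).  Pair classes, in priority order
(each pair carries exactly one potential):

| class | shells | energies |
|---|---|---|
| bond (∩ constraint) | [0.95·ref, 1.05·ref] (intersected) | ∞ / 0 / ∞ |
| constraint | [t − 0.01, t + 0.01] | ∞ / 0 / ∞ |
| angle (1-3) | [0.9·ref13, 1.1·ref13] | ∞ / 0 / ∞ |
| packing cage | [core, d0 − 0.3, d0 + 0.3, d0 + 0.9] | ∞ / −0.15 / −0.5 / −0.15 / 0 |
| nonbonded | [0.85σ, σ, 1.25σ], σ = Σr_vdw | ∞ / −0.10 / −0.05 / 0 |

The published all-atom parameterizations of stepwise force fields carry
angle, dihedral and hydrogen-bond structure that this simplified sampler
does not; the 1-3 wells (angle analogs, referenced at the topology's rest
geometry) and the packing cages (each mobile heavy atom attracted to a
pocket at its rest distances from its four nearest frozen scaffold
neighbors) are the minimal stand-ins that keep a sparse toy system from
behaving like a free chain in vacuum — a real protein provides this
localization through dense packing.  1-2/1-3/1-4 pairs, declared H-bond
contacts and the metal carry no generic nonbonded shells (metal coordination
is handled by constraints and the core freeze, never by auto-bonding);
hydrogen gets a deliberately small 0.4 Å vdW radius so H-bonded contacts
never sit inside a hard core.

The propagator is an indexed-heap event loop (one slot per pair plus one
ghost-collision slot per free atom, ties broken by slot index) with lazy
position updates; region indices are authoritative, so windows cannot be
lost to rounding.  The Andersen-style thermostat hits each free atom as a
Poisson process at the heat-exchange rate and redraws its full velocity
from Maxwell–Boltzmann.  Velocities are redrawn at each schedule
set-point change.  A schedule is: instantaneous ramp to θ = 0.20, five
500 t.u. steps linearly down to 0.10, then 10,000 t.u. of production at
0.10 (exchange 0.1 t.u.⁻¹, snapshots every 10 t.u. → 1,000 poses); the
clash-removal pre-run is 1,000 t.u. at θ = 0.10 with exchange 10 t.u.⁻¹,
run once before iteration 1 with only the static scaffold frozen (no
backend pass has happened yet, so there is no core to freeze).  Geometry
that starts inside a forbidden region is projected out by a descent on
overlap depth with progressively tightened windows (a homotopy avoids the
local minima of the raw distance-geometry penalty).

## The analytic surrogate backend

The backend contract (energy, gradient, partial optimization with frozen
atoms, finite-difference Hessians) is the seam where a real quantum-
chemistry engine would plug in; electronic structure itself is out of
scope.  The shipped surrogate is built at the toy site's ground-truth
geometry:

* a structured elastic network — harmonic pair terms for bonds (k = 300),
  1-3 pairs (k = 80), heavy-atom contacts within 5 Å (k = 8) and weak
  frame tethers (k = 3, each mobile heavy atom to the metal and its three
  nearest frozen scaffold atoms) — all with equilibria at native
  distances, so the native structure is a minimum by construction;
* metal–donor Morse wells, depth D = 40·(1 + 0.5·(q − 2)) kcal/mol and
  equilibrium (native distance − r_construction) + r_metal: equilibria
  lengthen monotonically with ionic radius, and depth/stiffness grow with
  charge (the electrophilicity analog);
* 12-6 background terms (ε = 0.05, minimum at 0.9·Σr_vdw) as
  excluded-volume guards for the remaining medium-range pairs;
* a Gaussian × angular hydrogen-bond well, −ε·exp(−(d−d0)²/2σ²)·((1−cos θ)/2)²
  on each declared donor–H···acceptor triple (ε = 3, σ = 0.35 Å);
* the reactive two-well term on ξ = R(O–C) − R(S–C) (reactant ξ > 0):
  V = h·(1 + κ(1+cos α))·((ξ/a)² − 1)² − (Δ/2)(ξ/a) + P·g(ξ) + ½k_η(η−η₀)²,
  with h = 10 kcal/mol, wells at a = ξ_native, α the O–C–S angle
  (collinear native), κ = 0.5 inflating the barrier as collinearity is
  lost, Δ = 3 + 8·(q − 2) stabilizing the reactant side with metal charge,
  and a product-side penalty P = 10·(r − r_ref) + 4·(1+cos α) switched on
  by g(ξ) = ½(1 − tanh(ξ/aw)): larger cations and misalignment raise the
  reaction end-point.  η = R(O–C) + R(S–C) pins the methyl transversally
  (η is constant along the collinear path, so the term adds no force
  there);
* a ξ-coupled proton term: the acceptor O–H equilibrium slides from
  0.98 Å (reactant) to 1.80 Å (product) through a normalized tanh switch,
  the proton-abstraction analog; switchable off.

The small tilt Δ means the constructed native geometry is not an exact
stationary point of the full surrogate; the residual relaxation is below
0.01 Å per atom, inside the 0.05 Å tolerance the generator guarantees.

Partial optimization is L-BFGS on the free atoms (frozen = caps' bond
partners plus the static scaffold) with an analytic gradient; Hessians are
central differences of that gradient (step 10⁻³ Å), mass-weighted;
eigenvalues within 10⁻⁴ of zero are treated as zero modes, ZPE sums the
real modes only.  During the sampling loop all cluster optimizations carry
a one-sided restraint keeping ξ on the reactant side — the loop
equilibrates the reactant state; barrier crossing belongs to the
mechanistic stage.

## Ensemble machinery and the acceptance rule

Clustering is average-linkage agglomerative on the pairwise Kabsch-RMSD
matrix of the heavy atoms of the active-site region (superposition on the
same selection; the frame is frozen, so alignment is nearly the identity),
cut at k = 5; fully degenerate ensembles are split by snapshot index.  Per
cluster, two representatives: the centroid (minimum summed RMSD to
members) and the lowest sampling energy.  The combined score is
rank(backend energy) + rank(sampling energy), lowest wins, ties to the
lower backend energy then the lower snapshot index — a scale-free choice,
since the two energies are not commensurate.  The acceptance rule compares
the active-site subset energy (metal, substrate, water and site-residue
fragments; the cofactor and the frozen frame anchors excluded — the frame
is not part of the active site) of the iteration's input and optimized
output and carries the lower one, ties preferring the output; the carried
subset energy is therefore non-increasing by construction.  A single run
seed deterministically derives per-iteration phase seeds, so any iteration
can be reproduced in isolation.

## Transition-state search

Reactant and product are minima confirmed by a zero imaginary-frequency
count (relaxation into the product basin uses the one-sided ξ guard, which
is inactive at the solution — it only stops line searches from hopping the
barrier).  The saddle is located by a 41-point constrained scan over ξ
(stiff harmonic restraint, all other free coordinates relaxed), taking the
highest interior point and polishing with Newton steps on the full
free-space Hessian (eigenvalue-filtered pseudo-inverse, step cap 0.2 Å).
A polished TS must carry exactly one imaginary mode whose eigenvector is
dominated by the transfer group; a failed polish returns the scan maximum
flagged "unpolished", and a scan whose maximum sits at an endpoint raises
"no barrier on path".  Ensemble profiles report ZPE-corrected ΔE‡ and
ΔE_rxn relative to each member's reactant as mean (sample SD, n−1);
members whose search fails are excluded and counted, never silently
dropped.

## Synthetic sites: what they emulate, what they do not

The generator builds a cation at the origin with octahedral-like slots:
three anchored arms (a bidentate-capable carboxylate, a carbonyl-like arm,
an amide-like arm), a tilted water completing the coordination and
hydrogen-bonded to a Glu-like acceptor arm, a bidentate substrate with an
abstractable proton hydrogen-bonded to a Lys-like base arm, and a frozen
S–CH₃ donor group aimed at the acceptor oxygen.  Native distances default
to an experimentally determined Mg-site geometry; every requested metric
is met exactly at the constructed positions (infeasible requests raise,
naming the offending pair).  The donor O–C and O–S distances sum exactly
to the native S–C bond length, so the native arrangement is collinear
(α = 180°); the ensemble-averaged alignment of a real site is a few
degrees off, which the toy reaches through sampling, not construction.
Stock metal parameterizations use standard ionic radii: Mg 0.72 Å/+2,
Ca 1.00 Å/+2, Fe(II) 0.78 Å/+2, Fe(III) 0.645 Å/+3.

Not emulated: real protein topology and sequence, rotamer states, solvent,
electrostatics and polarization, spin states, and the absolute energetics
of any real enzyme.  Passing the recovery and trend tests shows the
*protocol* is sound — partitioning, sampling, selection and acceptance
cooperate to find a known minimum and to respond in the right direction to
cation size and charge — not that the surrogate predicts real barriers.

## Problem sizes

The default toy site has 38 atoms (23 mobile during sampling).  Full
protocol phases are 10,000 t.u. (≈ 0.5 ns nominal) with 1,000 snapshots;
the distort-and-recover experiment (σ = 0.4 Å, 10 seeds, up to 10
iterations, success = heavy-atom RMSD < 0.3 Å) uses 5 × 200 t.u. annealing
and 3,000 t.u. production per iteration, a configuration chosen so the
whole experiment stays a desk-scale computation while leaving every stage
of the loop exercised.  The thermostat check runs a 62-free-atom,
six-armed site for 10,000 t.u.  Reaction profiles use 31–41 scan points.
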
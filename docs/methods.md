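# Methods

This note records the models, conventions, and numerical choices behind
`cycbind`, and what the synthetic-data tests do and do not demonstrate
about real molecular systems.

## Units and constants

Distances are Å, angles degrees, energies kcal/mol, temperatures K.
kB = 0.0019872 kcal mol⁻¹ K⁻¹ (the convention of the major MD engines, so
free energies round-trip cleanly against their output). The standard-state
volume is computed from Avogadro's number, 10²⁷/N_A = 1660.539 Å³ per
molecule at 1 mol L⁻¹. The electrostatic constant is 332.0636
kcal Å mol⁻¹ e⁻². The default working temperature is 300 K; 310 K is the
conventional choice for physiological-temperature contact analyses.

## Synthetic sampling

The samplers exist to realize stationary Boltzmann distributions on
analytic toy potentials, not to emulate molecular dynamics. The default is
a Metropolis random walk with many independent walkers; an overdamped
Langevin (MALA) scheme is available. During the burn-in (first 10% of
steps, configurable) the step size is auto-tuned toward a 30–50%
acceptance rate and the tuned value is then frozen, preserving detailed
balance for the recorded portion. Every generator is a pure function of
its configuration and seed.

Umbrella windows use the full-constant convention u(ξ) = (k/2)(ξ−c)²; this
is documented because several packages write the bias without the 1/2. The
reference window grid is 20 windows with centers 16.5–26.0 Å at 0.5 Å
spacing and k = 10 kcal mol⁻¹ Å⁻².

Replica exchange runs one chain per window; every `exchange_interval`
production steps, adjacent pairs (w, w+1) attempt configuration swaps with
w alternating between even and odd, accepted with probability
min(1, e^{−βΔ}) where Δ is the bias-energy difference of the swapped
configurations (the unbiased potential cancels). Acceptance is logged per
pair.

ABF-style gradient streams are idealized: per-bin samples of the true
analytic mean force plus Gaussian noise. The extended-system dynamics and
the CZAR-style unbiasing step of real eABF are not emulated; gradient
streams are assumed already unbiased. This is a fidelity limit: the tests
exercise the integration and bookkeeping, not the extended-coordinate
deconvolution.

The toy-complex builder places two chains so that the number of
inter-chain atom pairs within 5 Å is exact by construction (isolated
"bridge" pairs ≥ 12 Å apart, bulk clusters kept away from the interface),
with a 2.4 Å minimum interatomic separation, zero net charge per chain, GB
radii in [1.1, 2.1] Å, and Lennard-Jones parameters in typical protein
ranges. It is a fixture generator for scoring and geometry code, not a
physical structure model.

## Structures and geometry

PDB parsing and writing go through biotite; explicit bonds (including the
head-to-tail cyclization bond) are carried in CONECT records. Per-atom
parameters (charge, intrinsic GB radius, LJ ε and rmin/2) come from a
user-supplied TSV keyed on (residue name, atom name); reading fails loudly
listing any unparameterized atoms. Head-to-tail cyclization adds exactly
one bond between the first residue's backbone N and the last residue's C
and is idempotent; chains of fewer than three residues are refused.

Superposition is Kabsch via SVD with an explicit reflection guard
(det = +1 always). The dissociation screen measures peptide displacement
in the receptor frame: each frame is first aligned on the receptor
selection, then the peptide Cα RMSD is computed *without* fitting the
peptide onto itself, so rigid drift out of the binding site counts in
full. The alignment convention for the 25 Å stop rule is not uniquely
determined by the source protocol; the receptor-frame reading is this
package's default and both fitted and unfitted modes are exposed.

Residue numbering follows the input file (1-based); residue ranges are
inclusive. Contact definitions use exactly the atoms named in the
selection (hydrogens are kept when present, since H-bond criteria are
O⋯H distances). Contact occupancy is the fraction of (masked) frames with
minimum group-group distance below the threshold.

## MM-GBSA

Single-trajectory protocol: receptor and peptide geometries are excised
unchanged from each complex frame, so all intra-part bonded terms cancel
exactly and the score reduces to the inter-part Coulomb and
Lennard-Jones interaction plus the GB and SASA desolvation differences.
Conformational entropy is not estimated — the score is a screening
statistic.

The GB variant is OBC model II: Hawkins–Cramer–Truhlar pairwise
descreening integrals with a uniform descreening scale factor (default
0.8, exposed as a knob since per-element scale sets vary between force
fields), Born offset 0.09 Å, and tanh rescaling with α, β, γ = 1.0, 0.8,
4.85. The polar energy is the Still expression with
f_GB = √(r² + a_i a_j e^{−r²/4a_i a_j}), including self terms, with
ε_in = 1 and ε_solv = 78.5. Salt screening is off by default (κ = 0); a
Debye–Hückel variant is available. The choice of GB flavor among an MD
package's implementations is a judgment call; OBC-II is the widely used
default and all tests carry their own radii.

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, refused below 32) over spheres of radius
gb_radius + 1.4 Å; the nonpolar term is γ·SASA with γ = 0.00542
kcal mol⁻¹ Å⁻². LJ combining is Lorentz–Berthelot and the rescoring is
cutoff-free (all pairs).

Per-frame totals over the bound portion of a trajectory are summarized as
mean ± SEM treating frames as independent; no autocorrelation correction
is applied (a documented limitation — real trajectory frames at a 0.2 ns
stride are correlated).

## PMF estimation

WHAM pools samples per window (the standard treatment for REUS data, where
configurations migrate between windows) and iterates the self-consistent
equations in log space; convergence is the maximum absolute change in
window free energies, tolerance 1e-7 kcal/mol, with the first window's
free energy pinned to zero to fix the gauge. Histogram bin width defaults
to window spacing / 5 (0.1 Å on the reference grid) — the source protocol
does not state a bin width, so it is a package default. Bins with zero
total count are dropped from the PMF support rather than assigned +∞; a
disconnected support (a window-overlap gap) is an error naming the gap,
and non-convergence is reported in the result, not raised.

ABF integration is a cumulative trapezoid of per-bin mean gradients,
min-zero referenced. Window overlap diagnostics report Σ_bins min(p_i, p_j)
per pair.

The half-split uncertainty rule takes the maximum absolute difference
between the full-data estimate and the estimates from the first and second
halves; the earlier half gets ⌊n/2⌋ samples (odd-n handling is a package
convention).

## Geometric route

Angle integrals are carried in degrees at the interface and converted
inside the integrands, with the sinΘ/sinθ Jacobians written explicitly.
Angular PMFs supplied by users are assumed Jacobian-inclusive, matching
what colvar-based ABF output provides. The stage-3 radial integral I
carries no r² factor; the r*² geometric factor lives entirely in the
surface term S* (with r* = 26 Å and a = 16 Å as the reference geometry).
Stage numbering follows the applied-first convention (restraints applied
to the free ligand in stages 1–2, released from the complex in 4–9).

Quadrature is trapezoid on the PMF grid; a boundary check refuses the
integral if the restrained Boltzmann weight at the domain edges exceeds
1e-6 of the total. A zero-stiffness restraint returns exactly 0 (identical
integrands). The analytic orientational stage factorizes into three 1-D
adaptive quadratures and carries zero uncertainty. Default restraint
force constants, when a manifest omits them: 10 kcal mol⁻¹ Å⁻² for
distance/RMSD coordinates and 0.1 kcal mol⁻¹ deg⁻² for angles.

Stage uncertainties combine in quadrature (independent stages); totals are
kept at full precision and rounded only for display. The packaged
nine-stage reference table is an input: stages 1 and 3–9 required
microsecond-scale explicit-solvent trajectories and stage 2's restraint
parameters are not recorded, so none of those values is recomputed here.

### Path-consistency model

`cycbind.synth.toyroute.ToyBindingModel` is a separable toy surface — a
conformational coordinate with identical PMFs in the bound and free
states, isotropic orientation/direction angles, and a Gaussian radial
well. Separability gives the assembled total a closed form,
ΔG° = −kT ln(4π r*² I C°), independent of every restraint force constant,
so doubling all stiffnesses must leave the total unchanged. The stage PMFs
are computed deterministically from the surface by numerical
marginalization: the check isolates restraint-bias cancellation (the
route's defining property) from sampling noise, which the WHAM/ABF
recovery tests cover separately.

## What the synthetic tests do not show

The generators produce 1-D and angular coordinates under known potentials
and idealized gradient estimates. Passing tests demonstrate that the
estimators and the stage algebra are correct, not that a real peptide's
PMFs are converged: real systems add orthogonal slow degrees of freedom,
correlated frames, force-field error, and eABF extended-system effects,
none of which are emulated. The reference screening and stage tables are
carried as data, and quantities that would require the original
microsecond trajectories (per-candidate MM-GBSA energies, individual stage
values) are out of scope by design.

## Problem sizes

Default test-suite and acceptance-script sizes: 5·10⁴ recorded samples per
umbrella window across the 20-window grid, 10⁴ gradient samples per 0.1 Å
bin, 960-point SASA spheres, and toy complexes of tens of atoms. These
sizes put the stochastic estimator errors an order of magnitude below the
assertion thresholds while keeping a full run in tens of seconds on one
CPU.
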
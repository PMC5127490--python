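# Methods

`pullscope` reimplements, at desk scale, the analysis machinery needed to
compare simulated force spectroscopy of a protein across models of
different resolutions: a minimal C-alpha Gō simulator to generate
unfolding trajectories, contact-based order parameters, cross-model
normalization of temperature/time/force, and a TM-score taxonomy of
unfolding pathways.  This note documents the models, the numerical
choices, and what the synthetic test systems do and do not establish.

## Contact observables

The global order parameter is the smoothed fraction of native contacts

    Q(X) = (1/|S|) Σ_{(i,j)∈S} w_ij / (1 + exp[β₀ (r_ij − λ r⁰_ij)])

over the native pair set S (pairs of moieties at least `min_separation`
= 4 residues apart in sequence with native distance below `r_cut`).
Non-native contacts are counted with the same sigmoid around the single
length λR₀, where R₀ is the mean native pair distance.  Shipped contact
parameters per model family (β₀ in 1/nm, r_cut and R₀ in nm):

| model family        | β₀ | λ   | r_cut | R₀   |
|---------------------|----|-----|-------|------|
| heavy-atom (AA/HA)  | 50 | 1.8 | 0.48  | 0.24 |
| three-bead          | 50 | 1.2 | 0.60  | 0.46 |
| one-bead (C-alpha)  | 50 | 1.2 | 1.20  | 0.91 |

The printed R₀ values are shipped as constants rather than recomputed,
because the heavy-atom value is smaller than any plausible mean contact
distance under the same pair set; recomputation from a map remains
available (`NativeContactMap.mean_r0`).  One consequence of λ = 1.2
worth knowing: a native contact at r⁰ ≈ 0.45 nm contributes
expit(50·0.2·0.45) ≈ 0.989 even in the native frame, so Q(native)
saturates near 0.998, not 1.0 — the ≥ 0.999 level is reached only by the
λ = 1.8 parameter set.

C-alpha maps can be weighted by the number of heavy-atom contacts the
residue pair has in a heavy-atom reference (`weighting=
"heavy-atom-count"`), reproducing the energetic heterogeneity of
one-bead models derived from all-atom structures.

Frames are assigned to Q bins by nearest bin centre with half-width
δQ = 0.01 (configurable).  For the binarized maps (off-native
accounting, non-native frequency maps) a smoothed term above 0.5 counts
as a contact present; the source analyses do not state a binarization
rule, so the sigmoid midpoint is used.

## The C-alpha Gō model and its integrator

One bead per residue at the C-alpha position, reduced units: the depth
of one uniform native contact is the energy unit (ε = 1), bead masses
are 1, lengths in nm, k_B = 1.  Terms:

* harmonic bonds (k = 500 ε/nm²) and angles (k = 40 ε/rad²) at native
  values; dihedrals K[(1 − cos Δφ) + ½(1 − cos 3Δφ)] with K = 1 ε;
* native pairs: 10–12 wells ε w [5(r⁰/r)¹² − 6(r⁰/r)¹⁰] with minima at
  the native separations, well depths proportional to heavy-atom contact
  counts when a heavy-atom reference is supplied, else uniform;
* excluded volume (σ = 0.4 nm, r⁻¹² ) for all non-native pairs at least
  3 apart in sequence.

The bond constant is softer than structure-based force-field generator
defaults (2×10⁴ ε/nm²): with unit masses and the 0.004 time step used
here, the stiffer value would put the bond mode at the edge of Verlet
stability and bias the kinetic temperature by several percent.  500
ε/nm² keeps bonds two orders of magnitude stiffer than any contact
interaction while resolving the fastest mode (ω·dt ≈ 0.13).

Two numerical safeguards make the 0.004 step robust; both are
energy-consistent (forces are exact gradients, verified by finite
differences in the test suite):

* **Linearized cores.**  Below 0.9 of the reference distance both r⁻¹²
  walls (native 10–12 and excluded volume) continue linearly with
  matching energy and force.  The unsoftened walls reach curvatures with
  ω·dt ≈ 1 just below 0.9 r⁰, which pumps energy during thermal
  collisions until the run detonates; the linear continuation bounds the
  force while still climbing tens of ε within a tenth of a nm, so chain
  crossing stays thermally forbidden.
* **Dihedral collinearity switch.**  The torsion torque arm diverges as
  1/|b_i×b_j|² when an internal angle approaches π.  The dihedral energy
  is multiplied by s(θ₁)s(θ₂) with s = min(1, sin²θ/0.09), switching the
  torsion off smoothly within ~17° of collinearity.  Native geometries
  keep internal angles below ~135°, so the switch is inert except in
  rare thermal excursions.

Dynamics are integrated with the BAOAB splitting of Langevin dynamics;
the thermostat time constant (default 12 time units) is interpreted as
the inverse friction.  With friction off and T = 0 the scheme reduces to
velocity Verlet and conserves a shadow energy (drift < 10⁻³ of the
native well depth over 10⁴ steps is asserted).

## Pulling, melting, relaxation protocols

Constant-velocity pulling tethers the N-terminal bead to its initial
position and moves the C-terminal tether reference along the fixed
initial N→C axis (the direction is not re-evaluated during the run, so
the geometry matches a fixed-axis optical-trap assay).  Reported force
is the spring extension projected on the axis times k; extension δx is
the change in tether separation.  Defaults: k = 100 ε/nm² (the reduced
analogue of a stiff device spring), speed 0.05 nm per time unit, maximum
extension 30 nm scaled by chain length/110.

Melting curves come from either direct runs started in the native state
or replica-exchange (REMD) with Metropolis neighbour swaps.  For this
toy system direct native-start runs show strong hysteresis near the
transition; the calibrated folding temperature therefore comes from the
REMD mode, which equilibrates both basins (swap acceptance ~0.5 with the
default ladder).  Means and standard errors use Flyvbjerg–Petersen
blocking after discarding the first 30% of each series.

The perturb–relax protocol steers one residue pair 1.5 nm beyond its
native separation with a moving harmonic distance restraint (the
steering scheme is not specified in the source protocol; a moving
restraint is assumed), releases all restraints, and records Q(t).  The
relaxation clock of a model is t = 1/⟨κ₁⟩ from constrained
double-exponential fits (amplitudes ≥ 0, κ₁ ≤ κ₂, multi-start from a
log-linear single-exponential seed) to the Q autocorrelation.

## Cross-model normalization

* Temperature: the melting curve is fitted to the two-state form
  ⟨Q(T)⟩ = q_u + (q_f − q_u)·f(T), f = expit(ΔG/RT), ΔG = ΔH − TΔS,
  by bounded nonlinear least squares with a 10-point T_f multi-start
  grid; T_f = ΔH/ΔS, production runs at 0.9 T_f.  The relative
  transition width between 80% and 20% of the folded baseline is closed
  form: T_p = ΔH/(ΔS + R ln(p/(1−p))).  Note the width depends only on
  ΔS/R; scaling ΔH at fixed ΔS moves T_f without changing the width,
  whereas scaling ΔH and ΔS together sharpens the transition.
* Time: pulling speeds scale as v_a t_a = v_b t_b with t = 1/⟨κ₁⟩.
* Force: work integrals W = ∫₀ᴸ F dx (trapezoidal; non-monotone
  extension records are resampled onto a monotone grid first) feed the
  Jarzynski estimator ΔG = −β⁻¹ ln⟨e^{−βW}⟩ (log-sum-exp stabilized).
  The per-model force scale α solves −ln⟨e^{−β α W}⟩ = β_ref ΔG_ref by
  Brent bracketing; a convergence trace over the first k runs is
  reported.  No finite-sample bias corrections are applied, and no
  temperature-dependent heat capacity enters the two-state fit (the
  underlying models have temperature-independent interactions).

Block-averaged standard errors use successive pairwise blocking; the
plateau is the first level whose increase over the previous one is
within twice that level's own statistical error (est/√(2(n−1))), and the
returned value averages that level with the next two.  This detector
stays within ~10% of the closed-form AR(1) answer across seeds at
n = 10⁵, ρ = 0.9.

## Pathway taxonomy

TM = (1/L) Σ 1/(1 + (d_i/d₀)²) with d₀ = 1.24(N−15)^⅓ − 1.8 Å, floored
at 0.5 Å (the formula is negative below N = 21).  Same-sequence
conformations keep a fixed residue correspondence; only the rigid-body
superposition is searched, by sliding seed fragments (lengths L, L/2,
L/4) with iterative reselection of residues inside d₀.  For fragments of
≤10 residues the landscape is spiky on the d₀ = 0.5 Å floor, so every
3-residue subset seeds the search and a multi-start Nelder–Mead polish
over SE(3) follows; this matches an exhaustive rotation-grid reference
within 0.01 on decoy fixtures.

The folded segment at a given Q is the largest contiguous run of
residues with ensemble-average Q_k > 0.5, bridging internal
sub-threshold gaps of at most 10 residues.  One frame per trajectory per
Q bin (the frame closest to the bin centre) enters the all-against-all
TM matrix; hierarchical clustering on 1 − TM (average linkage by
default, single linkage available) is cut at 1 − 0.6.  Cluster-to-
cluster trajectory flow across descending Q levels forms the pathway
graph; edge weights are fractions of all trajectories, so outgoing
weights at a node sum to its flow.  The dominant pathway is the most
travelled full chain of clusters (ties broken by larger clusters, then
lower cluster ids).

The sliding-window reference curve takes every window (length, offset)
of the native chain as a partial structure, computes its Q as the weight
fraction of native pairs internal to the window, bins windows by Q and
TM-aligns within bins.  Cross-length comparisons align the residue-index
intersection of the two windows and normalize by the longer window; two
disjoint windows score 0.  This convention is one defensible reading of
an under-specified construction and is isolated in `tm_score_common`.

Strand-level unfolding-order correlations use a persistence score per
residue — the Q at which Q_k first drops below 0.5 scanning from Q = 1
downward (0 if it never drops: the most persistent end of the scale) —
averaged per strand and compared across models with Pearson r.  Strand
ranges are supplied by configuration, never computed from structure.

## Synthetic test systems

`generate_toy_structure` builds deterministic, self-avoiding C-alpha
chains with exact 0.38 nm virtual bonds: a two-layer beta sandwich
(strand spacing 0.5 nm, sheet separation 0.62 nm, pleat amplitude
0.095 nm, turns of two beads on exact circular arcs bulging away from
the partner sheet) or a three-helix bundle (radius 0.23 nm, 100° per
residue, rise set so the chord is exactly 0.38 nm).  A seeded jitter of
0.004 nm breaks lattice symmetry before bond lengths are restored
exactly.  The 40-residue sandwich used in the tests has 110 Gō contacts
and, under REMD with a ladder bracketing both baselines, a folding
temperature near 1.2 reduced units with a clean two-state melting curve
(the estimate shifts by ~15% with REMD length, as expected for a small
system with slow interbasin exchange); it is mechanically stable at
0.5 T_f and fully unfolds (terminal Q < 0.1) under tether pulling at
0.9 T_f.

`scripted_unfolding_trajectory` generates idealized ensembles that peel
residues off the folded core from the termini in a prescribed N/C
schedule, laying unfolded residues on an extended noisy tail.  These
provide ground-truth pathway structure for the taxonomy stages: a
single schedule must yield one dominant pathway (≥90% flow) and a high
mean-TM-vs-Q curve, two interleaved schedules a 50/50 split and a low
curve at low Q.

What these synthetic systems do **not** establish: fidelity to any real
protein's unfolding (no side-chain packing, no solvent, no sequence
heterogeneity beyond contact counts), the published trajectory-derived
numbers (force scale factors, cross-model correlation coefficients,
off-native tables — all of which require the original large-scale MD
ensembles), or the behaviour of three-bead/heavy-atom force fields,
whose trajectories this package analyses but does not simulate.

## Problem sizes

Default test-scale settings: 40-residue toy chains; REMD melting scans
of 8–10 replicas × 2×10⁴ steps; 10–20 pulling runs of ~5×10⁴ steps;
taxonomy ensembles of 12–20 trajectories × 40 frames.  These sizes give
stable pass/fail behaviour for every property asserted while keeping a
full run of the suite and the acceptance script on one CPU comfortable.
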
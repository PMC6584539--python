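# Methods

This note records the models implemented in `solvshell`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic generators do and do not emulate. Units throughout: Å, ps,
kcal/mol, degrees, elementary charges (CHARMM conventions).

## Geometry and periodicity

Boxes are orthorhombic. Minimum-image wrapping maps each displacement
component into [−L/2, L/2); the half-box tie resolves to the negative
end so results are deterministic and testable. Molecules are stored
whole (never split across a periodic seam), and all inter-molecular
vectors are taken relative to the solute COM with minimum-image
convention, so COM and plane computations never straddle a seam.

Plane normals (base and urea alike) are the smallest principal axis of
the centered atom cloud — the least-squares plane — with the sign fixed
by making the component along the laboratory axis of largest magnitude
positive. An angle between two such normals is therefore only defined
up to the 180° reflection; every consumer (the stacking gate, pose
round-trip tests) treats θ₁ symmetrically about 90°.

## Interaction energies

Nonbonded energies use the CHARMM forms: 12-6 Lennard–Jones with
Lorentz–Berthelot combining (geometric-mean ε, summed Rmin/2) and a
real-space Coulomb term with constant 332.0636 kcal·Å/(mol·e²). Both
terms are multiplied by the switching polynomial

    S(r) = (r_off² − r²)² (r_off² + 2r² − 3 r_on²) / (r_off² − r_on²)³

between r_on = 10 Å and r_off = 12 Å and are zero beyond the cutoff.
Real-space switched electrostatics (not Ewald) is a deliberate choice
for a desk-scale analysis tool: it is deterministic, local, and exactly
reproducible by a brute-force 27-image double loop, which is how the
implementation is verified. Absolute electrostatic energies therefore
differ from a PME treatment; relative energies across solvent
environments — the quantity of scientific interest — are much less
sensitive to this choice. The first 20 % of frames are discarded by
default as equilibration; the standard error is block-averaged over
5 equal blocks (a plain choice, since no error model is canonical).

## Two-domain preferential interaction coefficient

Γ is evaluated frame-wise as N_u^loc − (N_u^blk/N_w^blk)·N_w^loc and
then ensemble-averaged, with block-averaged errors. Frames without bulk
water are excluded with a warning. The default local rule is the most
literal reading of a 4.5 Å proximity criterion: a solvent molecule is
local iff *any* of its atoms is within 4.5 Å of *any* solute atom.

Two further rules are exposed because the counting rule matters more
than is usually appreciated:

* `com_any_atom` — molecule COM within the cutoff of any solute atom;
* `com_sphere` — molecule COM within a sphere around the solute COM.

The any-atom rule has a *molecular-size offset*: in a perfectly uniform
mixture, a urea (8 atoms, ~2.3 Å radius) pokes into the local region
more often than a water, so Γ_any-atom > 0 with no preference present
(≈ +2.5 for ~2000 molecules in a 40 Å box). The COM rules are
size-symmetric and have an exactly zero uniform-mixture null; the test
suite pins both behaviors. Real-trajectory users comparing against a
zero null should prefer a COM rule or subtract a uniform-mixture
baseline.

## RDF → long-range model → Kirkwood–Buff

RDFs are histograms of solute-COM→site distances (urea carbon, water
oxygen), normalized by the 4πr²Δr shell volume and the mean site
density, with 0.1 Å bins and r_max at half the smallest box edge.
Smoothing is Savitzky–Golay (window 11, polynomial order 3 — the filter
is standard, the parameters are ours).

The noisy tail is replaced by the damped sinusoid
g(r) = 1 + a·e^{−b(r−c)}·sin(d(r−e)), fitted by least squares on
r ≥ r_max2 starting from the feature-based recipe (a₀ = g(r_max2)−1,
b₀ from the log-ratio of the second-extremum amplitudes, c₀ = r_max2,
d₀ = π/(r_u4−r_u3), e₀ = r_u3); the stitched profile uses the direct
curve below r_u3 and the model above it. Two robustness measures:
feature detection cancels adjacent max/min pairs whose amplitude is
below 5× a robust (MAD-of-second-differences) noise floor, and the fit
adds four deterministic perturbed restarts around the recipe start to
escape the flat a ≈ 0 basin on noisy data. The model has exact
symmetries — (a,c) → (a·e^{bΔc}, c−Δc), (a,e) → (−a, e+π/d), and
e → e + 2π/d — so only canonicalized combinations are identifiable;
tests compare in a fixed gauge.

KB integrals use trapezoidal quadrature of (g−1)·w with the finite-size
three-dimensional hypersphere weight w(x,r) = 4πr²(1 − 3x/2 + x³/2),
x = r/R. Two facts matter when using this estimator on closed boxes:

1. At finite R the weight suppresses a compact perturbation of radius
   r₀ by ≈ (9/8)(r₀/R); G(R) approaches the thermodynamic-limit
   integral linearly in 1/R. `kb_integral_extrapolated` fits G(R) over
   a range of R and extrapolates to 1/R → 0, which is how the estimator
   is used in the KB literature.
2. In a closed box a locally enriched species has a long-range plateau
   slightly below 1 (the excess must come from somewhere), and the
   weight integrates that deficit as an R³ term. For oscillatory RDFs
   the fitted tail model removes this by construction (it decays to 1);
   for non-oscillatory profiles `renormalize_bulk` rescales the plateau
   to 1 first.

The contact coefficient is Γ_KB = ρ_urea·(G_su − G_sw) — the standard
preferential-binding combination of KB integrals. On constructed
enriched boxes this agrees with the shell-count Γ to within a few
percent once (1) and (2) are applied; the residual ~5 % deficit is the
genuine excluded-volume asymmetry between urea and water around the
solute.

## Interaction-mode classification

All gates operate on per-molecule geometry measured with minimum-image
vectors: d_com (base COM–urea COM), d_comN (base COM–nearest urea N),
θ₁ (plane normals), θ₂ (base normal vs COM–COM vector), θ₃ (the
N–H···COM angle at the hydrogen nearest the base COM), θ₄ (base normal
vs COM→H vector).

* stacking: d_com ≤ 4.5 Å ∧ (θ₁ < 40° ∨ θ₁ > 140°) ∧ (θ₂ < 70° ∨ θ₂ ≥ 110°);
* NH–π: d_comN < 4.5 Å ∧ (θ₄ > 150° ∨ θ₄ < 30°) ∧ θ₃ > 150°;
* hydrogen bond: donor-heavy→acceptor ≤ 3.5 Å ∧ D–H···A ≥ 150°, both
  directions (base N–H → urea O and urea N–H → base acceptor). The
  3.5 Å/150° convention is the widely used one; both thresholds are
  configurable.

The θ₃/θ₄ binding was a genuinely open design point: the alignment
criterion (>150° or <30°) is attached to the base-normal/COM→H angle
and the linearity criterion (>150°) to the N–H···COM angle, matching
the geometric intent of an N–H directed at the π face; both thresholds
are exposed in the config. The modes are *not* mutually exclusive — a
urea tilted ~35° with one N–H pointing down the ring axis satisfies
both the stacking and NH–π gates simultaneously, and the suite
constructs such a pose explicitly.

Spatial density maps superpose each frame's solute heavy atoms on the
first frame (Kabsch least squares; an RMSD above 1 Å warns that the
solute is not rigid), bin urea C/N/O atoms within 4.5 Å of any solute
atom into a 75³ grid spanning a cube of edge 2× the region radius
(7.75 Å for fused-ring solutes, 7.05 Å for single-ring ones,
auto-detected from the ring-atom count), with half-open voxel intervals
and boundary atoms excluded. Export is plain Gaussian cube (bohr
header, z-fastest).

## Residence dynamics

Contact series are per-molecule boolean vectors from frame-wise
classification. Dwell events are maximal true runs; gaps no longer than
the transient-disruption time t\* are bridged, and the bridged gap time
*counts toward the event duration* (duration = first-to-last contact
frame, matching the "time spent around the solute" reading; the
alternative contact-only convention would require only a different
duration formula on the same merged runs). Defaults: t\* = 0.5 ns for
distributions, 0.1 ns for lifetime comparisons. Boundary-truncated
events are kept; no censoring correction is applied (a deliberate
limitation — lifetimes are biased slightly low when events are long
relative to the trajectory).

Dwell histograms use bins centered on multiples of the bin width
(default: the frame spacing); the survival curve is evaluated at 0 and
the bin upper edges. With that grid the trapezoidal ∫S dt reproduces
the sample-mean duration exactly for durations on the dt lattice —
the identity ⟨τ⟩ = ∫S dt holds to well under 0.5 % on every ensemble.

The triexponential fit minimizes ‖Σ aᵢ e^{−t/τᵢ} − S‖ with aᵢ ≥ 0 and
log-space timescales, from five deterministic log-spaced starts;
amplitudes are renormalized to S(0) and components whose timescales
agree within 10 % are merged (they are not separately identifiable, and
merging lets a pure single exponential report one dominant component).

## Thermodynamic integration

The two-step path switches the Lennard–Jones cross term on first
(s: 0.01 → 1 in steps of 0.01, g = 0) and electrostatics second
(s = 1, g: 0.01 → 1). The LJ leg uses the Beutler soft core
U = 4εs·(σ¹²/D² − σ⁶/D), D = α(1−s)σ⁶ + r⁶, α = 0.5 — finite at r = 0
for s < 1 and exactly s× the standard LJ at s = 1 — with the analytic
∂U/∂s verified against finite differences. The electrostatic leg uses
plain Coulomb, since the repulsive core is fully on before g rises.

⟨∂U/∂λ⟩ is integrated per leg by trapezoid; grids starting at
λ = 0.01 are linearly extrapolated to λ = 0 from the first two points,
keeping the rule exact for constant and linear integrands. Errors
propagate from per-point block-averaged standard errors through the
trapezoid weights. Sampling is a vectorized Metropolis walker ensemble
(8 walkers, 100 burn-in + 600 production sweeps per λ-point by default,
warm-started along the schedule — the 1:6 burn-in:production ratio
mirrors common practice). The λ-scaled harmonic well provides the
analytic oracle ΔG = (kT/2)·ln(k₁/k₀), recovered within 3 % with
forward/backward hysteresis |ΔG_f + ΔG_b| an order of magnitude
smaller; a small periodic solute–solvent toy system exercises the full
two-leg path, the transfer free energy ΔΔG = ΔG_solv(urea env) −
ΔG_solv(water env), and the thermodynamic-cycle closure.

## Synthetic generators: what they emulate, and what they do not

The box builder packs rigid idealized molecules (planar urea from
standard bond lengths; TIP3P-like water; fused- and single-ring solute
templates with plausible charges normalized to exact neutrality) by
randomized sequential insertion with hard-core exclusions: 2.4 Å
solvent-to-solute and 1.8 Å solvent-to-solvent between non-hydrogen
atoms. Enrichment is implemented by region conditioning: each molecule
is assigned to the shell or the remainder by an exact Bernoulli draw
(urea probability fv/(fv+1−v), water v), and re-proposals after a clash
stay inside the assigned region. This makes the expected region counts
— and hence the constructed Γ — exactly their closed-form values even
with hard-core exclusion; density *reweighting* of proposals would not
(clash rejection is spatially non-uniform, and we measured ~25 %
enrichment loss that way). An `ideal=True` mode skips all exclusions
and is the strict reference for null-value tests.

Frames are i.i.d. configurations, not dynamics: the static estimators
(Γ, RDF, KB, density) need configurational sampling only. Where
dynamics *is* the object, the generators are dynamical: a discrete
Markov chain for contact series (P(on→off) = k_off·dt, mean bound time
1/k_off) and a Gaussian random walk for diffusion (per-step variance
2D·dt per dimension). The packed boxes have no attractive forces, no
equilibrium liquid structure, no hydrogen-bond network, and no
force-field accuracy; passing tests therefore demonstrate that the
estimators recover constructed ground truth, not that the synthetic
liquids resemble real aqueous urea. Posed geometries are exact rigid
placements used for classifier round-trips (requested (d, θ) reproduced
to 0.01 Å / 0.1°).

## Default problem sizes

The suites and the acceptance script run on one CPU in a few minutes
total: uniform-mixture Γ nulls on ~2000 molecules × 200 frames;
enriched-box cross-checks on 600–1600 molecules × 150–300 frames;
residence statistics on ~10⁴ dwell events; TI on 200 λ-points ×
700 sweeps × 8 walkers; diffusion on 10⁵ frames. These sizes were
chosen so every stochastic check sits several standard errors inside
its tolerance.

## Known limitations

* No Ewald/PME electrostatics, bonded terms, or pressure/virial.
* No triclinic cells; no binary trajectory formats (convert upstream).
* No censoring-corrected survival estimation.
* The KB route assumes the RDF reaches a usable plateau within half the
  box; heavily structured small boxes need the tail model or larger
  boxes.
* The toy TI systems are oracles for the integrator and sampler, not a
  general free-energy engine (no BAR/MBAR, no replica exchange).
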
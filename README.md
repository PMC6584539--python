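# solvshell

Solvation-shell analysis of cosolvent–solute interactions from
molecular-simulation trajectories, built around the question of how
urea competes with water for the surface of a small rigid solute such
as a nucleobase — the molecular picture behind urea-assisted RNA
unfolding. The package bundles the full analysis chain:

* **Interaction energetics** — solute–solvent pair energies with the
  CHARMM switching function (`S(r)` between 10 and 12 Å), decomposed
  into electrostatic and Lennard–Jones components, plus MSD/Einstein
  diffusion coefficients.
* **Two-domain preferential interaction coefficient** —
  `Γ = ⟨N_u^loc − (N_u^blk/N_w^blk)·N_w^loc⟩`, partitioning solvent at a
  4.5 Å shell around the solute.
* **Kirkwood–Buff chain** — solute-centered RDFs, Savitzky–Golay
  smoothing, a damped-sinusoid long-range model
  `g(r) = 1 + a·e^{−b(r−c)}·sin(d(r−e))` fitted in the least-squares
  sense and stitched onto the direct curve, finite-size KB integrals
  `G = ∫₀ᴿ (g−1)·w(x,r) dr` with the hypersphere weight
  `w = 4πr²(1 − 3x/2 + x³/2)`, and the contact coefficient
  `Γ_KB = ρ_u (G_su − G_sw)`.
* **Interaction-mode classification** — geometric gates for π–π
  stacking (`d ≤ 4.5 Å`, plane-normal angle θ₁, normal/COM-vector angle
  θ₂), NH–π contacts (COM–N distance, N–H alignment angles θ₃/θ₄) and
  hydrogen bonds (3.5 Å / 150°), with body-frame spatial density maps
  on a 75³ grid exported as Gaussian cube files.
* **Residence dynamics** — dwell events with a transient-disruption
  tolerance t\*, dwell-time distributions, survival probabilities
  `S(t; t*)`, mean lifetimes `⟨τ⟩ = ∫S dt`, and constrained
  triexponential fits.
* **Thermodynamic integration** — two-step coupling (soft-core LJ leg,
  then electrostatics), a 0.01-step λ schedule, a built-in Metropolis
  sampler for desk-scale toy systems with analytic free energies, and
  forward/backward hysteresis diagnostics; transfer free energies close
  the water → aqueous-urea thermodynamic cycle.
* **Synthetic data** — every input the analyses need can be generated
  with known ground truth: packed urea/water boxes with an optional
  enrichment shell (closed-form expected Γ), two-state Markov contact
  series (mean lifetime 1/k_off), Brownian solute paths (known D),
  rigid urea poses at prescribed (d, θ) geometry, and analytic RDF
  curves. No MD engine is required anywhere.

## Worked example

Build a 40-frame synthetic box (28 Å cube, 40 urea / 220 water, urea
enriched 3× inside a 9 Å shell) and analyze it from the shell:

```sh
$ solvshell synth --box 28 --n-urea 40 --n-water 220 --enrichment 3 \
    --shell-radius 9 --n-frames 40 --seed 7 \
    --out demo.xyz --topology-out demo_top.tsv
wrote 40 frame(s), 995 atoms; realized shell gamma 9.021

$ solvshell gamma --traj demo.xyz --top demo_top.tsv
gamma   5.6447
stderr  0.3764
frames  40
```

The builder reports Γ = 9.02 for its own construction region (molecule
COM inside the 9 Å enrichment shell), while `solvshell gamma` applies
the standard any-atom 4.5 Å local rule — a tighter region, so it sees
a smaller but still strongly positive urea excess. Both say the same
thing: urea is preferred near the solute roughly in proportion to the
enrichment factor.

```sh
$ solvshell energy --traj demo.xyz --top demo_top.tsv --discard-frac 0.2
component       mean    stderr
total   15.6197 8.1788
electrostatic   5.1526  5.8716
lennard_jones   10.4671 4.0098
```

Randomly packed (unequilibrated) configurations sit slightly uphill,
so the mean interaction energy is positive here; on relaxed input the
same command produces the usual negative solvation energies. The
number to watch in synthetic demos is the decomposition identity
(total = electrostatic + LJ, exact per frame).

```sh
$ solvshell ti --n-per-leg 100 --seed 1
forward delta_g=0.6937  stderr=0.0032
analytic        0.6931
backward        delta_g=-0.6907 stderr=0.0031
analytic        0.6931
hysteresis      0.0029  converged=True
```

The built-in λ-scaled harmonic well has the exact answer
`ΔG = (kT/2)·ln(k₁/k₀) = 0.6931` kcal/mol at kT = 1 and k₁/k₀ = 4; the
sampler recovers it to 0.1 % with forward/backward hysteresis two
orders of magnitude below |ΔG|.

Other subcommands: `rdf`, `kb`, `modes`, `density`, `dwell`, and `run`
(the full pipeline driven by a YAML config, writing TSV/cube outputs
plus a checksummed `manifest.json`).

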
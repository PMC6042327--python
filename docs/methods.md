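# Methods

This note records the models behind each module, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a maintainer would want to know.

## Coarse-grained conformers (`confgen`)

**Model.** One bead per residue at the CA position with uniform
scattering weight.  Consecutive beads are 0.38 nm apart (the CA virtual
bond); no two beads may come closer than 0.34 nm.  A protomer is grown
segment by segment: rigid segments are rigid-body transforms of a
template, flexible segments are self-avoiding walks with uniform
direction proposals (1,000 retries per bead, whole-chain restarts, and an
explicit growth-failure error — never a silent partial chain).

**Default architecture.** A 313-residue protomer: rigid N-terminal core
(1–69), linker (70–86), rigid central TPR-like domain (87–206), linker
(207–220), flexible C-terminal region (221–313).  Segment tables are
1-based inclusive and may overlap by one residue at boundaries, because
that is how construct boundaries are conventionally quoted.

**Templates.** The rigid domains use synthetic compact templates:
confined self-avoiding chains grown with fixed per-domain seeds, with
both chain termini forced near the cluster surface so linkers can attach
without threading through the interior.  The confinement radius is
`max(1.0, 0.45·N^{1/3})` nm — for 69 and 120 residues this gives clusters
of roughly the size of the corresponding folded domains.  Real
crystallographic coordinates can be substituted by registering a template
with the same residue count; nothing in the package requires them.

**Dimer states.** The two protomers are grown jointly: protomer A freely,
protomer B with A's beads as obstacles.  B's N-terminal core is placed
directly at the mandatory-contact target (center-center ≤ 3.0 nm — the
surface-touching distance for these cluster sizes; point beads cannot
interdigitate the way real helix bundles do, so the generic 1.5 nm
"in contact" default is overridden in the shipped architecture).  The two
states are then *defined*, not merely sampled:

* **closed** — the C-terminal segments' centers lie within 3.0 nm (B's
  C-tail is grown with a drift toward A's) *and* the central domains pack
  side by side (centers ≤ 4.0 nm);
* **open** — the central domains tumble independently (centers ≥ 4.4 nm)
  and the C-terminal contact is unconstrained.

The 4.0/4.4 nm gap makes the two states' TPR–TPR center-distance
supports disjoint by construction.  This mirrors the all-or-none reading
of the experimental evidence (domain tumbling either independent or
jointly slowed; closure is a discrete contact, not a continuum) and gives
the generator an unambiguous ground truth for parameter-recovery tests.
Consequences of this choice — lower ensemble Rg, shorter interlabel
distances, a sharper inter-domain P(r) peak for closed ensembles — are
*emergent but not independent evidence*; a green end-to-end test
establishes that the analysis pipelines detect the stated world's
signal, not that the real protein closes.

**Randomness.** A pool is seeded once; `SeedSequence(seed)` spawns one
child stream for the open/closed flags and one per conformer index, so
pools are bit-reproducible and any single conformer can be regenerated in
isolation.

**I/O.** CA-only PDB (chains A/B, Angstroms on disk, nanometres in
memory, factor 10) via biotite; pools as a PDB directory plus a TSV
manifest (index, Rg, closed flag, seed).

## SAXS (`saxs`)

Momentum transfer s is in nm⁻¹ throughout (`angstrom=True` on input
converts).  The Debye sum is exact up to 60,000 bead pairs; above that,
pair distances are binned at 0.02 nm (phase error ≤ s·Δr/2 ≈ 0.05 at the
widest angle used; I(0) = (Σw)² stays exact).

*Guinier*: weighted linear fit of ln I vs s², iterating the window until
`s_max·Rg ≤ 1.3` (config).  Fewer than five usable points or a
non-negative slope raise typed errors.

*IFT*: p(r) on 101 points with pinned zero endpoints, second-difference
smoothness penalty, non-negativity via active-set NNLS (a bounded
trust-region solver backs it up on ill-conditioned systems).  When α is
not supplied it is chosen by the discrepancy principle — the largest α on
a 31-point log grid whose back-transform still fits within the stated
errors (reduced χ² ≤ 1) — falling back to the L-curve corner when
nothing on the grid fits that well.  A pure corner criterion was tried
first and is kept for DEER, but on noiseless or low-noise SAXS curves
the L-curve has no corner (the residual floor is representation error,
not noise) and the discrepancy rule is the stable choice.

*Dmax estimation*: scan a grid seeded from the Guinier Rg (1.2–6 Rg),
score each IFT by reduced χ² plus a penalty for probability mass piled
just inside the outer endpoint, and return the smallest dmax from which
the score stays within `best + max(10%, one χ² unit)`.  The absolute
slack matters: once dmax is sufficient, scores fluctuate by O(1) χ²
units, and a purely relative band never plateaus.

*Porod*: `Q = ∫ s²(I−B) ds` with an `A/s⁴ + B` fit over the last decade;
the flat background B is subtracted, the `A/s_max` tail added, and the
result flagged when the extrapolated tail exceeds 20% of Q.

*EOM-style selection*: chromosomes are index multisets (repetition
allowed) of the configured ensemble size (default 50, the conventional
choice; pools default to 10,000 but every test scales down).  Population
100, 200 generations, tournament selection, single-point crossover,
mutation 0.05, elitism 10, analytic least-squares scaling inside the χ².
A GA that never improves on its seeded initial population returns the
result flagged, not an error.

## DEER (`deer`)

Dipolar constant 52.04 MHz·nm³; powder average by 1,001-point
Gauss–Legendre quadrature on x ∈ [0,1]; kernels cached on grid values.
Default r-grid 1.5–10 nm, 201 points.  Default acquisition mirrors the
reference four-pulse settings (τ₁ = 400 ns, Δτ₁ = 56 ns, τ₂ = 7–8 μs,
16 ns steps), giving ~430–490-point traces.

Background correction fits `exp(−kt)` to the final 65% of the trace
(`fit_start_fraction = 0.35`) and returns the dipolar evolution
`F = 1−λ+λS` plus the estimated modulation depth λ; k < 0 is clamped to
zero with a warning, λ < 0.08 triggers a shallow-modulation warning.
Inversion solves `min ‖KP−S‖² + α²‖LP‖²`, P ≥ 0, then renormalizes to
unit integral; α defaults to the L-curve corner (triangle method —
furthest point from the chord in normalized log–log space) over
10⁻³–10², which on DEER-type noise tracks the error-optimal α.

Known bias, deliberately not hidden: for distance modes near the
resolvable limit of the time window (≈ 7 nm at τ₂ = 8 μs) the dipolar
oscillation has not decayed inside the background window, so λ is
overestimated by a few hundredths and long modes shift slightly
downward.  The acceptance checks therefore probe λ in its valid regime
(mid-grid mode, SNR 50) and treat long-distance recovery as mode/shift
checks with grid-scale tolerances — the same failure mode any
tail-fitting analysis of such data has.

Mode statistics: peaks above a relative prominence (default 5%),
watershed mass split at inter-peak minima, masses summing to one, an
optional minimum-mass filter for reporting.

## NMR (`nmr`)

The default delay schedules are the reference 11-point
inversion-recovery (30.8…1540 ms) and 10-point CPMG (16.96…254.4 ms)
series.  Exponential fits are plain nonlinear least squares with a
log-linear initial guess; non-decaying data yields `converged=False`,
never an exception.  The isotropic τc estimate requires
`6·T1/T2 ≥ 7` and raises a typed error otherwise; ν_N is always an
explicit argument — relaxation data are field-dependent and silently
defaulting the field would invite cross-field mistakes.

Default domain ranges are 5–65 (N-terminal) and 87–206 (TPR).  The
source material prints both 206 and 205 as the TPR upper bound in
different paragraphs; 206 is used, and `n` in a domain summary counts
residues with converged T1 *and* T2 fits, so the one-residue ambiguity
only ever changes `n` by one.

CSP uses the standard `√(ΔδH² + (0.14·ΔδN)²)` amide weighting; CSI calls
helix where a 4-residue window exceeds +0.7 ppm (Cα) and +0.5 ppm (CO)
against the shipped random-coil table, with gaps preserved as
`undetermined` (never interpolated).  All three thresholds are arguments.

The relaxation generator inverts the τc equation exactly: per domain it
fixes T1 (default 1.2 s) and sets `T2 = 6·T1/(7 + (4πν_N τc)²)`, so the
noiseless round trip is the identity by construction and noisy runs have
a known truth.  It emulates per-residue intensity decays only — no
chemical-exchange broadening, no anisotropic tumbling, no per-residue
τc variation within a domain.

## Native MS (`massdeconv`)

Positive-ion mode, proton mass 1.00728 Da, centroided peak lists.
Charge series are found by testing every peak pair's consecutive-charge
hypothesis (50 ppm default tolerance), extending by predicted m/z, and
keeping only the consecutive-charge run containing the seed pair — the
guard that suppresses charge harmonics (an n-mer explains every second
charge of its submultiples).  Series are peeled off greedily by total
intensity, regenerating candidates from unassigned peaks after each
acceptance.  Ladder detection grid-searches the increment at 1 Da
resolution over 100–1,000 Da, requires ≥ 3 gap-free rungs starting at 0
or 1, and accepts when the rung residual SD is below 10 Da — a threshold
set so that unrelated random masses pass in well under 5% of cases (the
suite measures this on 1,000 seeded draws).

## Virtual experiment (`workbench`)

A run builds an open reference ensemble and a scenario ensemble at seeds
derived from one master seed (`SeedSequence.generate_state`, one stream
per stage, logged in the report), simulates all four data types, and
evaluates the four closed-state signatures with configurable margins:
P(r) inter-domain peak ratio > 1.1; EOM compaction > 0.25 pool-SD;
Δτc(TPR) > 0.5 ns; DEER mode shortening > 0.2 nm.  The open scenario
reuses the reference ensemble, so its self-comparison is exactly null.
Scenario-dependent generator settings follow the motivating system: TPR
τc 9.5 ns open vs 12 ns closed (N-terminal domain 10.5 ns in both), a
34 kDa monomer, and a ~370 Da adduct at stoichiometries 0–4 in the
closed-competent scenario.  Reports are JSON with sorted keys and
rounded stage metrics, and regenerate byte-identically from the same
config; `compare_reports` differences the oriented effect sizes, so
comparing a closed run against an open run from the same seeds
reproduces the closed run's internal deltas.

Scaling: the shipped defaults (ensembles of 30, pools of 60) and the
test settings (12/20) are deliberately far below a production pool of
10,000 conformers; every stage is O(n) in pool size, and nothing in the
logic depends on the scale.

## Known limitations

* Point-bead excluded volume understates real steric bulk; contact
  distances are therefore geometry-matched parameters, not predictions.
* The SAXS forward model has no hydration shell or atomic form factors —
  fine for bead-model inference, not for fitting real curves at high s.
* DEER omits excitation-bandwidth and orientation-selection corrections
  and multi-spin effects; the label is placed at the CA, with no rotamer
  model.
* The τc model is strictly isotropic.
* MS simulation draws a Gaussian charge envelope with ppm-scale m/z
  jitter; no isotope structure, no peak overlap resolution.
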
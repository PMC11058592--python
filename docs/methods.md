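# Methods

This note documents the models, defaults, and numerical choices behind
`loopshift`, and what the synthetic-data generator does and does not
emulate.

## Data model and geometry

Ensembles are rectangular arrays of coordinates in Å indexed by
`(replica, frame, atom, xyz)` bound to one topology. Residues are keyed by
`(chain_id, residue_index)`; insertion codes are rejected rather than
silently merged. HETATM records are read as ordinary atoms, because the
systems this package targets include non-standard chemistry (e.g. a
phospho-cysteine intermediate).

Superposition is the weighted least-squares Kabsch construction via SVD
with the determinant correction, so reflections are never returned.
Weights are unit by default, matching common Cα-RMSD practice; mass
weighting is opt-in. Sets of fewer than 3 atoms, or collinear sets, raise
an error rather than returning one of the degenerate solutions.

**Loop RMSD uses a fit/measure split**: frames are superposed on all
non-loop Cα atoms and RMSD is measured over the loop Cα atoms. Fitting on
the rigid scaffold isolates loop motion from global tumbling; fitting on
the loop itself would absorb exactly the motion being measured. The fit
set is echoed in output metadata. A consequence worth knowing: atoms
*inside* the fit set have a small part of their fluctuation absorbed by the
6 rigid-body degrees of freedom (a ~`sqrt(1 - 2/n)`-scale shrinkage that
grows with the atom's leverage about the centroid). Closed-form checks in
the test suite therefore plant noise on atoms outside the fit set.

Backbone dihedrals follow the IUPAC sign convention (verified against an
independent library implementation) in `(−180°, 180°]`. The Ramachandran
mask is deliberately coarse — three favored boxes (β, right- and
left-handed α) dilated by 20° for the allowed region — because downstream
use only needs a disallowed / not-disallowed call; the mask is a swappable
dataclass.

## State labeling and populations

Each frame's loop Cα-RMSD to the three reference conformations is computed;
the candidate state is the argmin and is accepted if its RMSD is at or
below the state's cutoff, else the frame is `other`. Ties break with the
fixed priority closed > open > wide_open, so labeling is deterministic and
auditable. Cutoffs default to 1.5 Å for all three states — the same
threshold used for the "fraction of frames within 1.5 Å of closed"
stability statistic (which is inclusive: ≤) — and are mandatory,
echoed-into-output configuration. `other` frames are excluded from all
state-conditioned statistics.

Histograms anchor their bin edges at 0 Å with a 0.16 Å default width so
bin boundaries are reproducible across runs and variants. Populations are
reported per replica and pooled, with the between-replica standard
deviation over `sqrt(n_replicas)` as the standard error: replicas, not
frames, are the statistical unit throughout, because frames within a
replica are autocorrelated.

The closure analysis averages the RMSD-to-closed and a catalytic
side-chain COM distance over a terminal window (defaulting to the last
5 ns worth of frames) and tabulates closed vs productive per replica; both
cutoffs are required configuration.

## Flexibility statistics

Per-replica RMSF uses a two-pass mean-structure alignment (superpose on
the scaffold fit set to the running mean, recompute the mean, re-superpose)
and reports `RMSF_i = sqrt(<|r_i − <r_i>|²>)` per residue. Variants are
compared residue-by-residue with a two-sided t-test over replicate RMSF
values. **Welch's test is the default**: replicas of different variants
carry no equal-variance guarantee; Student's pooled test is available for
exactness checks. Zero variance in both groups with equal means yields
p = 1 by convention.

Benjamini–Hochberg is applied over *all* residues tested (m = number of
residues), not a pre-filtered subset, at a 5% FDR default. The
implementation is the standard step-up with monotone-adjusted q-values; the
test suite checks it against an independently coded brute-force evaluation
of the step-up definition. Structure projections write significant ΔRMSF
values into the B-factor column and 0.00 for non-significant residues, so
they render white in the usual blue–white–red coloring.

## Interaction networks

Hydrogen bonds: donor–acceptor heavy-atom distance ≤ 3.5 Å and D–H···A
angle ≥ 135° (defaults; both are config echoed into outputs, since no
single criterion is canonical). Donors/acceptors come from per-residue
atom-name tables with an element-based fallback for non-standard residues;
**proline backbone N is never a donor** (it has no amide hydrogen). A
heavy-atom-only mode (distance criterion only) serves hydrogen-free
reduced models; the mode is recorded in output metadata. Contacts are
residue pairs with any sidechain heavy-atom distance ≤ 4.5 Å; oppositely
charged groups within 4.0 Å are flagged as salt bridges.

Occupancy is the fraction of a state's frames in which an interaction is
detected, with the per-replica breakdown retained for spread estimates.
Network differences are occupancy deltas within one state, ranked by
|delta| with a deterministic tie-break on the canonical key. Keys order
their partners by `(chain, residue_index)` and omit residue *names*, so
variants that differ by loop substitutions join by position. This module
is a transparent occupancy-difference analysis: deterministic,
oracle-checkable, and sufficient to express hydrogen-bond gains/losses
between variants; it does not attempt feature-importance scoring.

## EVB and LRA

The reaction is two diabatic states; sampling windows follow the linear
mapping potential `E_m = (1−λ_m)E1 + λ_m(E2+α)` over a ladder spanning
λ = 0..1 (51 windows by default). Window-to-window free energies are
Zwanzig exponential averages computed with a log-sum-exp guard, reported
bidirectionally (forward/reverse hysteresis is a sampling diagnostic). The
ground-state profile along the gap `x = E1 − E2′` (E2′ = E2 + α) is the
standard umbrella correction
`Δg(b; m) = ΔG_m − kT ln <1{x∈b} exp(−(E_g − E_m)/kT)>_m`, combining
overlapping windows by frame-count weighting (WHAM-style iteration is a
possible refinement, deliberately out of scope). Bins with fewer than 10
frames are dropped. kT uses T = 298 K by default.

**Barrier extraction** splits the profile at the diabatic crossing, which
sits at x = 0 by construction: the reactant basin is the profile minimum
over x < 0, the product basin the minimum over x ≥ 0, and ΔG‡ is the
maximum between them relative to the reactant minimum. Side-wise global
minima were chosen over a local-minima scan because sparsely sampled tail
bins show noise dips that a leftmost-local-minimum rule mistakes for
basins, systematically understating the barrier. With zero coupling the
barrier top is a cusp and finite gap bins smear it; resolving the crossing
height to better than a few percent needs ~300 bins instead of the default
100.

LRA group contributions use the endpoint half-sum convention
`ΔΔG‡_i = ½[⟨u_i^TS − u_i^RS⟩_RS + ⟨u_i^TS − u_i^RS⟩_TS]/ε_in` with both
charge-set evaluations required on both endpoint ensembles and ε_in = 4 by
default, recorded in the output. Contributions are exactly additive: the
sum over residues equals the functional applied to per-frame totals.

## Synthetic data: what it emulates, what it does not

The generator is built for exact ground truth, not physical realism. A
discrete Markov chain over loop states drives which reference each frame is
built from; frames are that reference plus independent per-atom Gaussian
noise. Reference geometries are a helical Cα scaffold with the loop
displaced along a smooth arc — 0 (closed), half scale (open), and the full
~10 Å scale (wide-open) — matching the displacement magnitude of the loops
this package targets, not their actual shape.

Defaults are the study conditions: 15 replicas × 5,000 frames at a 100 ps
stride, 0.3 Å per-axis noise, a 60-residue scaffold with a 10-residue loop
(span 25–34), and a closed-dominant default chain. `sticky_transition_matrix`
builds a reversible chain with an *exactly* prescribed stationary vector
(off-diagonals proportional to the target stationary, detailed balance by
construction), so population recovery can be tested against a closed form;
mobility 0.05 gives state dwell times of tens of frames, qualitatively like
the slow loop transitions seen in long simulations. Frames are generated at
the analysis stride, so positional noise carries no autocorrelation — state
persistence is the only temporal structure. Consequently, passing tests
demonstrate correctness of the estimators under known truth; they do not
demonstrate robustness to force-field artifacts, incomplete convergence,
or correlated solvent-coupled motions of real trajectories.

Planted hydrogen bonds place the acceptor exactly 2.9 Å from the (noisy)
donor with the rule's probability and 8 Å away otherwise, making per-frame
detection deterministic and recovered occupancy exactly binomial. Diabatic
ladders are Metropolis samples of 1-D harmonic diabats (defaults
k = 30 kcal/mol/Å², minima at ±1 Å, H12 = 3, ΔE = 0 → a ~12 kcal/mol
adiabatic barrier, enzyme-like); the proposal width defaults to 2.4 thermal
widths (empirical acceptance ≈ 0.4–0.5), 200 burn-in steps are discarded,
and a dense-grid evaluation of the analytic ground surface provides the
independent barrier oracle. For a 1-D coordinate the potential of mean
force equals the ground surface exactly, so the oracle is exact up to grid
resolution.

The multiple-testing calibration study draws replicate RMSF values
directly from their exact sampling distribution (`sigma·sqrt(chi²_{3(F−1)}/F)`,
times a lognormal between-replica multiplier emulating finite-sampling
heterogeneity) instead of simulating hundreds of full coordinate
ensembles. Under the null both variants share one distribution, so t-test
p-values stay calibrated by construction; the coordinate route is
exercised end-to-end by the other tests.

Seeding: one integer seed fans out via `numpy.random.SeedSequence.spawn`
to per-replica and per-stage streams; every generator output is
bit-identical under a repeated (spec, seed).

## Problem sizes

The test suite and the acceptance script run at 15 × 5,000 frames for the
ensemble-scale properties (state recovery, population-shift separation),
200 simulations for the FDR calibration, 50 seeded runs for interaction
rank recovery at 3 × 250 frames each, and 20 seeds × 51 windows × 1,000
samples for the EVB barrier study — sizes at which the targeted
statistical tolerances (3 SE bands, 2% closed-form agreement, ≥95% rank-1
recovery) are meaningful.

## Known limitations

- No periodic-boundary imaging, no solvent handling, no binary trajectory
  formats (DCD/XTC adapters would be straightforward additions).
- The umbrella estimator's count-weighted window combination is simple and
  transparent but statistically suboptimal relative to WHAM/MBAR.
- Markov-state-model estimation and kinetic rates are out of scope by
  design; the state chain here is a generator device, not an estimator.
- Hydrogen-bond criteria are geometric only; no energetic or
  orbital-overlap refinement.
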
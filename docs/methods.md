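# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the design choices made where the problem is genuinely
open, and what the synthetic-data generators do and do not emulate.

## Structure model

PDB text is parsed with gemmi into an ordered residue/atom model. Author
residue numbering is kept exactly as written (the same numbering used in
mutation notation such as `S67G`); nothing is renumbered. Waters are always
dropped; other HETATM groups are excluded by default and retained with
`include_hetero=True`. Alternate locations are resolved per atom name:
highest occupancy wins, ties go to the first-listed conformer (`"first"`
selects the first conformer unconditionally). Only the first MODEL of a
file is read as a structure; multi-model files are trajectories. All
internal coordinates are Å.

Distance primitives use minimum pairwise heavy-atom Euclidean distance.
`residues_within(center, cutoff)` is inclusive at the cutoff and always
contains the center residues. Hydrogens, when present, are kept in the
model but excluded from heavy-only distances, so results do not depend on
whether a structure was deposited with protons.

## Interaction detection

Crystal structures of this resolution class rarely carry hydrogens, so the
hydrogen-bond criterion is distance-only by default: a donor-capable N/O
within `hbond_max` = 3.5 Å of an acceptor-capable N/O, residues at sequence
separation ≥ 2 in the same chain (inter-chain pairs always eligible). When
the donor carries explicit hydrogens, the best D–H···A angle must
additionally be ≥ 120°. Donor/acceptor capability is a static per-residue
atom table (backbone N donates except in Pro, backbone O accepts; side
chains per standard chemistry, e.g. Ser OG both, Lys NZ donor, carboxylate
O acceptor). No protonation-state modelling is attempted.

Salt bridges pair a side-chain nitrogen of Lys/Arg/His with a side-chain
carboxylate oxygen of Asp/Glu within `sb_max` = 4.0 Å. His is included on
the basis that it can be protonated at assay pH; excluding it only removes
candidate interactions.

Hydrophobic clusters are connected components, of size ≥ 3, of the graph
whose edges join apolar residues ({A,V,L,I,M,F,W,P,Y}) with side-chain
heavy-atom minimum distance ≤ `hc_max` = 5.0 Å. The size-3 floor reflects
that anything smaller is a contact, not a cluster.

Wild-type/variant differencing compares interaction sets keyed by
(kind, donor partner, acceptor partner). At mutated positions the residue
type — and hence its atom names — changes between models, so interactions
there are compared at residue granularity; everywhere else exact atom
identity is required. The two models must share residue numbering; the
differ takes both structures as given and performs no relaxation, so a
"gained" bond on raw substituted models reflects the models supplied, not a
minimized prediction.

## Triage

Criteria are evaluated strictly in the order consensus → catalytic
proximity → critical interactions, and an excluded candidate records the
first criterion it failed, which makes exclusion reasons reproducible.

* Consensus is counted at the *site* level: any substitution at a position
  counts as that predictor's support for the position.
* Catalytic proximity uses all heavy atoms of the candidate residue against
  all heavy atoms of each catalytic residue — the most conservative
  computable reading of "within 5 Å". The catalytic residue set is always
  user-supplied configuration; the package never infers active-site
  residues.
* The critical-interaction criterion is deterministic rather than
  judgment-based: a substitution fails only if the wild-type side chain
  participates in a detected (or explicitly listed) hydrogen bond or salt
  bridge *and* the new residue type lacks the required capability
  (donor/acceptor for hydrogen bonds, charge sign for salt bridges) at the
  residue level. A `flag_only` mode marks instead of excluding, for
  workflows where a human wants to adjudicate. Because the criterion as
  practised in engineering campaigns involves discretionary judgment, exact
  reproduction of any particular published candidate count is not asserted;
  correctness is established against planted truth instead.

Ranking of measured singles applies a relative-activity floor (default 90%
of wild type), sorts survivors by residual activity descending with ties
broken by relative activity then position, and appends below-floor
variants after the survivors rather than dropping them.

## Stacking and epistasis

The planner is order-preserving and greedy: step *k* adds the *k*-th ranked
single to the cumulative set, labelled `Mu1…Mun`; one substitution per site
is enforced. It does not search subsets. The epistasis flagger compares
each step's metric (half-life, T_m, or relative activity) against the
previous step (or a `WT` baseline when present): NEGATIVE if lower,
NEUTRAL if equal within tolerance, else POSITIVE. The NEUTRAL band uses
the metric's reported uncertainty when supplied, else 1% relative — the
scale of replicate-to-replicate variation in these assays. Flags describe
the measured series; no spatial or mechanistic cause is asserted.

## Trajectory metrics

Superposition is closed-form unweighted Kabsch (SVD with a determinant
correction so the rotation is proper). Near-collinear point sets raise a
degeneracy error rather than returning an arbitrary rotation. Default
selection for RMSD and RMSF is Cα, the common MD-analysis convention; the
reference for RMSD is the first frame unless an external reference is
supplied.

RMSF uses an iterative mean-structure procedure: frames are superposed on
the running mean of the selection, the mean is recomputed, and the loop
stops when the mean drifts < 10⁻⁶ Å (max 10 iterations). This removes the
bias of fitting to an arbitrary single frame. Per-atom RMSF is aggregated
per residue by averaging over selected atoms. The equilibration skip
defaults to 0 frames — the package analyzes whatever production ensemble
it is given.

R_g is mass-weighted by default (standard atomic weights) and reported in
nm; SASA totals are reported in nm². Both are computed in Å internally and
converted at the reporting boundary (1 nm = 10 Å), matching how MD analysis
plots conventionally present them while keeping PDB-native units inside.

SASA is Shrake–Rupley: for each heavy atom, `n_points` = 960 quasi-uniform
sphere points (a deterministic golden-spiral lattice, so results are
reproducible without a point-set RNG) are placed at radius r_vdw + probe
(Bondi radii; probe 1.4 Å); the exposed fraction times 4πr² is the atom's
area. Neighbour search is a k-d tree query bounded by the sum of expanded
radii. Doubling the point count moves a lone-atom value by well under
0.5%; the packaged tests also verify the two-sphere overlap case against
the closed-form spherical-cap area and against an independent
implementation (mdtraj) with matched radii. Unknown elements fall back to
a configurable radius (default 1.70 Å) with a warning.

## Assay models

* **Inactivation**: first-order loss, A(t) = 100·e^(−kt), fitted by
  nonlinear least squares seeded from a log-linear regression;
  t₁/₂ = ln 2 ⁄ k. First-order decay is the standard single-parameter model
  behind published half-life tables; a model-free linear interpolation of
  the first 50% crossing is available where the data visibly deviate from
  exponential behaviour. Non-decaying data yield a warning and an infinite
  half-life rather than an exception.
* **DSF melt curves**: the Boltzmann sigmoid
  F(T) = F_min + (F_max − F_min)/(1 + e^((Tm−T)/s)) is fitted on the
  ascending limb only — the curve is truncated at its global fluorescence
  maximum, standard DSF practice to discard post-peak aggregation decay.
  The derivative method (T at the maximum of dF/dT over the ascending limb)
  serves as a cross-check; on symmetric transitions the two agree within a
  temperature step.
* **Kinetics**: v = V_max·S/(K_m+S) by nonlinear least squares. K_m is
  reported in whatever units the substrate concentrations carry; the
  package never converts substrate units silently. k_cat is derived only
  when the caller supplies a molar mass (k_cat = V_max·M/60000 for V_max in
  µmol·min⁻¹·mg⁻¹ and M in g/mol) — back-calculating a molar mass from
  published k_cat values is deliberately not done. Non-saturating data
  (fitted K_m above the highest tested concentration) trigger a warning.
* **Units and conversion**: 1 U = 1 µmol reducing sugar per minute;
  specific activity is U/mg. Conversion assumes chitobiose is the sole
  product (the dominant product of these chitinases), one reducing end per
  dimer, M = 424.40 g/mol; conversions above 100% are reported with a
  warning, not clipped.
* **Reusability**: cycle tables carry declared semantics — `accumulation`
  (each value is the running total in the reused system; cumulative = final
  value) or `per_cycle` (cumulative = sum) — because reported multi-cycle
  yields are ambiguous between the two. Fold is cumulative over the
  first-cycle value.

## Synthetic data

The generators exist to make every pipeline stage testable against known
truth at desk scale; all use `numpy.random.default_rng` with an explicit
seed and no global state, and identical (seed, parameters) reproduce
byte-identical output.

* **Structures** place residues in spatially isolated pockets ~40 Å apart
  so the only interactions present are the planted ones, with exact planted
  distances: Ser OG → Asn OD1 at 2.9 Å for hydrogen bonds; Lys NZ → Glu OE1
  at 3.8 Å for salt bridges (outside the H-bond cutoff, inside the
  salt-bridge cutoff, so feature counts never overlap); Leu rings with
  4.6 Å CB contacts for hydrophobic clusters; and single-atom catalytic
  residues with candidate residues whose nearest atom sits at an exactly
  specified distance. Background residues are glycines on a distant grid
  with small positional jitter. Idealized geometry is intentional:
  backbones are decorative, side chains are minimal, and no chemical
  realism (bond lengths, sterics, folding) is claimed.
* **Predictor tables** fix per-predictor proposal counts and the number of
  triple/pairwise-overlap sites, so the post-merge consensus counts — and
  hence the expected kept set under the consensus criterion — are known a
  priori.
* **Trajectories** displace every atom independently with isotropic
  Gaussian noise (background σ, elevated σ inside named residue-number
  regions), optionally composed with a per-frame random rigid motion that
  a correct superposition must remove. The implied per-atom RMSF is
  σ·√3, recorded in the truth sidecar.
* **Assay curves** come from the same models the fitters assume
  (first-order decay, Boltzmann sigmoid, Michaelis–Menten, geometric cycle
  growth) with optional Gaussian noise.

Because the assay generators share their functional form with the fitters,
zero-noise recovery tests establish correctness of the fitting machinery,
not robustness to model misspecification; the noisy-recovery tests
(multiplicative 5% noise, 200 seeded replicates, median error < 5%) probe
statistical behaviour but still within the generating model. Likewise the
trajectory generator's independent Gaussian displacements have no temporal
correlation, solvent, or anharmonicity, so passing tests demonstrate the
estimators' correctness, not agreement with any particular physical
simulation. Published ensemble statistics from long production MD runs are
not reproducible at this scale and are not asserted anywhere in the suite.

## Problem sizes and numerical choices

Tests run on 20–60-residue toy structures, trajectories of up to 2000
frames of ~100 atoms, and assay curves of 5–80 points; the full suite
completes in a few seconds on one CPU. Curve fits use
`scipy.optimize.curve_fit` with physically motivated initial values
(log-linear slope for decay rates; half-rise temperature for T_m; 1.5× the
maximum rate and the median concentration for kinetics). Ties in the
optimal-temperature scan resolve to the lower temperature with a warning.
Kabsch degeneracy is declared when the second singular value falls below
10⁻¹⁰ of the first.

## Known limitations

* Interaction detection is geometric only: no energies, no π-stacking,
  cation–π, or disulfide analysis, and no electrostatic surface modelling
  beyond side-chain charge bookkeeping.
* The capability rule is residue-typed, not conformation-aware: it asks
  whether the new side chain could in principle sustain the interaction,
  not whether it does in a modelled structure.
* Trajectory input is multi-model PDB; binary MD formats require external
  conversion.
* mmCIF parsing, structure prediction, docking, and MD simulation itself
  are out of scope.
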
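# thermotriage

Computational support for protein thermostability engineering campaigns,
built around the workflow used to stabilize microbial glycoside hydrolases
such as the chitinase BcChiA1: triage candidate point mutations proposed by
stability predictors against a 3D structure, stack the validated singles
stepwise while watching for epistasis, and analyze both the structural
models (interaction changes, MD stability metrics) and the wet-lab assay
data (half-lives, melting temperatures, Michaelis–Menten kinetics,
substrate conversion, reusability) that such a campaign produces.

It is a library first — plain functions over validated dataclasses — with a
thin `thermotriage` command-line tool on top, and a seeded synthetic-data
module that can generate every input class with planted ground truth, so
the whole pipeline is testable end to end without external downloads.

## What it computes

**Variant triage.** Candidate tables from several stability predictors
(e.g. PROSS, FireProt 2.0, ABAUCS — running them is out of scope; their
output tables are the input) are merged per site and filtered by three
exclusion criteria, in order:

1. *consensus* — sites proposed by fewer than `min_predictor_support`
   (default 2) predictors are excluded;
2. *catalytic proximity* — sites whose minimum heavy-atom distance to a
   user-supplied catalytic residue set is ≤ 5 Å are excluded;
3. *critical interactions* — a substitution is excluded when the wild-type
   side chain participates in a detected hydrogen bond or salt bridge and
   the new residue lacks the donor/acceptor/charge capability to sustain it
   (so K→R survives at a salt-bridge position; K→A does not).

**Stacking and epistasis.** Measured singles are ranked by residual
activity subject to a relative-activity floor; the planner builds the
greedy series Mu1 ⊂ Mu2 ⊂ … and, given a measured stability series, flags
each added mutation POSITIVE / NEUTRAL / NEGATIVE. A drop at step *k*
marks negative epistasis of the added mutation in the context of the stack.

**Structure analysis.** PDB parsing (via gemmi) into a validated atomic
model; minimum-distance and neighbourhood queries; geometric detection of
hydrogen bonds (donor–acceptor heavy-atom distance ≤ 3.5 Å, with a D–H···A
angle test when hydrogens exist), salt bridges (N⁺···O⁻ ≤ 4.0 Å), and
hydrophobic clusters (connected components, size ≥ 3, of the side-chain
contact graph over {A,V,L,I,M,F,W,P,Y} at ≤ 5 Å); and set-differencing of
interactions between wild-type and variant models.

**Trajectory metrics.** From multi-model PDB ensembles: per-frame RMSD
after optimal Kabsch superposition (Å), per-residue RMSF about the
iteratively refined mean structure (Å), mass-weighted radius of gyration
R_g (nm), and Shrake–Rupley solvent-accessible surface area (nm²), plus
per-region RMSF summaries for comparing flexible segments between wild
type and variant.

**Assay analytics.** First-order inactivation fits A(t) = 100·e^(−kt) with
t₁/₂ = ln 2 ⁄ k; Boltzmann sigmoid fits of DSF melt curves for T_m;
Michaelis–Menten fits v = V_max·S/(K_m+S) with k_cat = V_max·M/60000 when a
molar mass is supplied and efficiency k_cat/K_m; enzyme units (1 U = 1 µmol
reducing sugar · min⁻¹); substrate conversion on the chitobiose basis
(M = 424.40 g/mol, one reducing end per dimer); and reusability summaries
over reaction cycles (cumulative yield, fold vs first cycle).

## Worked example

```python
import numpy as np
from thermotriage import (
    fit_half_life, fit_tm, fit_michaelis_menten, delta_tm,
    plan_stepwise, flag_epistasis, Mutation,
)
from thermotriage.synthetic import make_decay_curve, make_melt_curve, make_kinetics

tc, _ = make_decay_curve(seed=1, t_half=295.0, times=np.arange(0, 301, 30))
half = fit_half_life(tc)
print(f"t1/2 = {half.t_half:.1f} min  (k = {half.k:.5f} min^-1)")

tm_wt = fit_tm(make_melt_curve(seed=1, tm=50.0)[0]).tm
tm_mu = fit_tm(make_melt_curve(seed=1, tm=60.0)[0]).tm
print(f"Tm(WT) = {tm_wt:.1f} C, Tm(variant) = {tm_mu:.1f} C, "
      f"dTm = {delta_tm(tm_mu, tm_wt):.1f} C")

kd, _ = make_kinetics(seed=1, vmax=28.63, km=5.31)
mm = fit_michaelis_menten(kd, molar_mass=20000.0)
print(f"Vmax = {mm.vmax:.2f} umol/min/mg, Km = {mm.km:.2f} mg/mL, "
      f"kcat = {mm.kcat:.2f} s^-1, kcat/Km = {mm.efficiency:.2f}")

ranked = [Mutation.parse(m) for m in
          ["N257Y", "N271E", "K177R", "S67G", "A220V", "A279V"]]
plan = plan_stepwise(ranked)
series = {"WT": 5, "Mu1": 13, "Mu2": 27, "Mu3": 42,
          "Mu4": 116, "Mu5": 295, "Mu6": 275}
for f in flag_epistasis(plan, series, metric="t_half"):
    print(f"{f.label}: {f.flag}  (t1/2 {f.value:.0f} min, change {f.delta:+.0f})")
```

prints

```
t1/2 = 295.0 min  (k = 0.00235 min^-1)
Tm(WT) = 50.0 C, Tm(variant) = 60.0 C, dTm = 10.0 C
Vmax = 28.63 umol/min/mg, Km = 5.31 mg/mL, kcat = 9.54 s^-1, kcat/Km = 1.80
Mu1: POSITIVE  (t1/2 13 min, change +8)
Mu2: POSITIVE  (t1/2 27 min, change +14)
Mu3: POSITIVE  (t1/2 42 min, change +15)
Mu4: POSITIVE  (t1/2 116 min, change +74)
Mu5: POSITIVE  (t1/2 295 min, change +179)
Mu6: NEGATIVE  (t1/2 275 min, change -20)
```

The half-life fit recovers the planted 295 min decay exactly; the melt
fits recover the planted transition midpoints, giving a 10 °C stabilization
of the variant; the kinetics fit recovers V_max and K_m and derives
k_cat = 9.54 s⁻¹ and an efficiency of 1.80 mL·mg⁻¹·s⁻¹ at a 20 kDa molar
mass; and the epistasis flagger marks the final stacking step NEGATIVE —
the added sixth mutation lowered the measured half-life of the stack.

The same operations are available from the shell, e.g.

```bash
thermotriage synth structure --seed 3 --out demo/
thermotriage interactions demo/structure.pdb
thermotriage triage --structure demo/structure.pdb \
    --candidates a.tsv --candidates b.tsv --catalytic A:13
thermotriage halflife decay.tsv
```

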
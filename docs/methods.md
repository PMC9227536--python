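# Methods

`pbpkcat` implements a bottom-up, cross-species physiologically-based
pharmacokinetic (PBPK) workflow for IDP-73152, an aminopiperidine peptide
deformylase inhibitor. "Bottom-up" means every disposition parameter is
derived from in-vitro assays and physiology; only two absorption scale
factors are estimated from in-vivo data. This note records the model, its
assumptions, the parameter choices that were genuinely open, and the known
limitations.

## From assay to parameter

**Permeability.** The apparent Caco-2 permeability is
`Papp = (dQ/dt) / (C0 · A)`, with `dQ/dt` the OLS slope of cumulative
receiver amount versus time. Sink conditions are assumed (no
donor-depletion correction) and all receiver samples, including t = 0,
enter the slope. The efflux ratio is `Papp(B→A)/Papp(A→B)`; values below 2
argue against active efflux.

**Binding and partitioning.** Equilibrium-dialysis unbound fraction is the
buffer:sample chamber concentration ratio. The blood:plasma ratio is
`BP = C_plasma,ref / C_plasma`. The erythrocyte:plasma partition
coefficient follows the blood mass balance `BP = (1 − Hct) + Hct · EP`,
i.e. `EP = 1 + (BP − 1)/Hct`; this is the only form under which the
composite volume equation interconverts blood- and plasma-referenced
quantities consistently.

**Intrinsic clearance.** Depletion courses are assumed first order; the
rate constant is the negative OLS slope of ln C versus time (unweighted —
the sparse 4-point designs give no basis for weighting; fits with
r² < 0.90 are flagged). Incubation-level clearance scales as
`k · V / (mg protein)` (microsomes) or `k · V / (10⁶ cells)` (hepatocytes),
and to the whole organ via

    CLu,int,H = CLint/fu,inc · (MPPGL or HPGL) · V_liver · ρ · 60/10⁶   [L/h]

with MPPGL 45 (animals) / 39.8 (human) mg/g, HPGL 120 ×10⁶ cells/g (rat)
and liver density 1.07 g/mL.

**Hepatic clearance.** The well-stirred liver model gives the
plasma-referenced organ clearance

    CLh = QLI·BP·fu,p·CLu,int,H / (QLI·BP + fu,p·CLu,int,H)

bounded above by the flow ceiling QLI·BP; the extraction ratio is
`ER = CLh/(QLI·BP)`. In the rat only, a whole-blood degradation clearance
`CLblood = k_blood · V_blood · BP` adds to plasma clearance (about 2% of
it; the compound is blood-stable in the other species).

## Distribution

Tissue partitioning rests on steady-state tissue:plasma ratios (Kp,ss)
measured in rats after a 10 h constant-rate infusion, not on
tissue-composition predictions (a Rodgers–Rowland-type calculation
grossly overpredicts the in-vivo volume for this compound and is a
non-goal). Other species reuse the rat table under the assumption that
Kp,ss/fu,p is conserved. The composite steady-state volume is

    Vss = Vp + Vrbc·EP + Σ V_T,i · Kp,ss,i        (plasma-referenced)

For the liver — the eliminating organ — the measured ratio understates
true partitioning, so the PBPK-operative coefficient is
`Kp,LI = Kp,ss,LI / (1 − ER)`.

## Whole-body model

Ten perfusion-limited tissues (adipose, brain, heart, kidney, liver, lung,
muscle, skin, spleen, testis) hang between arterial and venous blood
pools with the lung in series. Non-eliminating tissues obey
`V_T dC_T/dt = Q_T (C_art − C_T·BP/Kp_T)`. Splenic venous outflow routes
through the liver as a stand-in for portal drainage (the model has no gut
tissue compartment); the liver receives hepatic-arterial plus splenic
inflow and eliminates at `fu,p·CLu,int,H·C_LI/Kp,LI`. Absorbed drug
enters the liver directly (hepatic first pass, no gut-wall metabolism).
Plasma concentration is venous blood concentration divided by BP. Because
the liver inflow topology is not uniquely determined by the compartment
list, the structure is *pinned by oracles* in the test suite: simulated
IV dose/AUC must equal CLh + CLblood, steady-state tissue:plasma ratios
must recover the input Kp (and Kp,ss,LI for liver), and total mass must
balance to 0.1%. Any structural error breaks at least one of these.

Oral absorption uses a compartmental absorption and transit (CAT) chain:
stomach plus three small-intestinal and two large-intestinal segments,
first-order gastric emptying Ks, segmental transit Kt,i and absorption
ka,i; transit out of the last segment is fecal loss, and the asymptotic
absorbed fraction has the closed form `Fa = 1 − Π Kt,i/(Kt,i + ka,i)`.
The human segmental rate constant comes from the Caco-2 permeability via
the empirical correlation `log Peff = 0.4926·log Papp − 0.1454` (Papp in
10⁻⁶ cm/s, Peff in 10⁻⁴ cm/s — the convention of the jejunal-perfusion
permeability scale; applied in raw cm/s the correlation returns a
physiologically impossible Peff ≈ 4×10⁻³ cm/s and ka ≈ 20 h⁻¹) and
`ka = 2·Peff/R` with R = 1.53 cm. Animal segments scale by a fitted
interspecies factor SF (segments 1–3 in rodents, all five in dogs), and
rodent large-intestinal segments additionally by ASF — the slow colonic
absorption that produces the observed flip-flop kinetics. SF = ASF = 1 in
humans by construction.

## Parameter registry and provenance

Constants live in two YAML registries with per-constant provenance
comments. Two groups deserve note:

* **Assay-implied liver volumes and flows.** The detailed physiological
  appendix of the original study is not available, so liver volumes are
  backed out of the reported whole-liver intrinsic clearances (human
  1.47 L; rat 15.74 mL — about twice the anatomical size of a 200 g rat
  liver, which is retained because the whole derived-parameter chain is
  internally consistent with it; the literature fraction ships alongside
  and is selectable). Liver blood flows are likewise backed out of the
  reported CLh/ER pairs (rat 4.88, mouse 10.18, dog 3.46 L/h/kg, human
  87 L/h at 70 kg); generic reference flows do not reproduce the reported
  extraction ratios.
* **Transit constants.** Human: Ks 2.8 h⁻¹, small-intestinal Kt 3/3.32 h⁻¹
  per segment, colonic Kt 2/13.5 h⁻¹ per segment. Animal values are
  standard fasted transit-time figures (rat/mouse small-intestinal
  residence 1.5 h, colonic 7 h; dog 2 h and 12 h; gastric emptying 4, 6
  and 2.5 h⁻¹ for rat, mouse, dog). All are overridable; oral exposure
  predictions inherit their uncertainty, which is why the oral
  acceptance tolerances are wider than the IV ones.

Remaining defaults: hematocrits 0.45/0.46/0.42/0.45 (mouse/rat/dog/human);
body weights 0.02/0.2/10/70 kg (the human weight is a convention); blood
volumes 80/65.5/82/79 mL/kg (the rat value is the measured 13.1 mL per
200 g); tissue volumes are Davies & Morris / Brown-style fractional organ
weights. With these, the composite rat Vss evaluates to 2.08 L/kg and the
human value to 1.56 L/kg — no per-tissue tuning was applied.

## Numerics

The coupled gut + body system (22 states) integrates with LSODA at
rtol 10⁻⁸ / atol 10⁻¹⁰; a fixed-step classical RK4 mode exists for parity
runs. Bolus and oral doses are state jumps at segment boundaries;
infusions are piecewise-constant venous inputs. IV profiles carry a
genuine fast mixing spike (the bolus lands in a small venous pool), so
AUC quadrature uses geometrically spaced early time points. NCA uses
linear-up/log-down trapezoids, a 3-point terminal log-linear fit
(configurable) and standard moment extrapolations.

SF/ASF estimation is bounded least squares (SF ∈ [10⁻³, 10²],
ASF ∈ [10⁻⁴, 10]) on log-scale residuals (profiles span > 1 order of
magnitude; a linear option is kept since the original regression settings
are unreported). The objective surface has a shallow secondary basin at
high ASF, so local starts are seeded from a deterministic coarse
log-spaced scan of the bounded box; the finite-difference step is fixed
at 10⁻⁴ to stay above ODE integration noise. Fits run at relaxed solver
tolerance (rtol 10⁻⁶), which is far below the residual noise floor.

Conventions: closed fold-error intervals (a ratio of exactly 2.0 is not
an outlier); combined AAFE pools points across arms before averaging
(arm-averaging is available); oral study arms simulate to 96 h because
rodent flip-flop kinetics give a ~22 h terminal half-life.

## Synthetic data

Observed concentrations exist publicly only as figures, so the fitting,
NCA and validation machinery is exercised on synthetic datasets: the true
model profile sampled at the study schedules (7–8 points to 8 h in
animals; 16 points to 48 h in humans), multiplied by log-normal noise
with 15% CV (constant-CV behavior typical of plasma LC-MS/MS assays) and
censored below a 0.005 µg/mL quantification floor. Parameter-recovery
tests treat one "study" as the arithmetic mean of six subjects, matching
the original design of fitting mean profiles. The generator does **not**
emulate inter-individual physiological variability, dosing-time error or
assay bias — so passing recovery tests demonstrate estimator correctness
under the stated error model, not robustness to population heterogeneity.

## Known limitations

* Elimination is exclusively hepatic (plus rat blood degradation);
  biliary/renal routes, measured at ~0.5% and ~1.2% of dose, are ignored.
  All kinetics are linear; no transporters, no saturable metabolism.
* Absorption is permeability-limited only — no solubility, dissolution,
  pH or fed-state effects (fasted solution/capsule dosing).
* Moment-based Vss from simulated IV profiles sits a few percent below
  the composite volume because hepatic elimination is peripheral to the
  sampling compartment; the bias grows with ER and with the liver's share
  of Vss (largest in the rat, whose assay-implied liver is oversized).
* The portal circulation is approximated by the spleen→liver route; the
  oracles above constrain the input-output behavior but not intra-organ
  detail.
* Reported theoretical bioavailabilities in the source study are not
  mutually consistent with F = Fa·Fg·(1−ER) for every species; the
  package implements the formula, not the printed values.
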
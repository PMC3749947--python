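# Methods

## The model

`herdyn` implements a mass-action model of activation of the three HER
(ErbB) receptor tyrosine kinases HER1 (EGFR), HER2 and HER3 by the ligands
EGF (binds HER1) and HRG/heregulin (binds HER3).  HER2 binds no ligand and
HER4 is not modeled.  The model tracks 17 molecular species — the two
ligands, five monomers (R1, R1E, R2, R3, R3H) and ten dimers (R11E, R11EE,
R12E, R13E, R13H, R13EH, R22, R23H, R33H, R33HH; Rij = HERi–HERj dimer,
suffixes E/H = bound EGF/HRG) — in three compartments (cell surface, early
endosome EE, late endosome LE), for 51 state variables.  The state layout
is compartment-major, species-minor, 0-based.

### Reactions (surface and EE only)

* **Ligand binding** is reversible mass action.  Binding kinetics are
  independent of dimerization context, with three exceptions implemented by
  scaling the *off*-rate inside the dimer (the on-rate is untouched, so the
  Kd ratios hold exactly): EGF binds the R12 dimer with Kd/1.6 (≈60%
  stronger affinity), HRG binds the R23 dimer with Kd/25, and EGF binds an
  HRG-occupied R13 dimer with Kd×3.
* **Dimerization** occurs between two monomers whenever every non-HER2
  partner is ligand-bound; HER2, having no ligand, dimerizes
  constitutively.  This is precisely the rule that populates the ten dimer
  species and no others (ligand-free R11/R13/R33/R12/R23 dimers never
  exist; basal HER1/HER3 pre-dimers are taken as negligible by
  construction).  All forward dimerization uses a single diffusion-limited
  rate constant `kc`; each dimer type has its own dissociation rate `ku`
  per reactive compartment — 10 dimers × 2 compartments = 20 free rates.
* **Collapse rule.**  Loss of the *sole* ligand from a singly-liganded
  dimer destabilizes it instantly; the event is lumped into one reaction
  producing two free monomers plus the ligand.  Doubly-liganded dimers lose
  one ligand at a time (with a statistical factor 2 for the symmetric
  homodimers R11EE/R33HH) and stay intact.
* **Phosphorylation** is not a kinetic species: dimerization and
  trans-phosphorylation are fast relative to sampling, so each dimer's
  contribution to a receptor's phospho signal is `pf × abundance`, with
  lumped, compartment-specific phosphorylation factors `pf<ijc>` (HERi
  signal from the HERi–HERj dimer in compartment c).  13 pf names × 2
  compartments = 26 free factors.  HER3 homodimer pf values are identically
  zero (HER3 is kinase-dead), so they are not parameters.

### Trafficking

Species internalize from the surface (first order: `kt` for monomers, `ke`
for dimers), and leave the EE by recycling or LE sorting; LE species only
degrade (no biochemistry there, matching the idea that receptors are
dephosphorylated in multivesicular bodies before degradation).  From the
endosomal exit rate `kx`, recycling fraction `f` and the per-species LE
entry/exit ratio `δ`:

    kr = kx·f·(1+δ),  kl = kx·(1−f)·(1+δ),  kd = kx·(1−f)·(1+δ)/δ.

Assuming sorting precedes LE entry and a common degradation rate in the LE,
every δ follows from the single free parameter δ1 (the EGFR-monomer value):

    1 + 1/δi = kx1·(1−f1)·(1+1/δ1) / (kxi·(1−fi)).

Free parameters therefore total **47**: 20 `ku` + 26 `pf` + δ1.  Everything
else is fixed: ligand binding kinetics, `kc`, and the trafficking constants
`kt/ke/kx/f`.

### Fixed-rate defaults

The shipped defaults are plausible literature-range values for mammary
epithelial cells, chosen once and frozen; all structural/ratio assertions
in the test suite depend only on counts and printed ratios, never on these
numbers.  Units: receptors in molecules/cell, extracellular ligand in nM
(doses in ng/ml converted with MW 6.4 kDa for EGF, 7.5 kDa for the HRG EGF
domain), first-order rates in 1/min, `kon` in 1/(nM·min), `kc` in
1/((molecules/cell)·min).

| parameter | default | note |
|---|---|---|
| kon/koff EGF·HER1, surface | 0.097, 0.24 | Kd ≈ 2.5 nM |
| kon/koff EGF·HER1, EE | 0.05, 1.2 | weaker at endosomal pH |
| kon/koff HRG·HER3, surface | 0.04, 0.06 | Kd ≈ 1.5 nM |
| kon/koff HRG·HER3, EE | = EGF EE values | stated model assumption |
| kc (both compartments) | 1e−5 | diffusion-limited, common to all dimers |
| kt HER1 / HER2 / HER3 monomer | 0.05 / 0.01 / 0.01 | HER3 traffics like HER2 |
| ke, pure-HER1 dimers | 0.20 | rapid ligand-induced internalization |
| ke, HER2/HER3-containing dimers | 0.05 | slow HER2-like internalization |
| kx, f (HER1-class) | 0.09, 0.50 | reference for the δ chain |
| kx, f (HER2/HER3-class) | 0.05, 0.85 | mostly recycled |
| δ1 (free; truth value) | 2.0 | |

A species' trafficking class is HER2-like when it contains HER2 or HER3,
EGFR-like otherwise; ligand-occupancy does not change the class.  The free
`ku`/`pf` defaults double as the synthetic-data ground truth; they were
chosen so that the model reproduces the qualitative behavior expected of
these cell lines (sub-stoichiometric EGFR dimerization at saturating EGF,
pf for the doubly-liganded R11 dimer ≈ 0.03, a less stable R12 than R11,
HER2-driven HER3 activation) and then frozen.

### Ligand handling

Extracellular free ligand is clamped (no depletion; doses are saturating
and pinocytosis is ignored): the surface-ligand state entries have zero
derivative and stimulation protocols set their values.  Ligand carried into
the EE by internalized complexes is released on unbinding into a tracked EE
ligand pool that participates in EE binding; that pool is cleared to the LE
at a first-order sorting rate (default 0.05/min) and degraded there.  EE
bimolecular rates can be scaled by a compartment-volume correction factor
(default 1, i.e. the same molecules/cell basis as the surface).

## Equilibration and simulation

Before stimulation the cell is at the ligand-free steady state of the
trafficking network with constant synthesis of free monomers at the
surface.  HER1 and HER3 form no ligand-free dimers, so each obeys an
independent linear three-compartment balance solved in closed form; HER2
additionally populates the constitutive R22 homodimer, making its balance
nonlinear — it is solved with a damped Newton root-solve over (R2 surface,
R2 EE, R22 surface, R22 EE, synthesis) with the LE pools eliminated
analytically.  Synthesis rates are chosen so total copies per receptor
match the cell line's expression; the state is verified against the full
right-hand side (relative residual < 1e−9).  A consequence of constitutive
HER2 dimerization is a small basal R22 pool, hence a small nonzero basal
pR2 in HER2-expressing lines.

Integration uses LSODA with an analytically assembled Jacobian
(transport matrix + mass-action terms); default tolerances are rtol 1e−8 /
atol 1e−10 for simulation and rtol 1e−6 / atol 1e−8 inside optimization
loops, where the finite-difference step of the outer least-squares
(1e−3 in log10 space) keeps parameter-induced residual changes well above
the integrator noise floor.  Trajectories are clipped at zero to remove
integrator-scale negative excursions before observables are computed.

### Observables

For receptor i: `pRit` = surface + EE phospho signal (Σ pf × dimer
abundance), `pRii` = the EE part alone (the acid-stripping readout), and
`mRit` = every receptor copy in every compartment with homodimers counted
twice.  LE species contribute to mass only.  Units of pR are arbitrary
(pf × molecules), as in normalized ELISA output.

### HER2 blocking (pertuzumab/2C4 mode)

Blocking fraction β removes β of cellular HER2 from the reactive pool:
initial condition and synthesis feed scale by (1−β), matching an
irreversible-sequestration approximation justified when antibody ≫ Kd.
The sequestered pool cannot dimerize, so it sits at its own monomer
trafficking steady state and contributes a constant offset to `mR2t`
(sequestered HER2 is assumed to keep internalizing and degrading at
monomer rates; this choice affects only `mR2t`).

## Synthetic data

The generator emulates the study's measurement structure with four cell
lines — HER2−3− (200k HER1 only), HER2+3− (+600k HER2), HER2−3+ (+40k
HER3), HER2+3+ (all three) — and, per line: EGF dose series {0.6, 3, 12,
30} ng/ml and HRG dose series {4, 12, 40, 120} ng/ml with `pRt` read at
{0, 10, 30, 60} min; 2-hour time courses (9 time points) for 12 ng/ml EGF,
40 ng/ml HRG and their combination covering `pRt`, `pRi`, `mRt`; and
95%-HER2-blocked versions of the time-course treatments read at 10 and
30 min.  Only the printed dose *ranges* are fixed by the design; the two
intermediate doses per series are a frozen package choice.  Only expressed
receptors are measured, every condition has ≥ 2 replicates, and the
default design yields 1904 records (952 distinct measurements).

Noise is multiplicative lognormal per record with CV 10% by default
(typical ELISA replicate scatter), parameterized mean-preservingly
(σ² = ln(1+CV²), factor e^{σZ−σ²/2}) so replicate means converge to the
noiseless model output; an optional detection floor clips from below.
The generator does **not** emulate plate/batch effects, total-protein
normalization artifacts, or cross-line assay calibration differences — so
green tests show the estimation machinery recovers parameters from data
with the study's *design and noise scale*, not that it is robust to every
real-world ELISA artifact.

## Parameter estimation

Residuals are (prediction − measurement)/scale with one scale per
measurement type (its maximum observed value), concatenated over all
records; fit quality is the RMSE of this scaled vector.  Optimization is
bound-constrained trust-region least squares (`scipy.optimize.least_squares`,
TRF) over log10-transformed `ku` and `pf` (bounds 1e−3..1e3 and 1e−6..1)
and linear δ1 (0.1..10); starts are sampled uniformly in that transformed
space.  A simulation failure during a candidate evaluation yields a
constant penalty residual (10 per record) instead of raising.  One master
seed spawns per-start substreams, making multistart runs deterministic.

The progressive strategy fits (1) the 9 HER1-related parameters (4 ku +
4 pf + δ1) on the parental line; (2) the HER1–HER2 block (+10 parameters,
parental + HER2+3−) and HER1–HER3 block (+22, parental + HER2−3+), each
seeded with the stage-1 optimum; (3) all 47 on all four lines, seeded from
stages 1–2 with randomized HER2–HER3 interaction guesses.  The multistart
count is configurable up to the hundreds; solutions with RMSE ≤ 1.2× the
best (a package default — the retention threshold is otherwise
unspecified) are clustered by k-means on standardized log-parameters with
k chosen by silhouette over 2..10, and each cluster is summarized by its
minimum-RMSE member.

Problem sizes used in the shipped verification runs: the parameter-recovery
check fits the stage-1 block on a reduced parental design (4 EGF doses ×
4 times for pR1t plus one 2-h time course of pR1t/pR1i/mR1t, noiseless)
with 20 prior-sampled starts — small enough to run on a laptop while still
containing the dose-response and kinetic information that makes the HER1
surface parameters identifiable.  EE-compartment ku/pf exhibit the
expected correlated scatter (dissociation rate and phosphorylation factor
trade off against each other), while per-dimer *phospho signals* agree
closely across solution clusters; that product, not the individual
factors, is the identifiable quantity.

## Dimer analysis and downstream regression

Per-dimer contributions are `pf × abundance` summed over surface + EE
(consistent with the `pRt` definition — the EE share is included, which is
a documented package choice), reported per occupancy species and rolled up
to receptor pairs.  Expression scans fix HER3 at 40,000 molecules/cell and
vary HER1 over 1e3..1e6, HER2 over 1e3..3e6 (log-spaced, default 20×20),
evaluating at t = 60 min after 30 ng/ml EGF + 100 ng/ml HRG — the
phosphorylation pattern is essentially stationary past one hour, making
this snapshot representative.

Downstream Erk/Akt activation is summarized by ordinary least squares on
`pT = b0 + Σ bi·pRi` (receptor mode) or `pT = b0 + Σ biji·pRiji` (dimer
mode), always with an intercept.  Predictors are z-scored by default so
|coefficient| doubles as the importance ranking (the raw scale is
recoverable; `zscore=False` disables it).  Collinearity — intrinsic here,
since the two receptor-sides of one dimer are proportional signals — is
surfaced via the design condition number, and rank-deficient designs are
fitted with the minimum-norm pseudoinverse convention and flagged.

## Numerical and degenerate-case conventions

* fsolve tolerance 1e−13 for the HER2/R22 equilibrium; failure raises with
  the residual.
* `f = 1` (full recycling) or `kx ≤ 0` are rejected in the δ chain, as are
  parameter combinations whose implied δ would be non-positive.
* Zero-expression receptors simply never populate; a fully empty profile
  equilibrates to the zero state with zero synthesis.
* An all-identical solution set clusters to k = 1; clustering requires ≥ 2
  retained solutions.
* Observables at t = 0 are the pre-stimulation steady-state values.

## Known limitations

* No HER4; no ligand-free pre-formed HER1/HER3 dimers; no membrane
  microdomain or cytoskeletal corralling effects; no per-tyrosine
  phosphorylation resolution; no mechanistic MAPK/PI3K signaling (only the
  regression summary).
* Extracellular ligand depletion is ignored, so very low doses on dense
  cultures are outside the model's intended regime.
* The fixed trafficking/binding constants are literature-range defaults,
  not cell-line-calibrated measurements; conclusions that depend on their
  absolute values should be re-derived with measured inputs.
* Parameters of the R13/R22/R23/R33 blocks are practically unidentifiable
  from pR/mR data of this design (broad multistart scatter); the pipeline
  reports this scatter rather than hiding it, and downstream analyses
  should use per-dimer phospho signals, which are stable across solutions.
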
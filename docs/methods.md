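# Methods

`mripbpk` links dynamic contrast-enhanced MRI (DCE-MRI) kinetics of a
small-molecule gadolinium contrast agent to a physiologically based
pharmacokinetic (PBPK) model of monoclonal-antibody (mAb) tumor disposition.
The workflow is: (i) fit the Patlak model to per-subject tumor
concentration–time curves with each subject's own arterial input function
(AIF), yielding the volume transfer constant K<sup>trans</sup> (min⁻¹) and
fractional plasma volume V<sub>p</sub>; (ii) map these MRI parameters onto
two tumor PBPK parameters — plasma flow Q<sub>TU</sub> and vascular
reflection coefficient σ<sub>TU</sub><sup>V</sup> — through covariate
equations; (iii) estimate the covariate slopes by maximum likelihood on a
cohort dosed with a non-binding antibody (one terminal tumor concentration
per subject); (iv) predict, a priori, the tumor kinetics of a
target-binding (anti-EGFR) antibody in new subjects from their own MRI
parameters.

## DCE-MRI kinetics (`mripbpk.dce`)

**Pre-contrast T1.** Saturation-recovery signals at variable repetition
times TR ∈ {200, …, 5000} ms are fit to S(TR) = M₀(1 − e^(−TR/T1)) by
nonlinear least squares. Degenerate data (saturated signals, unbounded T1)
are flagged, never silently clipped.

**Signal → concentration.** The spoiled-gradient-echo steady-state equation

    S = M0 · sin α · (1 − E1) / (1 − E1 cos α),   E1 = exp(−TR · R1)

is calibrated from the mean pre-injection baseline (M₀ from the baseline
signal and R₁₀ = 1/T₁₀) and inverted per frame for R₁(t); concentration
follows from linear relaxivity, C(t) = (R₁(t) − R₁₀)/r₁. Frames whose
signal implies E₁ outside (0, 1) — above the SPGR signal ceiling — are
flagged invalid and excluded from fitting. The relaxivity default
(r₁ = 3.3 L·mmol⁻¹·s⁻¹) is an assumption appropriate for gadobutrol at high
field and must be configured per agent and field strength.

**Patlak fit.** Under the no-reflux assumption the tissue curve is linear
in the parameters,

    Ct(t) = Ktrans · ∫₀ᵗ Cp dτ + Vp · Cp(t),

so the fit is a bounded linear least-squares problem (K<sup>trans</sup> ≥ 0,
0 ≤ V<sub>p</sub> ≤ 1; trapezoid integration on the frame grid) solved
deterministically — no starting values, no local optima. On interior optima
the solution coincides with the closed-form normal-equations solution to
1e−8; active bounds are reported via the returned estimates. The reflux
parameters of the Tofts family (K<sub>ep</sub>, V<sub>e</sub>) are outside
the model by assumption. The default fit window is all post-injection
frames; pre-injection frames carry no information in this model (their
design rows are zero) so the choice is inconsequential for the estimates.

## Tumor PBPK model (`mripbpk.pbpk`)

The tumor comprises vascular, endothelial (endosomal) and interstitial
sub-compartments plus a cellular antigen layer. States are amounts;
volumes grow as V(t) = V₀·e^(kgrowth·t), which dilutes concentrations
without explicit dilution terms. The full ODE system is emitted verbatim by
`mripbpk show-equations`. Transport and elimination:

- plasma flow Q_TU in, (Q_TU − L_TU) out; convective extravasation
  (1 − σ_V)·L_TU into the interstitium; lymph drainage (1 − σ_L)·L_TU of
  free interstitial mAb;
- fluid-phase endosomal uptake Clup_TU from both the vascular and free
  interstitial concentrations; FcRn binding in the endosome at
  quasi-equilibrium (KD_FcRn, C_FcRn), with bound mAb recycled
  (Clup_TU·FR to vascular, Clup_TU·(1−FR) to interstitial) and unbound mAb
  catabolised at Cl_TU;
- interstitial EGFR binding at quasi-equilibrium (KD_EGFR, C_EGFR), the
  complex internalised with Cl_TMD = Kint·V_I (first-order loss of the
  bound amount at Kint).

Both binding steps use the stable closed form of the two-total quadratic,
B = 2·C_T·R_T / (b + √(b² − 4·C_T·R_T)), b = C_T + R_T + K_D, which handles
K_D → 0 (stoichiometric limit) without cancellation. The receptor pools
(C_FcRn, C_EGFR) are constant totals; receptor synthesis/turnover is not
modelled. Default parameter values are the tabulated base set for a
~0.16 mL xenograft (Q_TU = 1e−4 L/min, σ_V = 0.734, etc.); EGFR
concentrations are cell-line specific (NCI-N87 1.14e−7 M, Panc-1
9.24e−8 M, LS174T 3.53e−8 M) and 0 for the non-binding antibody.

**Plasma.** Systemic disposition drives the tumor as a forcing function —
a dose-normalised biexponential C_p(t) = D·(A e^(−αt) + B e^(−βt)) with
C_p(0⁺) = D/(central volume 1/(A+B)), or any tabulated curve. This replaces
a whole-body multi-organ model and is the single largest structural
simplification in the package: tumor uptake does not feed back on plasma.
Defaults are mouse-IgG-like (V_c ≈ 1.2 mL for a 25 g mouse, phase
half-lives ≈ 10 h and 6 d, dose 1 mg/kg, MW 150 kg/mol). A closed
two-region configuration (plasma as a finite, well-mixed state receiving
lymph drainage and vascular outflow) exists for mass-balance verification:
with catabolism and target binding off, total antibody is conserved to
better than 1e−6 (measured: ~2e−15).

**Numerics.** LSODA with a banded Jacobian exploiting the block-diagonal
structure (the population likelihood integrates all 26 subjects as one
stacked system); rtol 1e−8 and atol 1e−12 × dose by default, rtol 1e−6
inside iterative fitting (config-exposed). The right-hand side is compiled
(numba). Negative states beyond 1e−3 relative are an error; smaller
transients are clamped to zero on output.

Two structural facts worth knowing:

- *Flow is weakly identified.* Q_TU affects tumor uptake only through
  sieving polarisation of the vascular space, C_V/C_p = Q/(Q − σ_V·L) at
  quasi-steady state — a few-percent effect at physiological flows. Slopes
  on Q_TU are therefore recovered exactly from noise-free data but are
  erratic under realistic noise (the slope-recovery study reports this
  honestly). Below Q_TU = σ_V·L_TU the vascular balance is unstable, so the
  likelihood rejects Q_TU ≤ 1.05·L_TU.
- *FcRn saturation is weak but real.* At 1 mg/kg the endosomal mAb
  concentration is ~0.6% of C_FcRn, so with target binding off the system
  is linear in dose only to ~1e−6…1e−5 relative; exact linearity (1e−8)
  holds in the tracer-dose limit. Tests assert both regimes.

## Covariate model and estimation (`mripbpk.covariate`)

The covariate equations are

    Q_TU   = θ_Q · x                  σ_TU^V = 1 / (1 + θ_σ · x)

with x the subject's MRI parameter; the reciprocal form keeps
σ<sub>TU</sub><sup>V</sup> in (0, 1] for any non-negative predictor. For the
two-covariate structure the linear predictor θ₁·K^trans + θ₂·V_p is used in
both equations — the simplest extension preserving the single-covariate
forms; subjects with V_p = 0 simply lose that term. Candidate structures:
`base` (tabulated values, nothing fitted), `population` (one shared
(Q_TU, σ_V) pair fitted), `ktrans`, `vp`, `ktrans+vp`. A subject with a
zero predictor under a covariate structure would receive Q_TU = 0 and is
flagged unpredictable rather than simulated.

**Likelihood.** Each subject contributes one terminal tumor concentration;
with one observation per subject, inter-individual random effects on the
slopes are not identifiable, so estimation is direct maximum likelihood
over fixed effects with a proportional (lognormal) residual error,
obs ~ LogNormal(log pred, s²). The lognormal form matches the
multiplicative error structure of such assays (and of the synthetic
generator) and is symmetric on the log scale — a normal proportional error
is asymmetric there and drags fits toward systematic overprediction. The
error scale is profiled out analytically, leaving a 2- (or 4-)dimensional
objective optimised by Nelder–Mead on log- (and logit-)transformed
parameters, started from the best points of a deterministic coarse grid.
Everything is deterministic given data and settings; fits are
byte-reproducible. AIC = −2·loglik + 2·(fitted fixed effects + 1 error
parameter); ties break toward fewer parameters.

**A priori prediction.** For a target-binding antibody, the slopes fitted
on the non-binding cohort individualise (Q_TU, σ_V) from each new subject's
own MRI parameters; the EGFR module is switched on at the group's receptor
concentration; nothing is refit to the binding-arm data.

## Synthetic cohorts (`mripbpk.synthetic`)

The generator emulates the study design the analysis assumes: four
xenograft groups (LS174T, LS174T+sorafenib, NCI-N87, Panc-1) with group
sizes 10/7/5/4 (non-binding arm, 26 subjects) and 9/6/5/3 (binding arm,
23); one terminal observation per subject, allocated round-robin over
{3 h, 8 h, 1 d, 3 d, 6 d} within each group so small groups still cover
early and late times; 70 DCE frames at 17 s (end-of-frame timestamps,
~19.8 min span) with injection 2 min after scan start; per-subject AIF
jitter (multiplicative, on amplitude and decay rates) on a bolus
biexponential; proportional signal noise on DCE and saturation-recovery
curves; mean-preserving lognormal error (default CV 20%) on terminal
observations. Group K^trans distributions are lognormal with geometric
means 1e−2/3e−3/5e−3/1e−3 min⁻¹ (10-fold span, matching the observed
contrast between high- and low-enhancement xenografts); V_p is normal
truncated at zero, with a point mass at V_p = 0 in the matrix-rich Panc-1
group, emulating tumors with undetectable vascular fraction.

Ground truth flows through the same covariate equations and simulator used
for analysis, so zero-noise cohorts are exactly self-consistent (observed =
simulated at machine precision) and recovery studies have a known answer.
The default truth is a K^trans structure with θ_Q = 0.02 L and θ_σ =
50 min. θ_Q reproduces the tabulated base flow at the mid-cohort K^trans;
θ_σ puts the cohort-average reflection coefficient (~0.79) above the
tabulated base value (0.734), so the base model overpredicts tumor uptake
on average — the qualitative geometry the in-vivo study reported (its base
model overpredicted, and its population fit improved on it). This makes the
expected ordering MPE(covariate) < MPE(population) < MPE(base) a property
of the synthetic world, as it was of the real one.

What the generator does *not* emulate: voxel-level images and segmentation,
Rician noise, motion, bolus-arrival-time jitter, assay-specific error in
gamma counting, or inter-individual variability in systemic disposition
(one plasma model per antibody). Passing tests therefore demonstrate
correctness of the estimation machinery under the stated statistical
assumptions, not performance on real images.

## Evaluation (`mripbpk.evaluation`)

Mean prediction error is the mean absolute percent error,
MPE% = (100/N)·Σ|pred − obs|/obs; the signed variant (mean of
(pred − obs)/obs) is always computed alongside and labelled distinctly,
since either convention appears in practice. Tumor/plasma ratio tables
report per-(group, antibody) means rounded to 2 decimals, and the
binding/non-binding ratio of arm means per group (computed before
rounding); a missing arm yields no ratio, never an imputed one. The AIC
table sorts candidate structures by AIC with Δ AIC and per-structure MPE.

## Built-in studies (`mripbpk.studies`) and expected behaviour

- *Noise-free slope recovery* (26 subjects): both slopes within 1%
  (measured ~1e−8…1e−6 relative; the objective is exactly minimised at the
  truth, so the error is pure optimiser/ODE tolerance).
- *Slope recovery at 20% CV* (20 replicates): θ_σ relative bias a few
  percent, RMSE ~10%; θ_Q dispersion large (weak identifiability, see
  above) and reported without a threshold.
- *Structure selection* (20 replicates, 20% CV): in-sample MPE ordering
  covariate < population < base, and AIC ranking the true structure first,
  each hold in all replicates at the default conditions.
- *Patlak under noise* (200 tumors, 5% signal noise, 70 frames): median
  relative bias of K^trans ≪ 1%; median absolute relative error ~4–5%
  (dispersion, not bias).

Problem sizes throughout (26/23 subjects, 20 replicates, 200 tumors) are
the study-design sizes; they keep any single study under ~2 minutes on one
CPU.

## Known limitations

- The plasma forcing function ignores tumor-to-plasma feedback and
  inter-subject systemic variability; absolute tumor/plasma ratios depend
  on its parameterisation.
- The population structure can possess a second, physiologically
  implausible likelihood optimum (very low Q_TU with σ_V → 1, fitting the
  data through vascular sieving polarisation); it is a genuine optimum of
  this reduced model, guarded only by the Q_TU stability bound, and is
  reported as fitted when the likelihood prefers it.
- Quasi-equilibrium binding assumes on/off kinetics fast relative to
  transport; no receptor synthesis/internalisation dynamics for FcRn.
- MPE conventions differ across the literature; both absolute and signed
  forms are emitted, and only the absolute form is used for ordering.
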
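# mripbpk

MRI-informed PBPK modelling of monoclonal-antibody tumor disposition.

Predicting how much of an anti-cancer antibody reaches an individual solid
tumor is hard: tumor blood flow, vessel permeability and stromal composition
vary widely between subjects, and none of them can be measured from a
biopsy. `mripbpk` implements a strategy that uses dynamic contrast-enhanced
MRI (DCE-MRI) of a gadolinium tracer as a subject-specific probe of those
passive transport properties, and feeds the imaging parameters into a
mechanistic tumor PBPK model so that antibody tumor kinetics can be
predicted *a priori*, one subject at a time. It is aimed at
pharmacometricians and quantitative imaging scientists working on
antibody disposition in xenograft models.

The chain has three quantitative links:

1. **Patlak DCE-MRI fitting.** Per subject, tumor contrast concentration
   (from the spoiled-gradient-echo signal equation and a measured
   pre-contrast T1) is fit against the subject's own arterial input
   function: `Ct(t) = Ktrans·∫Cp dτ + Vp·Cp(t)`, a bounded linear
   least-squares problem solved exactly.
2. **Covariate equations.** The MRI parameters individualise two tumor
   PBPK parameters: `Q_TU = θ_Q·x` (plasma flow) and
   `σ_TU^V = 1/(1 + θ_σ·x)` (vascular reflection coefficient, kept in
   (0, 1] by construction), with `x` = Ktrans, Vp, or an additive
   combination. Slopes are estimated by maximum likelihood on a cohort
   dosed with a non-binding antibody, and candidate structures are ranked
   by AIC and mean prediction error (MPE).
3. **Tumor PBPK simulation.** A three-sub-compartment tumor (vascular,
   endosomal with FcRn salvage, interstitial) plus a cellular EGFR layer
   with quasi-equilibrium binding and internalisation, growing
   exponentially, driven by a configurable plasma forcing function. The
   exact ODE system is printable (`mripbpk show-equations`).

A synthetic-cohort generator reproduces the study design this analysis
assumes (four xenograft groups with 10-fold Ktrans spread, ~25 subjects per
antibody, one terminal observation each at 3 h–6 d), so the whole pipeline
is testable end-to-end with known ground truth. See `docs/methods.md` for
the model details and assumptions.

## Worked example

Run the full pipeline — simulate both antibody arms, fit every subject's
DCE curves, fit the candidate covariate structures on the non-binding arm,
predict the binding arm a priori, and evaluate:

```bash
mripbpk run-all --seed 7 --outdir runs/demo
```

`runs/demo/model_comparison.csv` then contains (seed 7):

```
 structure  n_params     loglik         aic  mpe_percent  delta_aic
    ktrans         3 449.264416 -892.528832    20.914272   0.000000
      base         1 436.759409 -871.518818    39.102734  21.010014
population         3 438.289947 -870.579893    33.129148  21.948939
```

The Ktrans covariate structure (the structure that generated the data) wins
on AIC by ~21 units and halves the in-sample MPE relative to the
uncalibrated base parameter set. The a priori predictions for the
*target-binding* antibody — covariate slopes carried over from the
non-binding fit, EGFR binding switched on, nothing refit — are summarised
in `mpe_binding.csv`:

```
 structure            arm  mpe_percent  signed_mpe_percent
      base target-binding    33.653857           24.688176
population target-binding    26.928649           -2.098308
    ktrans target-binding    19.852511           14.011659
```

i.e. individualising the tumor parameters from each subject's own MRI
measurement improves out-of-cohort prediction (19.9% vs 33.7% MPE), which
is the point of the method. `tp_ratios.csv` shows the target-binding
antibody accumulating relative to the non-binder in every group
(binding/non-binding tumor-to-plasma ratios 1.57–3.80 at the subjects'
terminal times), the signature of target-mediated retention.

The same stages are available individually (`simulate`, `fit-dce`,
`fit-population`, `predict`, `evaluate`), all driven by a YAML config
(see `mripbpk.config.RunConfig`; every run writes a `manifest.json` with
the config hash and seed, and re-running a manifest's config reproduces
the outputs byte-for-byte).

Library use mirrors the CLI:

```python
from mripbpk.pbpk import TumorPBPKParams, PlasmaPKParams, simulate
from mripbpk.covariate import fit_population
from mripbpk.synthetic import default_groups, default_truth, generate_cohort, NoiseModel

base, plasma = TumorPBPKParams(), PlasmaPKParams()
cohort = generate_cohort(default_groups(), default_truth(), base,
                         NoiseModel(obs_cv=0.2), seed=7, plasma=plasma)
fit = fit_population(cohort, "ktrans", base, plasma)
print(fit.model.theta_q, fit.model.theta_sigma, fit.aic)
```

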
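# deltazone

Dose-zone delta-radiomics for predicting grade ≥2 radiation pneumonitis
(RP) after thoracic chemoradiotherapy.

Thoracic radiotherapy injures lung tissue in proportion to the local dose,
and patients on consolidative immunotherapy after concurrent
chemoradiotherapy are at particular risk of symptomatic pneumonitis.
`deltazone` implements, end to end, a risk-modelling pipeline for paired
planning CT studies: the planning scan (CT₁) and the mid-treatment
resetting scan (CT₂) are rigidly aligned, the lungs are partitioned into
nine dose-gradient zones (0–5, 5–10, 10–15, 15–20, 20–30, 30–40, 40–50,
50–55, 55–60 Gy, each kept only above 0.5 cm³), and the longitudinal
change of texture features inside each zone drives a per-zone radiomics
signature that is combined with clinical and hematological covariates into
logistic risk models.

It is aimed at radiation-oncology imaging researchers who want a tested,
reproducible reference implementation of the dose-segmented delta-radiomics
workflow — including a synthetic phantom/cohort generator, so every stage
runs and is validated without access to patient data.

## The model

For each dose zone *z* and each scan, features of seven classes (shape,
first-order, GLCM, GLRLM, GLSZM, NGTDM, GLDM; ~107 original-image features,
IBSI conventions: z-normalized intensities, fixed bin width 25, 3-D
matrices with 26-connectivity, GLCM/GLRLM angle-averaged at distance 1) are
extracted. The longitudinal change of feature *f* is

    ΔRF_f = (RF_f(CT₂) − RF_f(CT₁)) / RF_f(CT₁) × 100 %

Features with ICC(2,1) ≤ 0.8 across two delineations are discarded. Per
zone, an L1-penalized logistic regression over the ΔRF matrix (penalty by
10-fold cross-validated deviance) selects a sparse subset, and the
radiomics signature is the pure weighted sum

    RS_z = Σ_i w_i · ΔRF_i

Candidate predictors (RS of the best zone, clinical variables, DVH metrics
MLD/V5–V40/PTV-to-lung ratio, and inflammation indices PLR, NLR, LMR, SII
at six timepoints plus their changes from baseline) are screened at
p < 0.1 (Shapiro-routed t/Mann-Whitney tests; chi-square for categories),
ranked for importance across four learners (random forest, gradient
boosting, a single-hidden-layer network, a recursive-partitioning tree)
over 10 CV folds, and the top three stable variables enter nested logistic
models. Models are evaluated by ROC AUC with DeLong confidence intervals
and paired DeLong tests, confusion metrics at a Youden threshold,
calibration intercept/slope, and decision-curve net benefit

    NB(p_t) = TP/n − FP/n · p_t/(1−p_t).

## Worked example

```python
import deltazone as dz

# one affected subject: paired CTs, dose grid, lung and target masks
spec = dz.PhantomSpec(seed=7)
ct1, ct2, dose, lung, ptv = dz.generate_phantom_pair(spec, "S000", rp_label=1)

zones, dropped = dz.build_dose_zone_rois(dose, lung)
print([z.zone_label for z in zones])
m = dz.dvh_metrics(dose, lung, ptv)
print(f"MLD={m.MLD_Gy:.1f} Gy  V5={m.V5:.1f}%  V20={m.V20:.1f}%")

import numpy as np
diff = ct2.data - ct1.data
for z in zones:
    print(z.zone_label, round(float(diff[z.data].var()), 1))
```

prints

```
['0-5', '5-10', '10-15', '15-20', '20-30', '30-40', '40-50', '50-55', '55-60']
MLD=12.4 Gy  V5=45.9%  V20=27.3%
0-5 394.7
5-10 420.7
10-15 399.0
15-20 401.1
20-30 409.2
30-40 397.3
40-50 408.4
50-55 1851.4
55-60 393.2
```

— all nine dose zones exist, the dose-volume metrics are in a clinically
plausible range, and the injected texture change of this affected subject
is confined to the 50–55 Gy zone (its CT₂−CT₁ variance sits far above the
~400 HU² acquisition-noise floor seen everywhere else).

The full pipeline runs from the shell:

```bash
deltazone run-all --out run1 --seed 0 --n-subjects 40   # or stage by stage:
deltazone init-config cfg.yaml
deltazone simulate -c cfg.yaml && deltazone zones -c cfg.yaml  # ... etc.
```

producing per-stage CSV/JSON reports (cohort, DVH, features, ΔRF, ICC
retention, per-zone signatures, screening, stability ranking, model
coefficients, metrics, calibration and decision curves), each stamped with
the config hash; a rerun with the same config is bit-identical.

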
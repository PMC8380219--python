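# radpipe

PET radiomics robustness screening and prognostic modelling, end to end.

Quantitative features extracted from FDG-PET tumour images — shape,
intensity, texture and wavelet descriptors — are promising prognostic
biomarkers in non-small cell lung cancer, but their values depend on how
the tumour was delineated, how attenuation was corrected and how much the
lesion moved with breathing.  A natural response is to *preselect robust
features* (those with intraclass correlation ICC > 0.9 across perturbed
re-measurements) before building outcome models; whether that helps or
instead discards the prognostic signal is an empirical question.
`radpipe` implements the full study design needed to ask it:

* **simulation** of heterogeneous-uptake tumour phantoms on lung-like CT
  backgrounds, perturbation pairs for three factors (re-delineation,
  attenuation-style intensity bias, respiratory-style blur), and cohorts
  whose binarized event-free / overall survival depends on known image
  features through a logistic model;
* **extraction** of an IBSI-aligned 1404-feature vector per tumour:
  18 shape + 17 intensity + 137 texture features on the 5.5 mm resampled,
  HU-cleaned, 0.25-SUV-binned ROI, plus 17 + 137 on each of 8 undecimated
  Haar subbands;
* **robustness screening**: per-feature ICC(1,1) / ICC(3,1) / ICC(3,k)
  across conditions, the strict ICC > 0.9 stability rule, per-family
  stability percentages and the three-study Venn intersection;
* **modelling**: endpoint binarization at 12/18/24 months, Horn parallel
  analysis + PCA feature grouping, per-group univariable AUC screening
  (Wald p < 0.05), backward-AIC multivariable logistic regression,
  leakage-free fivefold cross-validation, trade-off model selection,
  DeLong-CI external validation and median-split Kaplan–Meier risk
  stratification with the G-rho test.

The statistical core in brief: a feature's stability is judged by the
Shrout–Fleiss intraclass correlation of its subjects × conditions matrix,
e.g. ICC(3,1) = (BMS − EMS)/(BMS + (k−1) EMS); prognostic value is judged
by the Mann–Whitney AUC (the probability that a random case outranks a
random control) and multivariable models minimize AIC = 2k − 2 log L.

## Worked example

```python
from radpipe.synthetic import PhantomSpec, generate_phantom, delineation_variants
from radpipe.features import extract_all
from radpipe.robustness import run_study
import pandas as pd

pet, ct, mask, truth = generate_phantom(PhantomSpec(seed=7))
res = extract_all(pet, ct, mask)
print(f"features extracted: {len(res.features)}")
for name in ["shape/volume_mm3", "shape/sphericity", "intensity/mean",
             "texture/glcm_avg/joint_entropy",
             "wavelet/HHL/texture/ngldm/dependence_count_entropy"]:
    print(f"  {name:55s} {res.features[name]:8.3f}")

tables = {"manual": {}, "threshold": {}, "gradient": {}}
for i in range(6):
    pet, ct, mask, _ = generate_phantom(PhantomSpec(seed=100 + i))
    variants = delineation_variants(pet, mask, threshold_pct=0.34, seed=i)
    for cond, m in zip(tables, variants):
        tables[cond][f"P{i}"] = extract_all(pet, ct, m).features
study = run_study({c: pd.DataFrame(d).T for c, d in tables.items()},
                  study="delineation")
print(f"\ndelineation study: {study.percent_stable():.1f}% of features stable")
print(study.percent_stable_by_family().round(1))
```

prints

```
features extracted: 1404
  shape/volume_mm3                                        33940.500
  shape/sphericity                                           0.903
  intensity/mean                                             6.016
  texture/glcm_avg/joint_entropy                             6.722
  wavelet/HHL/texture/ngldm/dependence_count_entropy         5.450

delineation study: 67.9% of features stable
intensity    76.5
shape         5.6
texture      81.8
wavelet      67.1
```

The tumour volume is exactly `voxel count × 5.5³` mm³.  Re-delineation
leaves most intensity and texture features stable (their ICC across the
three contouring methods exceeds 0.9) but destabilizes almost every shape
feature — shape is, unsurprisingly, what changes when the contour changes.

The full chain — three robustness studies, robust-set intersection,
training and validation cohorts, both model families per endpoint, KM
stratification — runs from one config:

```bash
radpipe run-all --seed 1 --out runs/demo      # or --config run.yaml
```

and writes per-study ICC tables, Venn counts, model JSONs, a metrics
table, KM curve data and a `summary.json`, each with a provenance sidecar.

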
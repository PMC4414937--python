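# halfcontour

Shape analysis of breast tumors in B-mode ultrasound when **posterior
acoustic shadowing (PAS)** corrupts the lesion boundary.

A strongly attenuating mass casts a dark acoustic shadow below itself.
Automated segmentation then merges the shadow with the (equally dark,
hypoechoic) lesion, so any shape feature computed on the **full** tumor
contour is contaminated. The *upper half* of the contour, however, is
acquired before the beam crosses the mass and is essentially unaffected.
`halfcontour` implements this idea end to end, for people building or
evaluating ultrasound CAD pipelines:

* **Segmentation** — per-column adaptive thresholding: a pixel is dark iff
  both its intensity `I(x, y)` and its `(2n+1)×(2n+1)` window mean `Ī(x, y)`
  fall below the column mean `TH_x = (1/N) Σ_y I(x, y)`; the tumor is the
  seeded dark connected component (holes filled, boundary regularized), and
  its closed contour comes from Moore-neighbor tracing.
* **Half-contour extraction** — the contour is split at its leftmost and
  rightmost pixels `P_l`, `P_r`; the upper arc plus the chord `L_lr`
  closing it form the half contour. An optional column-exclusion window
  ignores laterally shadowed portions when locating `P_l`/`P_r`.
* **Six shape features**, computed in full- or half-contour mode:
  - tumor circularity `TC = P²/A`,
  - mean and sample standard deviation of the normalized radial length
    `d̂(i) = d(i)/max(d)` (`NRL_M`, `NRL_STD`),
  - area ratio `AR = (1/(d̄N)) Σ (d̂(i) − d̄)` over the one-sided excesses,
  - roughness index `RI = (1/N) Σ |d̂(i) − d̂(i+1)|`,
  - **SDD**, the standard deviation of degree: the population standard
    deviation of the vertex angles
    `θ_s = arccos( (M_s M_{s−k} · M_s M_{s+k}) / (|M_s M_{s−k}||M_s M_{s+k}|) )`
    formed at each contour pixel with its neighbors at offset ±k.
* **Evaluation** — per-feature benign/malignant ROC curves with rank-based
  AUC, accuracy / sensitivity / specificity at the Youden-J operating point,
  and two-sided Welch t-tests.
* **Synthetic phantoms** — seeded speckled B-mode-like images with a
  hypoechoic lesion of controllable spiculation, ground-truth masks and an
  optional depth-decaying posterior shadow, so the whole pipeline is
  testable without clinical data.

## Worked example

```python
from halfcontour import ShapeSpec, make_shape_mask, feature_vector
from halfcontour.segmentation import TumorRegion, trace_contour

smooth = ShapeSpec(base_radius_px=40, center=(128, 128))
spiky  = ShapeSpec(base_radius_px=40, spiculation_amplitude=0.3,
                   spiculation_lobes=12, center=(128, 128), rng_seed=7)
for name, spec in [("smooth", smooth), ("spiculated", spiky)]:
    contour = trace_contour(TumorRegion(make_shape_mask(spec, (256, 256)), (128, 128)))
    fv = feature_vector(contour, mode="full", k=5)
    print(name, round(fv.tc, 1), round(fv.sdd, 1))
```

prints

```
smooth 10.0 7.0
spiculated 39.2 34.3
```

i.e. the smooth lesion sits near the digital-disk circularity floor
(continuum limit `4π ≈ 12.6`) with vertex angles dispersed by only 7°,
while the spiculated lesion roughly quadruples both measures — the
separation the classifier exploits.

Running the full synthetic experiment
(`python examples/04_pas_robustness_experiment.py`) prints, for a 25+25
cohort in which every case is shadowed:

```
feature mode  accuracy_pct  sensitivity_pct  specificity_pct   auc        p
     tc full            68               80               56 0.746  0.00143
     tc half            88              100               76 0.872   0.0001
```

Full-contour circularity degrades badly under shadowing while half-contour
circularity stays strongly discriminative — the package's central result.

The `halfcontour` command exposes the same stages from a shell
(`halfcontour phantom | segment | features | evaluate | run`); see
`halfcontour --help`.

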
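# toothpair

Quantitative contralateral pair matching for maxillary anterior teeth on
3D surface meshes.

In implant and restorative dentistry the mirror image of the healthy
contralateral tooth is a natural template for an individualized
restoration in the esthetic zone — provided left/right pairs really are
similar enough, and provided "similar enough" can be made quantitative.
`toothpair` implements that measurement end to end:

- **mirror** the contralateral tooth across the plane containing its long
  axis (the line through the root apex and crown midpoint);
- **register** the pair: closed-form Kabsch superimposition on three
  reference points (apex + two incisal-edge points), refined by a
  *constrained* point-to-plane ICP whose motion is restricted to rotation
  θ about the long axis and translation (u, v) in the perpendicular plane;
- **extract elements**: the crown (coronal to the gingival margin) and
  the emergence profile (the band between the margin and its 3 mm
  geodesic offset along the surface), with the root excluded;
- **score** each pair by the symmetric Hausdorff distance
  `HD(A, B) = max( max_a min_b |a − b|, max_b min_a |b − a| )` between the
  registered element point sets;
- **calibrate** a match threshold by ROC analysis over a population:
  n symmetric pairs (same individual) vs n(n−1) nonsymmetric pairs, with
  the operating point chosen as the largest HD threshold retaining 100%
  specificity, and report sensitivity/accuracy per tooth type × element.

Because no tooth-scan data ship with the package, a seeded synthetic
generator provides bilateral cohorts of parametric central incisors,
lateral incisors and canines whose left sides are near-mirror images of
the right (smooth harmonic shape variation: inter-individual SD
`sigma_pop`, within-pair asymmetry SD `sigma_asym`).  See
`docs/methods.md` for the model and its limitations.

## Worked example

```python
from toothpair import PopulationConfig, generate_population
from toothpair.pipeline import StudyConfig, match_population, build_report, report_to_dict

pop = generate_population(PopulationConfig(
    n_individuals=5, sigma_pop=0.5, sigma_asym=0.05,
    resolution=(32, 32), seed=1))
df = match_population(pop, StudyConfig(seed=1))          # 150 comparisons
rep = report_to_dict(build_report(df))
print(df.groupby("is_symmetric").hd.describe()[["mean", "min", "max"]])
print(rep["central/crown"])
```

prints

```
                  mean       min       max
is_symmetric
False         2.903608  0.751483  6.249105
True          0.364321  0.309472  0.428014
{'auc': 1.0, 'threshold_mm': 0.428013649458167, 'threshold_degenerate': False,
 'threshold_full_sensitivity_mm': 0.428013649458167, 'tp': 5, 'fn': 0,
 'tn': 20, 'fp': 0, 'sensitivity_pct': 100.0, 'specificity_pct': 100.0,
 'accuracy_pct': 100.0}
```

Symmetric (same-individual) pairs sit around 0.36 mm — residual asymmetry
plus discretization — while cross-individual pairs sit at 0.75–6.2 mm, so
the ROC threshold for central-incisor crowns (~0.43 mm here, the largest
HD with zero false positives) classifies every pair correctly.  On larger
cohorts with the default shape variation the calibrated thresholds move
into the ~2 mm regime reported for real anterior teeth.

The same workflow is scriptable from the shell:

```sh
toothpair simulate pop/ --n 10 --seed 1        # STL meshes + manifest
toothpair match pop/ hd.csv                    # all pairwise HDs
toothpair report hd.csv results/               # ROC, thresholds, tables
```

The HD-threshold classifier is also exposed as a scikit-learn estimator
(`toothpair.HausdorffPairClassifier`) for use in sklearn pipelines and
model selection.

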
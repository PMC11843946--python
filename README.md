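# leafcolor

A toolkit for RGB-image-based monitoring of leafy crops — including
anthocyanin-rich, red-leaved varieties for which conventional
greenness-based vegetation indices break down.

Leaf chlorophyll (Chl) tracks plant health, and handheld SPAD meters are
the non-invasive gold standard for estimating it — but they are slow and
point-based. Digital color indices computed from ordinary RGB photographs
scale to whole-crop monitoring, yet nearly all established indices (ExG,
GLI, VARI, NGRDI, DGCI, ...) were developed on green-leaved crops: high
anthocyanin (Anth) content shifts the greenness–redness balance of a leaf
and makes those indices read a healthy red-leaved plant like a sick green
one. Leaf *redness*, by contrast, is driven by Chl absorption in the red
band, where Anth is optically quiet. The redness-based contrast indices

```
SREx = R − G − B        TREx = 2R − G − B = (R − G) + (R − B)
```

exploit this: TREx correlates with SPAD readings consistently across green-
and red-leaved samples.

`leafcolor` provides the full workflow:

* **imaging** — segment a single leaf from a near-white stage background
  (Otsu-on-saturation ∩ value threshold, morphological cleanup, largest
  component, minimum 5000 px) and average 12 color features over the mask:
  R, G, B; H (degrees), S, V; L\*, a\*, b\* (D65/2°); chromatic r, g, b.
* **indices** — all 22 derived vegetation indices from the mean features,
  with flagged (not raised) undefined values on zero denominators.
* **pigments** — Chl and carotenoid contents from acetone-extract
  absorbances, anthocyanin from pheophytin-corrected A530 against a
  cyanidin-3-O-glucoside standard curve; all in mg/g fresh weight.
* **curvefit** — spreadsheet-style trendlines (linear, quadratic,
  exponential, logarithmic, power), best-fit selection by R², and elbow
  location by the Extremum Distance Estimator on the fitted curve.
* **synthetic** — leaf-image and study-table generators with exact ground
  truth, so the whole pipeline is testable offline.
* **cli** — `leafcolor extract | pigments | merge | analyze | simulate`.

## Worked example

```python
from leafcolor import compute_all_indices, analyze_relation
from leafcolor.imaging import segment_leaf, extract_mean_features
from leafcolor.synthetic import (SyntheticLeafSpec, SyntheticStudySpec,
                                 make_leaf_image, make_study_dataset)

# segment a noisy synthetic leaf painted (95, 135, 60) and recover its color
leaf = make_leaf_image(SyntheticLeafSpec(base_color=(95, 135, 60),
                                         channel_noise_sd=5.0, seed=42))
mask = segment_leaf(leaf.image)
feats = extract_mean_features(leaf.image, mask, "demo_leaf")
print(f"pixels={feats.pixel_count}  mean RGB=({feats.R:.2f}, {feats.G:.2f}, {feats.B:.2f})")
idx = compute_all_indices(feats)
print(f"TREx={idx['TREx'].value:.2f}  SREx={idx['SREx'].value:.2f}  "
      f"G/R={idx['G/R'].value:.4f}  DGCI={idx['DGCI'].value:.4f}")

# n=320 study-shaped dataset: G/R declines logarithmically with Anth/Chl
df, truth = make_study_dataset(SyntheticStudySpec(seed=1))
res = analyze_relation(df["Anth/Chl"].to_numpy(), df["G/R"].to_numpy(), elbow=True)
c = res.fit.coefficients
print(f"family={res.fit.family}  G/R = {c['a']:.4f} ln(Anth/Chl) + {c['b']:.4f}  "
      f"R2={res.fit.r_squared:.3f}  elbow at Anth/Chl = {res.elbow.x_star:.3f}")
```

prints

```
pixels=19993  mean RGB=(94.98, 135.01, 59.99)
TREx=-5.03  SREx=-100.01  G/R=1.4214  DGCI=0.4831
family=logarithmic  G/R = -0.1731 ln(Anth/Chl) + 0.7171  R2=0.855  elbow at Anth/Chl = 0.201
```

The segmented mean recovers the painted color to within a few hundredths of
a channel unit; the derived indices follow from those means (for a pure
green-dominated leaf TREx sits near zero and G/R well above 1). The study
dataset was generated with a logarithmic G/R law, noise calibrated for
R² ≈ 0.85 and an elbow at Anth/Chl = 0.2; the analysis recovers the family,
the coefficients (truth: −0.17 and 0.7264), and the elbow — the point past
which additional anthocyanin no longer shifts the greenness–redness
balance.

The same flow from the shell:

```
leafcolor simulate --out-dir sim --n-images 5 --seed 1
leafcolor extract sim/images --out sim/features.csv
leafcolor analyze sim/study.csv --pair "Anth/Chl:G/R" --elbow --out sim/relations.csv
```

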
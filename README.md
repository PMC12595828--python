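# gcxquant

Quantification of the **ependymal glycocalyx** from two-channel fluorescence
microscopy, for researchers studying the brain–CSF interface in aging and
acute injury models.

The glycocalyx (Gcx) is the glycan layer coating the apical surface of the
ependymal cells that line the brain ventricles.  In dual immunofluorescence
it shows up as a thin lectin-positive band just luminal of the cell body
(marked by S100β).  gcxquant turns such images — or synthetic stand-ins with
exact ground truth — into:

* **Thickness** `T = x₀(marker) − x₀(lectin)`: each channel's radial
  intensity profile along a line perpendicular to the surface is fitted with
  a smooth model (8th-degree polynomial, or a four-parameter logistic
  `y = A + (B−A)/(1+e^{−(x−x₀)/s})` for validation) and the boundary is the
  inflection point of the rising phase; the inter-inflection distance is the
  Gcx thickness in µm.
* **Coverage**: the percent of the *analyzable* surface arc length positive
  for the glycan stain, after excluding denuded (marker-negative) gaps from
  numerator **and** denominator.
* **Statistics**: mean ± S.E.M summaries, pooled/Welch t tests, one-way
  ANOVA with Dunnett's comparisons against a control, Pearson correlation,
  and Bland–Altman agreement (bias ± 1.96·SD limits) between the two
  inflection methods.

A first-class synthetic module generates profiles, curved two-channel
surface images, and hierarchical animal/site cohorts with known ground
truth, so every stage is testable without any imaging data.  See
`docs/methods.md` for the model and all defaults.

## Worked example

```python
from gcxquant import ProfileSpec, generate_profile_pair, thickness_at_site

spec = ProfileSpec(x_lectin_edge=1.24, thickness_true=0.65, noise_sd=5.0)
lectin, marker, truth = generate_profile_pair(spec, seed=1)
for method in ("polynomial8", "logistic4"):
    m = thickness_at_site(lectin, marker, method=method)
    print(method, m.x_inflection_lectin, m.x_inflection_marker, m.thickness)
```

prints (positions in µm):

```
polynomial8 : lectin inflection 1.245 µm, marker inflection 1.938 µm -> T = 0.693 µm
logistic4   : lectin inflection 1.236 µm, marker inflection 1.877 µm -> T = 0.641 µm
```

The lectin inflection marks the outer Gcx boundary (true 1.24 µm), the
marker inflection the apical membrane (true 1.89 µm); both methods recover
the true 0.65 µm thickness to within about half a pixel at 5% noise.  The
scripts in `examples/` walk through each capability the same way
(`profile_thickness.py`, `surface_coverage.py`, `method_agreement.py`,
`cohort_statistics.py`) — each builds a small input, runs the method and
prints what the numbers mean.

A thin CLI covers shell use:

```bash
gcx simulate image --seed 3 --out run/      # TIFF + ROI + ground truth
gcx measure --image run/image.tif --roi run/surface_roi.csv --seed 1 --out run/
gcx coverage --image run/image.tif --roi run/surface_roi.csv
gcx run --config run.yaml                   # full simulate→measure→report pipeline
```

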
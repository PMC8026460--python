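# pelvimetry3d

Tools for **3D CT pelvimetry** — measuring the bony pelvis from CT-derived
models — aimed at colorectal-surgery and imaging researchers who want to
quantify how pelvic shape differs between patients (classically: between
female and male patients) and what that implies for operating deep in the
pelvis. The package covers the full workflow:

1. **Synthetic pelvis phantoms** — patient CT series with ground-truth
   landmarks are rarely shareable, so the package generates them: a
   mirror-symmetric landmark template is calibrated by least squares to a
   table of target measure means (per sex), Gaussian landmark noise
   calibrated to the target SDs produces cohorts, and a bone-like solid
   swept through the landmark rings is voxelised at high contrast against
   the background — the property real CT segmentation exploits.
2. **Seeded level-tracing segmentation** — on each axial slice, starting
   from a seed pixel, the 4-connected region of pixels within an intensity
   tolerance of the seed's grey level is filled and outlined by a closed
   contour; tolerance 0 reproduces the literal equal-grey-level rule.
3. **Surface meshing with a volume audit** — marching-cubes isosurface of
   the binary mask, then umbrella (Laplacian) smoothing. The audited
   contract is that smoothing changes the enclosed volume by **< 1%**; the
   default filter is the shrink-compensating Taubin two-step
   (λ = 0.3, μ = −0.32, 10 iterations), which passes the audit where the
   pure umbrella filter does not.
4. **The 21-measure pelvimetry suite** — from 19 named fiducials
   (pubic symphysis superior/middle/inferior, sacral promontory, S3/S4
   disc, lower sacrum, coccyx tip, and paired iliopectineal, sacroiliac,
   iliopubic-eminence, ischial-spine, ischial-tuberosity and femoral-head
   points): the obstetric/true/diagonal conjugates, transverse and oblique
   inlet diameters, straight and median outlet conjugates, bis-ischiatic
   diameter, symphysis height, sacral chain distances, ischial-spine
   distance, pelvic depth (inlet midpoint → coccyx), pelvic tilt, the
   angles α, β, χ (inlet–promontory–coccyx), δ (promontory–coccyx–outlet),
   ε (the angle at S3), and the pelvic inlet / pelvic depth ratio.
5. **Cohort statistics** — per-measure two-sample pooled Student t-tests
   (two-tailed, α = 0.05; Welch by flag) and a priori power analysis for
   two independent means via the noncentral t distribution:
   δ = d·√(n₁n₂/(n₁+n₂)), power = P(|T| > t₁₋α/₂,df) under T ~ nct(df, δ).

## Worked example

```python
import pelvimetry3d as p
from pelvimetry3d.synthetic import PhantomParams, sample_landmark_cohort

records, labels = [], []
for sex, seed in (("female", 17), ("male", 18)):
    for lset, label in sample_landmark_cohort(PhantomParams(sex_label=sex, seed=seed), 100):
        records.append(p.compute_pelvimetry(lset))
        labels.append(label)

results = p.CohortComparison(records, labels).fit()
print(results.summary())
```

```
Pelvimetry cohort comparison: female vs male
two-tailed Student (pooled) t-tests, alpha = 0.05
18 of 21 measures significant

measure                   unit     female mean (SD)      male mean (SD)        t           p
obstetric_conjugate       mm         126.47 (8.04)      120.11 (7.65)     5.74    3.49e-08  *
true_conjugate            mm         122.83 (8.47)      114.15 (9.21)     6.94     5.5e-11  *
...
bis_ischiatic_diameter    mm         117.62 (11.04)      101.03 (11.32)    10.49    9.46e-21  *
pelvic_depth              mm         103.29 (9.45)      110.16 (7.97)    -5.56    8.84e-08  *
...
inlet_depth_ratio                      1.23 (0.13)        1.10 (0.10)     8.53    3.84e-15  *
```

The synthetic female cohort shows the expected dimorphism: a wider inlet
and outlet (obstetric conjugate 126.5 vs 120.1 mm; bis-ischiatic diameter
117.6 vs 101.0 mm) but a shallower pelvis (depth 103.3 vs 110.2 mm),
hence a larger inlet/depth ratio (1.23 vs 1.10) — a rounder, shorter
female pelvis versus a narrower, deeper male one.

The power analysis used to size such a comparison:

```python
print(p.t_power(d=0.4, n1=100, n2=100, alpha=0.05))
```

```
two-sample t-test power analysis (two-tailed)
  effect size d   = 0.4
  alpha           = 0.05
  n1, n2          = 100, 100
  noncentrality   = 2.8284271
  critical t      = 1.9720175
  df              = 198
  achieved power  = 0.8036475
```

i.e. two groups of 100 detect a medium-small effect (d = 0.4) with 80%
power at the two-sided 5% level.

The same pipeline is scriptable from the shell:

```bash
pelvimetry3d simulate --sex female --n 100 --seed 7 --out fem/ --raster --spacing 2
pelvimetry3d segment  --in fem/female_0000.nrrd --out mask.nrrd
pelvimetry3d mesh     --in mask.nrrd --out pelvis.stl        # prints the volume audit
pelvimetry3d measure  --cohort-dir fem/ --out records.csv
pelvimetry3d compare  --records records.csv --labels labels.csv --out table.csv
pelvimetry3d power    --d 0.4 --n1 100 --n2 100
```

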
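# svef3d — segmental volume analysis of the left ventricle

Regional left-ventricular (LV) wall motion is usually graded by eye on 2D
echocardiography — subjective, semiquantitative and reader-dependent.
Volumetric 3D echocardiography makes an objective alternative possible: track
the endocardial surface over one cardiac cycle, split it into the standard 17
AHA segments, and let each segment's own volume-time curve quantify its
contraction.  `svef3d` implements that analysis end to end for researchers
working with closed endocardial surface meshes (or wanting a fully synthetic
test bed for such pipelines).

The central quantity is the **segmental volume ejection fraction**.  For each
segment *s*, with EDV and ESV the largest and smallest values of that
segment's volume-time curve,

```
SVEF_s = (EDV_s − ESV_s) / EDV_s × 100  (%)
```

and the global EF follows the identical rule on the summed curve.  Around it
the package provides:

- **`phantom`** — a deforming LV phantom (truncated prolate spheroid, radial
  contraction `r(θ,z,t) = R(z)·(1 − A·s(θ,u)·g(t))`) with a configurable
  regional wall-motion abnormality confined to one coronary territory, plus a
  two-Gaussian generator of SVEF score populations.
- **`aha`** — the 17-segment AHA partition from the standard landmark set
  (four mitral-annular points, apex, mid-septum) and the typical ASE/EACVI
  coronary territory templates (LAD = {1,2,7,8,13,14,17}, RCA = {3,4,9,10,15},
  LCX = {5,6,11,12,16}).
- **`volumes`** — per-segment cavity volumes by signed tetrahedral
  decomposition to the long axis, with exact conservation (17 segmental
  volumes sum to the cavity volume) and no geometric shape assumption.
- **`svef`** — EDV/ESV, SVEF and the per-subject table.
- **`roc`** — Mann–Whitney AUC, Youden-optimal abnormality cutoff,
  Hanley–McNeil CI; model 1 (fixed SVEF cutoff) and model 2 (SVEF normalised
  by the subject's global EF), with EF-stratified variants.
- **`bullseye`** — two-color 17-segment polar maps and culprit-artery
  prediction by Jaccard matching of the abnormal pattern against the
  territory templates.
- **`agreement`** — Cohen κ with the Fleiss–Cohen–Everitt CI, ICC(2,1) and
  friends, one-way ANOVA with Bonferroni post hoc, two-group summaries.

## Worked example

```python
from svef3d import (PhantomConfig, generate_phantom, build_svef_table,
                    tag_segments, predict_culprit)

seq = generate_phantom(PhantomConfig(rwma_territory="LAD", rwma_severity=0.3,
                                     noise_sd=0.5, seed=42))
table = build_svef_table(seq, subject_id="demo")
print(round(table.global_ef, 1))            # 36.7  (% global EF)
bmap = tag_segments(table, cutoff=44.0)
print(sorted(bmap.abnormal))                # [1, 2, 7, 8, 13, 14, 17]
print(predict_culprit(bmap).artery)         # LAD
```

A hypokinetic LAD territory (contraction scaled to 0.3 of normal) drops the
seven LAD-template segments to ≈17–22% SVEF while the remaining segments stay
near the ≈51% of a normally contracting phantom; tagging at the 44% cutoff
recovers exactly the LAD template and the Jaccard match names the left
anterior descending artery as the culprit.  The `examples/` directory walks
through each capability (`01` phantom and volume curves, `02` SVEF and
bull's-eye, `03` ROC cutoff, `04` agreement statistics); each script prints
the numbers it computes.  A thin CLI mirrors the same steps
(`svef3d simulate | volumes | svef | roc | bullseye | classify | agree |
reproduce`).

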
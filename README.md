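# myoaniso

Analysis pipeline for **anisotropy of ultrasonic backscatter** in short-axis
myocardial B-mode images, with the companion histology readouts: picrosirius-red
polarized-light collagen quantification and circular statistics of
myocyte/fiber orientation. A synthetic-data generator reproduces the structure
of the collagenase-perfusion experiment the analysis was designed for, with
exact ground truth, so every stage of the pipeline can be validated by
parameter recovery.

## Who this is for

Researchers quantifying myocardial fibrosis and collagen organisation from
ultrasound: backscatter intensity depends on the angle between the beam and
the tissue's collagen/myofiber axis, being maximal where fibers lie
perpendicular to the angle of insonification. In a short-axis left-ventricular
view the anterior and posterior walls hold predominantly perpendicular fibers
and the lateral and septal walls predominantly parallel ones, so the
*difference* in mean backscatter between those walls — the Anisotropy Index —
tracks collagen organisation (crosslinking), not just collagen amount.

## The statistics at the core

For mean ROI backscatter `I_pos` at the four cardinal mid-myocardial walls,
the four pairwise indexes and their average are

    AI_pq        = I_p − I_q,   p ∈ {anterior, posterior}, q ∈ {lateral, septal}
    AI_avg       = (|AI_AL| + |AI_AS| + |AI_PL| + |AI_PS|) / 4

ROIs are 250 × 250 µm squares centred half-way between the endocardial and
epicardial ellipses on the four cardinal rays. Collagen content of a
picrosirius-red micrograph is the percentage of pixels with 8-bit hue in 2–128
after blue- and black-component subtraction (red/orange 2–38, yellow 39–51,
green 52–128, all inclusive). Fiber disarray is the Batschelet angular
deviation `s = √(2(1−r))` with `r` the mean resultant length, computed on
doubled angles for axial data.

## Worked example

```python
import numpy as np
from myoaniso import (PhantomParams, TreatmentProtocol, default_geometry,
                      generate_treatment_series, build_series,
                      index_timecourse, fit_decay)

params = PhantomParams(image_size_px=(160, 160), pixel_size_um=25.0, seed=0)
geometry = default_geometry(params)                      # circular annulus
protocol = TreatmentProtocol(arm="collagenase30", decay_rate_per_min=0.1)

frames = generate_treatment_series(geometry, params, protocol, heart_id="demo")
series = build_series(frames, geometry)                  # 4 walls x 13 frames
tc = index_timecourse(series)
print(tc[["timepoint_min", "average_index"]].head(3).to_string(index=False))
fit = fit_decay(tc, stop_min=30.0, method="signed")
print(fit.summary())
```

Output:

```
 timepoint_min  average_index
           0.0      27.903096
           2.5      20.620098
           5.0      23.765032
Anisotropy-index exponential decay fit
  model      : index(t) = gap0 * exp(-k * min(t, 30))
  gap0 (a.u.): 28.81
  k (1/min)  : 0.101
  points used: 13 (excluded non-positive: 0)
  log-RSS    : 159.2
```

The average index starts near the true perpendicular/parallel gap (30 a.u.)
and decays, with speckle noise, as the simulated collagenase digestion closes
the gap; the fitted rate 0.101/min recovers the true 0.1/min from a single
speckled heart.

The same pipeline runs from the shell over a whole synthetic cohort
(8 control + 7 + 7 collagenase hearts):

```bash
myoaniso full --out run --seed 1
# -> run/backscatter.csv, anisotropy.csv, fits.json, histology.csv,
#    circstats.csv, circstats_pooled.csv, manifest.json
```

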
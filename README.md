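# platemech

Single-platelet mechanophenotyping by real-time fluorescence and
deformability cytometry (RT-FDC), as a reusable, tested Python pipeline.

Platelets are anucleate, discoidal cell fragments whose cytoskeleton-
dependent mechanics matter for haemostasis and for diagnosing inherited
platelet disorders.  In RT-FDC, platelets in platelet-rich plasma are
driven through a 15 × 15 µm microfluidic constriction; each cell is imaged
in bright field, its contour traced, and its shape summarised by the
isoperimetric deformation

> deformation = 1 − 2·√(πA) / P

(A: projected area, P: contour perimeter; 0 for a circle), alongside
per-event fluorescence maxima (CD61 identity gate, CD62P degranulation,
PAC-1 activated integrin αIIbβ3).  The choice of ex vivo anticoagulant
(ACD-A, Na-Citrate, K2-EDTA, Li-Heparin, r-Hirudin) is a critical
pre-analytical variable: it shifts resting deformation and size and blunts
or preserves the TRAP-6 response.  `platemech` is written for researchers
who want to analyse such event data — or prototype analyses without an
instrument, via a synthetic generator calibrated to published
condition-level values, including TRAP-6 stimulation, latrunculin-B
softening and an MYH9-like (large, stiff) macrothrombocytopenia phenotype.

## What is in the box

| module | contents |
| --- | --- |
| `platemech.synthetic` | ellipse shape model (exact elliptic-integral perimeter), calibrated condition presets, multi-donor event sampling, bright-field frame and confocal two-channel rendering |
| `platemech.imaging` | background-threshold segmentation with sub-pixel marching-squares boundary tracing, contour area / perimeter / convex-hull area ratio |
| `platemech.features` | the deformation metric, hard gates (CD61 150–33000 AU, area ratio ≤ 1.1, size 0–10 µm²), acquisition stop (5000 events / 600 s), gate audits |
| `platemech.stats` | per-sample medians, geometric-mean fluorescence, percent positive, stimulation fold changes, KDE event densities, tidy multi-donor tables |
| `platemech.lineprofile` | 5 µm × 1 µm confocal line profiles, tubulin ring edge-to-edge distance, F-actin peripheral index |
| `platemech.io` / CLI | CSV/TSV + HDF5 event stores with full provenance metadata; `platemech simulate / process / gate / summarize / profile` |

## Worked example

Simulate a paired six-donor ACD-A experiment (resting vs TRAP-6), gate it
with the default acquisition gates, and summarise:

```python
import numpy as np
from platemech import synthetic, features, stats

panel = synthetic.simulate_donor_panel(
    ["ACD-A:none", "ACD-A:TRAP-6"], n_donors=6, n_events=5000, seed=1)
records = features.events_from_analytic(panel)

summaries = {}
for (donor, cond), sample in records.groupby(["donor_id", "condition_label"]):
    gated, audit = features.apply_gates(sample, features.GateConfig())
    summaries[(donor, cond)] = stats.summarize_sample(gated)

table = stats.condition_panel_table(list(summaries.values()))
print(stats.condition_means(table).round(4).to_string(index=False))

folds = [stats.fold_change(summaries[(d, "ACD-A:TRAP-6")],
                           summaries[(d, "ACD-A:none")], "deformation").ratio
         for d in sorted({d for d, _ in summaries})]
print("mean deformation fold change:", round(float(np.mean(folds)), 2))
```

Output:

```
condition_label             metric      mean       sd  n_donors
   ACD-A:TRAP-6         gmean_CD61 2123.5655 162.0554         6
   ACD-A:TRAP-6        gmean_CD62P  239.9341 165.0224         6
   ACD-A:TRAP-6         gmean_PAC1  114.6493  56.3845         6
   ACD-A:TRAP-6    median_area_um2    3.8520   0.5809         6
   ACD-A:TRAP-6 median_deformation    0.0402   0.0143         6
     ACD-A:none         gmean_CD61 2141.7997 163.0156         6
     ACD-A:none        gmean_CD62P   10.0747   2.1899         6
     ACD-A:none         gmean_PAC1   35.1275   5.7348         6
     ACD-A:none    median_area_um2    4.7798   0.4940         6
     ACD-A:none median_deformation    0.1138   0.0207         6
mean deformation fold change: 3.01
```

Read it as a wet-lab result: resting ACD-A platelets deform at a median of
≈ 0.11 (condition mean of donor medians; the calibration target is
0.127 ± 0.033, and this seed's six donors landed within one between-donor
SE).  TRAP-6 stimulation drops deformation to ≈ 0.04 — a mean fold change
of 3.0 against the calibrated 2.76 ± 0.64 — shrinks the cells, and raises
CD62P ≈ 24-fold and PAC-1 ≈ 3-fold, the expected activation signature.

The same flow is available from the shell:

```sh
platemech simulate --preset ACD-A:none --preset ACD-A:TRAP-6 \
    --donors 6 --events 5000 --seed 1 --out events.h5
platemech gate --in events.h5 --out gated.h5
platemech summarize --in gated.h5 --out summary.csv --aggregate-out means.csv
```

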
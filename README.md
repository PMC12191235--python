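# radassay

Quantification pipelines for radiation-response assays in cultured cells —
built for studies of radioresistance and of radioprotection transferred by
small extracellular vesicles (sEVs), where the readouts are single-cell
biosensor imaging, DNA-damage foci, colony formation, dye-uptake flow
cytometry, bulk viability and mitochondrial respirometry.

The centrepiece is single-cell death calling with the GEDI biosensor
(Genetically Encoded Death Indicator): cells co-express a calcium sensor
(GC150, green) and a constitutive marker (mApple, red). Apoptotic commitment
triggers an irreversible calcium influx, so the per-cell ratio

```
R = mean GC150 intensity / mean mApple intensity
```

steps from a low "live" value to a high "dead" value. A cell is scored dead
at the first scheduled imaging timepoint where `R > theta` (threshold
calibrated from a lethal 25 Gy exposure, conventionally `theta = 1`) or
where a previously tracked cell has disappeared from the field of view
(dead cells detach). The resulting event/censor times feed a Kaplan–Meier
product-limit estimate

```
S(t) = prod_{t_i <= t} (1 - d_i / n_i)
```

and log-rank comparisons between treatment arms (e.g. increasing sEV doses
against control).

Because no suitable public imaging data exist for these assays, the package
ships a first-class synthetic-data module (`radassay.synthgen`) that
generates every input — timelapse TIFFs, foci fields, colony images,
flow-cytometry event tables, oxygen-consumption traces — together with
machine-readable ground truth, so the full pipeline is testable end to end.

## Modules

| module | contents |
| --- | --- |
| `radassay.synthgen` | generators + ground truth for all assay inputs |
| `radassay.imgseg` | rolling-ball background subtraction, PSF sharpening, thresholding, labeling, red-channel cell masks, DAPI nuclear masks |
| `radassay.gedifate` | GEDI ratios, greedy nearest-centroid tracking, threshold calibration, fate calling, Kaplan–Meier, log-rank |
| `radassay.focicount` | 53BP1 / γ-H2AX puncta detection (≥10× background rule), per-cell counts, ANOVA/Tukey comparisons |
| `radassay.plateassays` | viability normalisation, colony counting, flow gating and MFI, sEV particles-per-cell dosing, Seahorse-style stress-test metrics |
| `radassay.io` | FrameStack container, multi-page TIFF round-trip |
| `radassay.cli` | `radassay` command: `simulate`, `segment`, `gedi`, `foci`, `viability`, `colonies`, `flow`, `ocr` |

## Worked example

Simulate a radioprotection experiment (120 cells, control death hazard
0.12/h vs 0.04/h under high-dose sEV pre-treatment), run the imaging
pipeline, and compare survival:

```python
import numpy as np
from scipy.spatial import cKDTree
from radassay import synthgen as sg, imgseg, gedifate as gf

params = sg.TimelapseParams(
    n_cells=120,
    hazard_per_group={"control": 0.12, "sev_high": 0.04},
    seed=42,
)
frames, truth = sg.gen_timelapse(params)

tables = {f.timepoint_h: imgseg.segment_cells_red(f).table for f in frames}
tracks = gf.track_cells(tables, max_displacement_px=12)

tree = cKDTree(truth.cells[["row", "col"]].to_numpy())
for t in tracks:                       # label tracks with their condition
    if t.present[0]:
        _, i = tree.query([t.centroid_row[0], t.centroid_col[0]])
        t.group = truth.cells["group"].iloc[i]

fates = gf.call_fates(tracks, theta=1.0, schedule=(0, 6, 12, 18))
for g in ("control", "sev_high"):
    print(g, "S(18h) =", round(gf.km_curve(fates[fates.group == g]).survival_at(18.0), 3))
print(gf.logrank(fates, control="control").summary())
```

Output:

```
control S(18h) = 0.1
sev_high S(18h) = 0.6
Log-rank test
  chi2 = 40.15  df = 1  p = 2.356e-10
  pairwise:
    control vs sev_high: chi2 = 40.15  p = 2.356e-10  p_bonferroni = 2.356e-10
```

Read: by 18 hours post-irradiation only 10% of control cells are still
alive versus 60% of sEV-pre-treated cells; the log-rank test rejects equal
survival decisively. The same analysis is available from the shell:

```sh
radassay simulate --preset gedi --seed 42 --out sim/
radassay segment sim/timelapse.tif --out objects.csv
radassay gedi objects.csv --theta 1.0 --schedule 0,6,12,18 --out results/
```

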
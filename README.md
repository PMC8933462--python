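# octaquant

Quantitative flow analysis of en-face optical coherence tomography
angiography (OCTA) images, with a synthetic-eye simulator for studying how
image signal strength distorts flow metrics.

OCTA devices report a 0–10 signal strength (SS), and a change in SS — from
media opacity, small pupils, or a neutral density filter (NDF) placed in the
beam — changes the binarized flow maps and every quantity computed from
them. `octaquant` packages the standard FIJI-style quantification workflow
as a tested library so this sensitivity can be measured end-to-end on
synthetic cohorts where the ground truth is known: phantom retinas are
rendered under controlled attenuation, quantified exactly as real exports
would be, and pushed through the repeated-measures statistics a clinical
reading would use.

It is intended for OCTA methodologists and image-analysis engineers; the
public face is the importable API plus the short scripts in `examples/`. A
thin `octaquant` command-line interface covers the file-based workflows
(`simulate`, `quantify`, `experiment`, `analyze`, `report`).

## What it computes

For a 6 × 6 mm en-face slab image of the superficial (SCP) or deep (DCP)
capillary plexus, or the choriocapillaris (CC):

* **Binarization.** Retinal slabs are binarized along two chains and
  intersected: (a) single-scale Frangi-type Hessian vesselness followed by
  Huang's minimum-fuzziness global threshold, and (b) a circular-window
  local-median threshold (radius 15 px). The CC is binarized with
  Phansalkar's local threshold,
  `t = m·(1 + p·e^{−q·m} + k·(s/r − 1))` with the published
  `k=0.25, r=0.5, p=2, q=10` and a 15-px radius (43.94 µm at a 2048-px
  raster).
* **Large-vessel masking.** Superficial arterioles/venules are segmented
  from the SCP (Gaussian smoothing, Kapur maximum-entropy threshold,
  caliber-based opening, 2-px dilation) and excluded from DCP/CC
  quantification — projection and shadow artifacts count neither as flow
  nor as deficit.
* **Metrics.** Vessel density `VD = 100·|flow ∧ ¬mask| / |¬mask|`; vessel
  length density `VLD` computed the same way on the Zhang–Suen skeleton;
  CC flow deficit `CCFD = 100 − VD` of the CC map.
* **Acquisition model.** NDF transmittance `T = 10^(−OD)` (OD 0.3 ≈ 50 %
  reduction, OD 0.6 ≈ 75 %), device sampling grids `6000/350 = 17.1 µm`
  (spectral-domain) and `6000/420 = 14.3 µm` (swept-source), a bounded
  multiplicative speckle model, an additive noise floor, and a device-style
  SS score mapping contrast-to-noise onto 0–10.
* **Statistics.** Shapiro–Wilk/Lilliefors normality routing into either
  one-way repeated-measures ANOVA or the Friedman test, Bonferroni-corrected
  pairwise paired-t / exact Wilcoxon signed-rank tests, and pooled Pearson
  correlation + OLS regression of SS against each flow metric.

## Worked example

```python
from octaquant import (AcquisitionSetting, PhantomParams, generate_phantom,
                       quantify_slab, render_slab)

phantom = generate_phantom(seed=3, params=PhantomParams(side=256))
acq = AcquisitionSetting.for_device("SS", ndf_od=0.0, seed=2)

scp = render_slab(phantom, "SCP", acq)
for slab in ("SCP", "DCP", "CC"):
    img = scp if slab == "SCP" else render_slab(phantom, slab, acq)
    m = quantify_slab(img, scp)
    print(slab, m.vd_pct, m.vld_pct, m.ccfd_pct)
```

prints (see `examples/02_quantify_slabs.py`):

```
SCP: VD  32.6%, VLD  12.2%   (ground-truth flow fraction 34.0%)
DCP: VD  37.3%, VLD  13.8%   (ground-truth flow fraction 38.0%)
CC: VD  73.0%, CCFD  27.0%   (ground-truth flow fraction 75.0%)
```

i.e. at full signal the pipeline recovers the phantom's designed flow
fractions to within a few percentage points, and the CC deficit is the
complement of CC flow. Running the cohort experiment
(`examples/03_cohort_experiment.py`) shows the attenuation effect: on the
spectral-domain model the cohort-mean CC flow deficit climbs
27.0 → 41.8 → 94.4 % as the filter OD runs 0 → 0.3 → 0.6 while SS falls
10 → 6.7 → 3.3, and SCP vessel density never increases; the swept-source
model shows the same directions but shallower, and the pooled Pearson
correlation between SS and CCFD is strongly negative on both device models.

The same workflows are available from the shell:

```bash
octaquant simulate --n-subjects 1 --side 256 --seed 7 --out-dir sim/
octaquant quantify --scp sim/subject1_SCP_SD_od0.0_rep0.tif --out metrics.csv
octaquant report --n-subjects 20 --seed 1 --out-dir results/
```

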
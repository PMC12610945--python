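# agescore

Quantification of cellular aging markers and their aggregation into a
composite **AgeScore**, for accelerated-aging cell-culture studies such as
doxycycline-inducible progerin expression in human microglia (HMC3).

Biological age in vitro is not a single number that any one assay measures.
The AgeScore approach instead measures a panel of classic aging hallmarks —
per-cell, from fluorescence microscopy and companion tabular assays —
statistically tests each marker against the non-induced control, binarizes
the outcome, and sums:

* **primary hallmarks** (causes of damage): γ-H2A.X DNA-damage foci ↑,
  H3K9Me3 heterochromatin ↓, telomere content ↓;
* **antagonistic hallmarks** (responses to damage): p21 ↑, p16 ↑,
  SA-β-Gal activity ↑, IL-6 ↑, IL-8 ↑ (SASP), Lamin B1 ↓, nucleus area ↑.

A marker is rated **1** at a timepoint only when its condition effect is
significant (*p* < 0.05 on per-well averages) *and* in the direction
expected with age; otherwise **0**. The primary and antagonistic ratings
sum to the primary and antagonistic AgeScores, and their total is the
**full AgeScore** (0–10 with this panel).

The package provides:

* `agescore.imagequant` — per-cell image readouts: nucleus segmentation,
  focus counting per nucleus (intensity window 20–200, minimum size 5 px),
  corrected total cell fluorescence
  (CTCF = integrated density − area × mean background), nuclear
  morphometrics (area, solidity, form factor 4πA/P²), nucleocytoplasmic
  ratios, cytoplasmic puncta, phagocytic-cell fractions;
* `agescore.assayquant` — ΔΔCt relative expression, telomere T/S ratio
  from a standard dilution series with CV < 0.3 QC, technical-duplicate
  averaging, scratch-wound closure;
* `agescore.markerstats` — per-well aggregation (wells are the biological
  replicates), Welch t-test / one-way ANOVA + Tukey / two-way ANOVA +
  Sidak per-timepoint contrasts, direction-aware binarization;
* `agescore.scoring` — AgeScore aggregation and scorecard rendering, plus
  the packaged reference rating matrix of the progerin-microglia study;
* `agescore.synthetic` — a ground-truthed synthetic study generator
  (scenes + assay tables) so the whole chain is testable end to end;
* a CLI: `agescore simulate | quantify | score | run`.

## Worked example

Simulate the default two-arm (−DOX / +DOX), 3/7/14-day study with the
default effect preset (DNA damage, H3K9Me3, SA-βGal, IL-6/IL-8 and
Lamin B1 shifted at all timepoints, nucleus area only at 14 days; telomere,
p16 and p21 left null), quantify every scene and table, test, and score:

```python
import agescore as ag
from agescore import pipeline

result = pipeline.run_study(ag.StudyDesign(seed=1))
print(result.trajectory)
# [0, 6, 6, 7]
```

The trajectory is the full AgeScore of the control column followed by the
induced arm at 3, 7 and 14 days: the planted aging pattern is recovered
from the pixels and Ct values, not copied from the ground truth. The same
run from the shell:

```sh
agescore run --seed 1 --out runs/demo
# full AgeScore trajectory: [0, 6, 6, 7]
```

`runs/demo/` then contains `measurements.csv` (per-well marker values),
`calls.csv` (p-value, direction and 0/1 rating per marker × timepoint) and
the scorecard. The packaged reference rating matrix renders to the same
scorecard layout:

```python
from agescore.scoring import (REFERENCE_COLUMNS, compute_agescore,
                              reference_marker_calls, write_scorecard)
results = {c: compute_agescore(reference_marker_calls(c))[0]
           for c in REFERENCE_COLUMNS}
write_scorecard(results, "scorecard")
```

| marker                | category     | control | day3 | day7 | day14 |
|:----------------------|:-------------|--------:|-----:|-----:|------:|
| gamma_h2ax            | primary      |       0 |    1 |    1 |     1 |
| h3k9me3               | primary      |       0 |    1 |    1 |     1 |
| telomere              | primary      |       0 |    0 |    0 |     0 |
| p21                   | antagonistic |       0 |    0 |    0 |     0 |
| p16                   | antagonistic |       0 |    0 |    0 |     0 |
| sa_bgal               | antagonistic |       0 |    1 |    1 |     1 |
| il6                   | antagonistic |       0 |    1 |    1 |     1 |
| il8                   | antagonistic |       0 |    1 |    1 |     1 |
| lamin_b1              | antagonistic |       0 |    1 |    1 |     1 |
| nucleus_area          | antagonistic |       0 |    0 |    0 |     1 |
| primary AgeScore      |              |       0 |    2 |    2 |     2 |
| antagonistic AgeScore |              |       0 |    4 |    4 |     5 |
| full AgeScore         |              |       0 |    6 |    6 |     7 |

## Documentation

`docs/methods.md` describes the measurement models, the statistics, the
synthetic-data generator and its limits, and the numerical design choices.
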
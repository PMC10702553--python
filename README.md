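# gratio

Automated selection of myelinated nerve fibers and g-ratio morphometry for
optical-microscopy cross-sections.

In semi-thin stained nerve sections (PPD or toluidine blue), each
myelinated fiber shows an axon wrapped in a myelin ring. The **g-ratio**
— inner over outer diameter of the myelin sheath — quantifies relative
myelin thickness, but manual measurement is slow and biased, and not every
sectioned fiber is measurable: obliquely cut, incomplete or tiny profiles
must be rejected first. `gratio` implements the full automated chain:

1. **Segmentation** of axon / myelin / background — a trainable U-Net
   (two conv–BN–PReLU layers per depth, Dice loss, Adam) implemented in
   pure numpy, plus a deterministic oracle backend for validation;
2. **Post-processing** — probability thresholding at 0.8 with
   axon > myelin priority, then filling of enclosed cavities larger than
   5 px;
3. **Fiber extraction & selection** — per-axon instances with myelin
   assigned by seeded watershed; fibers excluded when axon eccentricity
   > 0.95, solidity < 0.9, or area < 50 px;
4. **Morphometry** — per fiber, with region = axon ∪ myelin:
   AVF = |axon|/|region|, MVF = |myelin|/|region|, and

       g = √(1 / (1 + MVF/AVF)) = √(AVF),

   plus area-equivalent axon diameter and myelin thickness in μm
   (default sampling 0.05 μm/px);
5. **Reliability statistics** — ICC(3,1) with F-based CI and qualitative
   bands (<0.50 poor, 0.50–0.75 fair, 0.75–0.90 good, ≥0.90 excellent),
   Bland–Altman limits of agreement, Shapiro–Wilk gated Wilcoxon /
   paired-t comparison, and one-way ANOVA across parallel sections.

A built-in **phantom generator** renders stylized stained sections with
exact per-fiber ground truth — including oblique, incomplete and
undersized nuisance fibers constructed strictly beyond the selection
thresholds — so the whole pipeline is testable without any histology data.

## Worked example

```python
import pandas as pd
from gratio import generate_scene
from gratio.pipeline import PipelineConfig, run_pipeline

# 23 fibers: 12 clean + 5 oblique + 3 incomplete + 3 undersized
scene = generate_scene(
    512, 512, 23, (8, 20),
    {"oblique": 5/23, "incomplete": 3/23, "undersized": 3/23},
    seed=3,
)
summary = run_pipeline(scene, PipelineConfig(), "runs/demo")
print(summary["n_fibers"], summary["n_selected"], summary["exclusion_counts"])
g = summary["selected_morphometrics"]["g_ratio"]
print(round(g["mean"], 3), "+/-", round(g["sd"], 3))
```

prints

```
23 12 {'solidity': 3, 'area': 3, 'eccentricity': 5}
0.6 +/- 0.001
```

All 23 fibers are found; exactly the 12 clean ones survive selection, each
rejected fiber carrying the reason that matches its designed defect, and
the mean g-ratio of the selected fibers recovers the design value 0.6 to
within pixelation error. The run directory contains the label mask
(`mask.png`, codes 0/1/2), instance maps (`instances.tif`), per-fiber
tables (`fibers.csv`, `morphometrics.csv`), `summary.json`, the config and
a log listing every exclusion.

The same chain is available from the shell:

```bash
gratio phantom --width 512 --height 512 --n-fibers 23 --seed 3 --out-dir scene/
gratio run --mask scene/mask.png --out-dir runs/demo
gratio compare runs/demo runs/other      # staining / section comparison
gratio train --data-dir scenes/ --out model.npz
```

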
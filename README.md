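# histostep

Stepwise (two-stage) fine-tuning for pathology patch classification, plus the
two low-cost "medium-level" dataset builders that make the first fine-tuning
stage cheap:

* **tissue-wise** — background / epithelium / stroma patches cut from
  annotated images by a purity-thresholded grid;
* **cell-wise** — fully automatic: H&E color deconvolution → Phansalkar
  adaptive local thresholding of the hematoxylin channel → watershed
  splitting of touching nuclei → border-following contour tracing → the
  2-D (total nucleus area, nucleus count) feature → K-means pseudo-labels.

Because real clinical data are private, a synthetic-data module renders
ground-truthed H&E-like patches with a Beer–Lambert absorption model
(elliptical hematoxylin-rich nuclei over an eosin background), so every
stage of the pipeline is testable end to end. Training uses a small,
deterministic pure-NumPy CNN backbone (4 conv blocks + swappable head);
larger backbones are out of desk scope but pluggable at the schedule level.

## Layout

| module                    | role                                                       |
| ------------------------- | ---------------------------------------------------------- |
| `histostep.synth`         | synthetic patch generator with ground truth                |
| `histostep.stains`        | optical density + color deconvolution (fixed 3×3 matrix)   |
| `histostep.morphometry`   | local threshold, watershed, contours, (area, count)        |
| `histostep.datasets`      | patch extraction, filtering, K-means, splits, manifests    |
| `histostep.nn`            | minimal NumPy CNN (forward/backward/SGD)                   |
| `histostep.training`      | stage schedules, head swapping, stepwise orchestration     |
| `histostep.evaluation`    | ROC, AUC, accuracy, precision, recall                      |
| `histostep.config` / `cli`| YAML config schema, seed fan-out, `histostep` entry point  |
| `histostep.demo`          | end-to-end synthetic benchmark (one-stage vs two-stage)    |

## CLI

```bash
histostep synth --mode cellwise --n 50 --seed 1 --patch-size 64 --out patches/
histostep separate-stains --in patches/ --out stains/
histostep segment-nuclei --in patches/ --out features.tsv
histostep build-medium --mode cell --features features.tsv --out medium/
histostep train --scheme two-stage --out runs/
histostep evaluate --scores scores.tsv --out report.json
histostep demo --seed 1 --out demo_out/       # full synthetic comparison
```

All commands accept `--config run.yaml`; unknown keys are rejected and every
parameter defaults to the documented module defaults.

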
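# leafbench

Benchmarking how leaf images should be **acquired** and **preprocessed**
for automated plant species identification.

Field botanists and citizen-science projects collect leaf photographs to
train classifiers, but every image costs effort: arranging the leaf,
holding a background sheet, drawing boxes, placing segmentation markers.
`leafbench` implements a controlled evaluation of that trade-off.  Each
*observation* (one leaf individual) is imaged as **nine image types** —
{top, back side} x {flash on, off} x {natural, plain background} plus a
destructive *back light* shot against the sky — and prepared with **three
strategies** (none / crop to a bounding box / semi-automated GrabCut
segmentation), giving 27 datasets.  Each dataset is scored by linear-SVM
species classification over repeated observation-consistent 70/30 splits,
and each combination's accuracy `a_i` is related to its per-image manual
effort `e_i` (person-seconds) through the accuracy–effort gain

    G_i = (a_i − a_b) / a_b · e_b / (e_i − e_b)

against the cheapest baseline *b*: a top-side, natural-background,
unpreprocessed image (13.4 person-seconds).

Because no public dataset provides per-pixel ground truth for all nine
conditions, the package ships a seeded synthetic leaf generator (parametric
morphology, venation, clutter, flash specularities, white-balance error,
back-light translucency) with exact masks, boxes and focus points, plus a
simulated user that refines segmentations with logged markers.  See
`docs/methods.md` for the model and all numeric choices.

## Worked example

```python
from leafbench.experiment import ExperimentConfig, evaluate_pipeline
from leafbench.effort import gain, total_effort, BASELINE_KEY

cfg = ExperimentConfig(n_species=3, obs_min=4, obs_max=4, seed=7,
                       n_splits=5, strategies=("none", "crop"))
grid, features, _ = evaluate_pipeline(cfg)
for (img_type, strategy), r in sorted(grid.items(),
                                      key=lambda kv: -kv[1].mean_acc)[:5]:
    print(f"{img_type:24s} {strategy:5s} {r.mean_acc:5.1f} +/- {r.sd_acc:4.1f}")

a_b = grid[BASELINE_KEY].mean_acc
a_i = grid[("backlight", "crop")].mean_acc
e_b = total_effort(*BASELINE_KEY)
e_i = total_effort("backlight", "crop")
print(f"baseline a_b={a_b:.1f}%, e_b={e_b:.1f} person-s")
print(f"backlight+crop a_i={a_i:.1f}%, e_i={e_i:.1f} person-s, "
      f"G={gain(a_i, e_i, a_b, e_b):.3f}")
```

prints (3 species, 4 observations each — a deliberately tiny run):

```
top_flash_on_natural     crop   73.3 +/- 14.9
backlight                none   63.3 +/- 13.9
top_flash_off_plain      crop   60.0 +/-  9.1
back_flash_off_natural   crop   56.7 +/- 19.0
back_flash_off_plain     crop   56.7 +/- 19.0
baseline a_b=26.7%, e_b=13.4 person-s
backlight+crop a_i=46.7%, e_i=42.8 person-s, G=0.342
```

Accuracies are percent of correctly classified test images, mean ± sample
sd over the split replicates.  `G = 0.342` says backlight+crop buys its
accuracy increase at about one third of the relative accuracy gain per
unit of relative extra effort.  At the default desk scale (5 species x 12
observations, 25 splits) the grid shows the expected structure: cropping
raises natural-background accuracy by tens of points, and a back-light
cell tops the grid in nearly every seeded rerun.

The same stages are scriptable from the shell:

```bash
leafbench generate --species 5 --obs-min 12 --obs-max 12 --seed 1 --out run/dataset
leafbench preprocess --strategy crop --manifest run/dataset/manifest.csv --out run/crop --seed 1
leafbench extract --manifest run/crop/manifest.csv --backbone fallback --out run/crop_features.csv --seed 1
leafbench run --config experiment.yaml --out run/   # full orchestrated study
```

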
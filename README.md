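# psimlabel

**Explainable atlas-based auto-labeling for multi-label grayscale images.**

Building labeled corpora is the bottleneck of medical-image model
development: report-mined labels are noisy, expert panels don't scale.
`psimlabel` turns a *validated* multi-label classifier into an
auto-labeler with a reject option: for every image and label it computes a
**pSim** (probability-of-similarity) score, emits the label automatically
when pSim clears a per-label threshold calibrated to PPV/NPV = 1 on a
small reader-labeled subset, and defers everything else to a human. Every
auto-emitted positive label carries its *prediction basis* — the K most
similar patches from the model's own reference atlas — so the decision is
auditable.

It is aimed at researchers studying selective prediction / auto-labeling
pipelines for imaging classifiers; everything runs on synthetic data at
desk scale, on one CPU, with no downloads.

## The score

For label c with ensemble predicted probability `y^c`:

```
Confidence_P = max( f_P(y^c) - (1 - f_N(y^c)), 0 )
Confidence_N = max( (1 - f_N(y^c)) - f_P(y^c), 0 )

patch_similarity = 1 - f_D( mean distance of the input CAM patch
                            to its K nearest atlas patches in a
                            cosine-metric 2-D embedding )

pSim_positive = 2ab / (a + b),  a = Confidence_P, b = patch_similarity
pSim_negative = Confidence_N
```

`f_P`, `f_N` are the empirical CDFs of the training-set predicted
probabilities of positive/negative samples (the *distribution atlas*);
`f_D` is the empirical CDF of the atlas's own mean K-NN distances (the
*patch atlas*, built from CAM patches of training images predicted with
probability >= 0.9). Mode selection: if `y^c >= TH_pos` the image is a
positive candidate and `pSim_positive` is compared with the label's
threshold `theta_PPV1`; otherwise `pSim_negative` is compared with
`theta_NPV1`. At or above threshold the label is emitted (1 or 0); below
it the cell is marked -1 and deferred.

See `docs/methods.md` for the full model, the weighted BCE loss with
ignore labels and view weighting, and every default
(`TrainConfig.full_scale_profile()` holds the full-scale optimizer
settings for larger backbones).

## Worked example

```python
from psimlabel.model import AtlasAutoLabeler, PipelineConfig

cfg = PipelineConfig(master_seed=1)          # 3 labels: focal, global, mixed
model = AtlasAutoLabeler.from_config(cfg)    # synthesizes train/cal/test/pool
res = model.fit()                            # trains, builds atlases, calibrates
print(res.summary())
```

```
Atlas-based auto-labeler
  members: 2 (omegas [1.5, 1.1]), TH_pos = 0.5
  patch atlas: K=5, tau=0.3, inclusion >= 0.9

  label        atlas n  theta_PPV1  theta_NPV1  PPV@theta  NPV@theta
  label0           212        0.24        0.00      1.000      1.000
  label1            96        0.76        0.00      1.000      1.000
  label2           129        0.45        0.18      1.000      1.000
```

Per-label pSim thresholds were chosen as the lowest grid values reaching
PPV = 1 (positive side) and NPV = 1 (negative side) on the ten-bin
stratified calibration subset — by construction PPV/NPV at those
thresholds is 1.000 there. On the held-out test set the trade-off shows up
as intended:

```python
scores = res.evaluate_auroc(model.test_set)
print({k: round(v, 4) for k, v in scores.items()})
# {'label0': 0.9857, 'label1': 0.9289, 'label2': 0.9377}

decisions, capture = res.autolabel(model.pool_set)
print(capture[0])
# {'n': 400, 'self_positive': 98, 'self_negative': 254,
#  'reannotation': 48, 'capture_fraction': 0.88}
```

88% of the pool was auto-labeled for the focal label at PPV/NPV-calibrated
thresholds; the remaining 12% was flagged for human review.
For the focal label, raising the threshold from 0 to the calibrated 0.24
lifts held-out PPV from 0.84 to 0.99 while capture falls from 136 to 89
positives — accuracy is bought with labeling efficiency, and the price is
visible. Auto-labeled exams with at least one positive label (test set
excluded) can then fine-tune the ensemble:

```python
retrain = res.select_for_retraining(decisions, model.pool_set,
                                    test_ids=model.test_set.ids)
res_ft = res.finetune(retrain, test_ids=model.test_set.ids)
after = res_ft.evaluate_auroc(model.test_set)
print({k: round(v, 4) for k, v in after.items()})
# {'label0': 0.9863, 'label1': 0.9293, 'label2': 0.9379}  # preserved/improved
```

The same pipeline is scriptable from the shell:

```bash
psimlabel run-all --seed 1 --workdir run1        # everything + report.json
psimlabel synth --workdir run2                   # or stage by stage:
psimlabel train --workdir run2
psimlabel build-atlas --workdir run2
psimlabel calibrate --workdir run2
psimlabel autolabel --workdir run2 --split pool
psimlabel retrainset --workdir run2
psimlabel finetune --workdir run2
psimlabel eval --workdir run2
```

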
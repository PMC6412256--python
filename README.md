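# odsensor

A non-invasive "software sensor" that estimates the optical density (OD, a
biomass proxy) of a shake-flask culture from colour images. The pipeline:

1. **colourspace** — decode PNG/JPEG frames to sRGB and convert to CIELAB
   (D65); whole-image means serve as an illumination reference.
2. **segmentation** — K-means pixel clustering in CIELAB (own Lloyd
   implementation with k-means++ seeding, restarts and empty-cluster
   repair), elbow-based choice of K, and region-of-interest tracking: each
   frame is segmented independently, the cluster nearest to a running
   reference centre is matched, and the reference is updated with the mean
   of the four replicate frames' matched centres.
3. **features** — per-timepoint colour summaries and a 9-predictor log-log
   design matrix: the region colour, the experiment's baseline colour
   (first retained measurement, t = 0.5 h) and the whole-image reference
   colour. The t = 0 row is dropped (OD is 0 by blank definition).
4. **model** — OLS with rank reporting, R², back-transformed OD
   prediction, residual autocorrelation with the ±2/√N whiteness band, a
   one-sample KS normality check, and both leave-one-experiment-out and
   (shuffled) leave-one-out cross-validation with pooled held-out R².
5. **synthetic** — fully deterministic fixture campaigns: exponential
   growth with dilution-emulating OD readings, an OD→Lab medium-colour
   model calibrated against a reference trajectory, and a schematic flask
   scene renderer (two backdrop styles, illumination jitter, ground-truth
   masks). No real images ship with the package; everything is testable
   offline.
6. **cli** — `odsensor` command with `simulate`, `segment`, `features`,
   `fit`, `crossval`, `predict`, `diagnose` and `run` subcommands.

## Quick start

```bash
# generate a small synthetic campaign (images + manifest + ground truth)
odsensor simulate --experiments 6 --timepoints 8 --height 96 --width 128 \
    --seed 1 --out scratch/campaign

# run the full pipeline on it
odsensor run scratch/campaign --out scratch/bundle --k 9 --seed 1 \
    --subsample 6000
cat scratch/bundle/report.json
```

Or in Python, without touching disk:

```python
from odsensor.synthetic import CampaignSpec, generate_campaign
from odsensor.cli import PipelineConfig, run_campaign

campaign = generate_campaign(CampaignSpec(image_size=(128, 170), seed=11))
result = run_campaign(campaign, PipelineConfig(k=9, seed=7, subsample=6000))
print(result.cv.r_squared)        # pooled leave-one-experiment-out R^2
```

## Notes

- The interactive "choose the cluster of interest" step is exposed
  non-interactively as a cluster index or a reference Lab colour
  (`--roi-index` / `--roi-lab`); synthetic runs default to the ground-truth
  medium colour of the first frame.
- CIELAB a/b channels can in principle be non-positive, which breaks the
  plain log transform; this raises a clear error by default and can be
  handled with the `log_offset` shift (recorded in the model metadata).
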
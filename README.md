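# naunet — neighbored-attention U-Net for retinal vessel segmentation

Retinal vessel morphology in fundus photographs is a diagnostic signal for
diabetic retinopathy, and segmenting the vessels — a per-pixel binary
labelling — is the first step of many automated screening pipelines. This
package implements the **neighbored-attention U-Net (NAU-Net)**: a five-level
U-Net in which, at each decoder level, the two *neighbouring* encoder feature
maps are fused (the deeper map is up-convolved and concatenated onto the
shallower one) and the fused skip is re-weighted by an additive attention
gate before entering the decoder,

&nbsp;&nbsp;&nbsp;&nbsp;q_L = σ₁(W_g d_L + W_x e′_L),&nbsp;&nbsp;
α_L = σ(ψ(q_L)) ∈ (0, 1),&nbsp;&nbsp;
s_L = α_L ⊙ e′_L,

with σ₁ = ReLU and 3×3 gate convolutions. The design sits between the
attention U-Net (which gates only same-level skips) and U-Net++ (which fuses
all levels through nested dense pathways), trading a small parameter increase
for multi-scale skips at much lower cost than dense nesting. Both baselines
are included, as are the BCE-Dice training loss, the Dice/IoU/accuracy/
precision evaluation protocol, readers for the DRIVE, HRF and CHASE_DB1
dataset layouts, a synthetic-fundus generator (so everything is testable
offline), and a static profiler that accounts parameters, activation memory,
FLOPs and MAdds. The networks, reverse-mode autodiff and optimizer are
implemented directly on NumPy — there is no deep-learning framework
dependency.

## Worked example

Generate synthetic fundus images, train a reduced-width NAU-Net, and
evaluate on held-out images (about half a minute on a laptop CPU):

```bash
naunet synth --seed 0   --size 64 --n 24 --out data
naunet synth --seed 900 --size 64 --n 8 --split test --out data
naunet train --config config.yaml --data data --out nau.npz
naunet eval  --checkpoint nau.npz --data data --split test --size 64 --out summary.csv
```

with `config.yaml`:

```yaml
model:
  variant: nau_net
  channel_schedule: [8, 16, 32, 64, 128]
  seed: 7
train:
  epochs: 25
  batch_size: 4
  image_size: 64
  seed: 3
```

This prints:

```
wrote 24 samples to data (manifest data/manifest.csv); vessel fraction 0.049-0.266
wrote 8 samples to data (manifest data/manifest.csv); vessel fraction 0.122-0.209
final training loss 0.2538 (25 epochs); checkpoint written to nau.npz
  model    metric     mean      std  n
nau_net      dice 0.932152 0.013962  8
nau_net       iou 0.873204 0.024229  8
nau_net  accuracy 0.983887 0.003586  8
nau_net precision 0.955890 0.024604  8
```

The summary rows are the per-image metrics averaged over the 8 held-out
images (mean ± sample standard deviation): the tiny model recovers 93% Dice
overlap with the true vascular trees after 25 epochs. The same pipeline is
available from Python via `naunet.synthesize_dataset`, `naunet.build_model`,
`naunet.train` and `naunet.evaluate`.

Static complexity accounting of the full-width models at the standard
3×576×576 input:

```
$ naunet profile --input-size 576
         model  params_millions  memory_gb  flops_g  madds_g
attention_unet            34.88       3.62   337.08   673.35
       unet_pp            36.63       7.04   698.81  1396.53
       nau_net            37.25       4.13   423.51   846.27
```

NAU-Net's cost sits between the two baselines while carrying the most
parameters — the extra fusion path is cheap relative to U-Net++'s nested
pathways. See `docs/methods.md` for the architecture details, the counting
conventions behind the profiler, and what the synthetic benchmark does and
does not demonstrate.

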
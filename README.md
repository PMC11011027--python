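# tigerreid

Individual re-identification of striped animals (Amur tigers and other
large quadrupeds with individually distinctive coat patterns) from cropped
camera-trap or surveillance images. Given a query image, the task is to
rank a gallery of sightings so that images of the same individual come
first — the standard query/gallery retrieval protocol of person re-ID,
applied to wildlife monitoring and population counting.

## The model

The descriptor extractor is a serial dual-branch convolutional network:

1. **Backbone** — a 50-layer residual network whose final stage keeps the
   previous stage's resolution (the last down-sampling is removed), giving
   stage maps `C1 ∈ R^256×32×64 … C4 ∈ R^2048×8×16` for a 256×512 input.
2. **Global branch (inverted feature pyramid)** — instead of the classic
   top-down pyramid, fusion runs **bottom-up**: each level is spatially
   down-sampled and channel-expanded onto the next stage and fused
   additively,

   `P1 = ReLU(conv(proj(C1) + C2))`, `P2 = ReLU(conv(proj(P1) + C3))`,
   `P3 = ReLU(conv(proj(P2) + C4))`,

   so shallow stripe texture is carried into the deepest, most semantic
   level. `P3 + C4` is average-pooled into `F_Global ∈ R^2048`.
3. **Local branch (dual-domain attention)** — the fused map is cut into
   4 horizontal blocks; each is max-pooled, reduced to 512 channels by a
   1×1 convolution, gated by channel-then-spatial (CBAM-style) attention
   and a ReLU, giving parts `L1..L4 ∈ R^512` whose concatenation is
   `F_Local ∈ R^2048`.

`[F_Global; F_Local] ∈ R^4096` is the retrieval descriptor; a single
linear layer on top is trained with softmax cross-entropy
`L = −Σ_c y_c log p_c` over identities (SGD, base lr 0.002, classifier lr
0.02, momentum 0.9, weight decay 5·10⁻⁴, batch 16, ×0.1 decay at epoch
100; random rotation and random erasing as augmentation). Retrieval ranks
the gallery by ascending Euclidean distance `‖A − B‖₂` (descending
similarity) and is scored with Rank-1 / Rank-5 (CMC) and mAP.

Everything — including convolution, batch normalisation and the backward
passes — is implemented on numpy via a compact reverse-mode autodiff
engine (`tigerreid.autograd`), so the whole stack trains on a single CPU.
Two size profiles share every structural contract: `full` (the 2048-d
branches above) and `desk` (widths ÷ 8, basic residual blocks), which
trains in about a minute. A procedural generator of striped pseudo-animals
(identity-specific stripe frequency/phase/angle over nuisance pose,
clutter and occlusion) makes the pipeline testable end to end without any
external dataset.

## Worked example

```python
from tigerreid import ReIDModel, TrainConfig, make_dataset

ds = make_dataset(8, 12, size=(64, 128), seed=7)     # 8 identities x 12 images
model = ReIDModel.from_dataset(ds, config=TrainConfig(seed=7), profile="desk")
res = model.fit(epochs=30, eval_every=10)
print(res.summary())
print(res.evaluate("val").summary())
```

prints

```
Serial multi-scale re-identification network
====================================================
profile: desk   classes: 8   descriptor dim: 512
branches: IFPM=on  LAEM=on  retrieval feature: concat
train images: 64   val images: 32
schedule: SGD lr 0.002/0.02 (x0.1 at epoch 100), momentum 0.9, weight decay 0.0005, batch 16
epochs run: 30   final loss: 0.2200
val Rank-1: 0.9375   val mAP: 0.9118

queries=32  mAP=0.9118  Rank-1=0.9375  Rank-5=0.9688
```

i.e. after 30 CPU epochs the learned descriptors retrieve the correct
individual first for 94% of the 32 validation queries (chance is 12.5%),
with a mean average precision of 0.91 over each query's three same-identity
gallery images.

The same workflow is available from the shell:

```bash
tigerreid synth --n-ids 8 --imgs-per-id 12 --seed 7 --out data/
tigerreid train --config cfg.yaml --manifest data/manifest.csv --epochs 30 --weights-out w.npz
tigerreid eval  --config cfg.yaml --weights w.npz --manifest data/manifest.csv --json-out eval.json
tigerreid rank  --config cfg.yaml --weights w.npz --query data/id000/img000.png \
                --gallery-manifest data/manifest.csv
```

Real data plugs in through the same manifest format (CSV with columns
`path,entity_id,split`) via `ReIDModel.from_manifest`.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
the synthetic benchmark's scope and the numerical design choices.
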
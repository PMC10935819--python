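"""Overfit the tiny adapter-ViT on ten synthetic pages (a few seconds on CPU).

Only adapters, prompt embeddings and the mask decoder train; the randomly
initialized backbone stays frozen, which the backbone hash proves.
Run:  python examples/train_tiny_model.py
"""

from chemseg import (
    ChemSegModel,
    EncoderConfig,
    SynthesisConfig,
    TrainConfig,
    mean_train_iou,
    synthesize_pages,
    train_adapters,
)

pages = list(synthesize_pages(SynthesisConfig(n_pages=10, seed=7)))
model = ChemSegModel(EncoderConfig.tiny(), seed=0)
hash_before = model.backbone_hash()

ckpt = train_adapters(
    pages, model,
    TrainConfig(learning_rate=0.05, batch_size=10, max_steps=200, seed=0),
)
print(f"loss: {ckpt.losses[0]:.4f} -> {min(ckpt.losses):.4f} over 200 steps")
print(f"mean training IoU: {mean_train_iou(model, pages):.3f}")
print(f"backbone untouched: {model.backbone_hash() == hash_before}")

# IoU is measured between thresholded footprint predictions and the
# footprint targets; >= 0.5 shows the adapter/decoder path can learn.
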
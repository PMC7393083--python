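"""Train a scaled-down residual U-Net on synthetic blob patches.

Uses the small 5-level spec (32 x 32 input) so the whole run finishes in
about a minute on one CPU core. The network minimizes the Dice loss
under SGD with momentum; the held-out DSC near 1 shows the architecture
and training loop learn dense segmentation from scratch.
"""

from noduleseg.nn import SMALL_SPEC, TrainConfig, build_network, evaluate_dsc, train
from noduleseg.synthetic import generate_blob_patches

patches, masks = generate_blob_patches(250, SMALL_SPEC.input_shape, seed=7)
train_p, train_m = patches[:200], masks[:200]
test_p, test_m = patches[200:], masks[200:]

model = build_network(SMALL_SPEC, seed=3)
cfg = TrainConfig(learning_rate=0.1, momentum=0.9, batch_size=8, max_epochs=25, seed=3)
history = train(model, train_p, train_m, cfg)

print(f"epochs: {len(history.loss)}")
print(f"dice loss: first {history.loss[0]:.4f} -> last {history.loss[-1]:.4f}")
print(f"train DSC: {history.train_dsc[-1]:.4f}")
print(f"held-out DSC (50 patches): {evaluate_dsc(model, test_p, test_m):.4f}")
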
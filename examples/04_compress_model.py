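"""Compress a trained model: structured pruning, then INT8 quantization.

Trains a small network briefly, prunes the deepest structurally free
convolution layers by L2-ranked channel importance, fine-tunes, fuses
conv-BN pairs and applies post-training static INT8 quantization with
min/max calibration on training tiles.  Prints the parameter count, conv
weight storage and segmentation quality at each stage.
"""

import numpy as np

from maarnet import MAARNet, NetworkConfig, SynthConfig, generate_sample
from maarnet.compression import (apply_prune, build_prune_plan,
                                 calibrate_and_quantize, conv_weight_bytes)
from maarnet.profiling import count_params
from maarnet.training import TrainConfig, evaluate, image_to_input, train

config = NetworkConfig(stage_widths=(8, 16, 24, 32), stage_blocks=(1, 1, 1, 1),
                       high_semantic_width=48, context_width=16,
                       decoder_widths=(16, 24, 24, 16), final_width=16)
model = MAARNet(config, seed=0)
tiles = SynthConfig(tile_size=96, n_vessels=(2, 5), vessel_width=(3, 8))
data = [generate_sample(tiles, seed=i) for i in range(8)]
train(model, data, TrainConfig(epochs=15, batch_size=4, seed=0))
print(f"float model: {count_params(model):,} params, "
      f"IoU {evaluate(model, data).iou:.3f}")

plan = build_prune_plan(model, keep_ratio=0.7, n_layers=4)
print(f"pruning {plan.layer_names()} (keep 70% of channels, deepest first)")
pruned = apply_prune(model, plan)
train(pruned, data, TrainConfig(epochs=5, batch_size=4, seed=1,
                                learning_rate=2e-4))  # short fine-tune
print(f"pruned model: {count_params(pruned):,} params, "
      f"IoU {evaluate(pruned, data).iou:.3f}")

calib = [image_to_input(s.image, np.float32)[None] for s in data[:4]]
quantized = calibrate_and_quantize(pruned, calib)
fb, qb = conv_weight_bytes(pruned), conv_weight_bytes(quantized)
print(f"quantized model: conv weights {fb:,} -> {qb:,} bytes "
      f"({fb / qb:.1f}x smaller; attention gates stay float), "
      f"IoU {evaluate(quantized, data).iou:.3f}")
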
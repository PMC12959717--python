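"""Generate a synthetic PAS-style dataset and inspect it.

Writes 10 image/mask pairs (512x512 RGB tiles with thin curvilinear and
ring-shaped vessels on a pink-purple textured background) split 6:2:2 into
train/val/test, then reads one pair back and prints its foreground
statistics.  The foreground fraction of a few percent mirrors how sparse
microvessels are in real stained kidney tissue.
"""

from pathlib import Path

from maarnet import SynthConfig, generate_dataset, read_sample

out = Path("scratch/example_dataset")
config = SynthConfig(tile_size=512, n_vessels=(4, 10), vessel_width=(2, 12))
manifest = generate_dataset(config, n_total=10, seed=7, out_dir=out)

counts = {s: sum(1 for r in manifest if r["split"] == s)
          for s in ("train", "val", "test")}
print(f"wrote {len(manifest)} pairs: "
      f"{counts['train']} train / {counts['val']} val / {counts['test']} test")

row = manifest[0]
pair = read_sample(out / row["image"], out / row["mask"])
print(f"tile {row['image']}: image {pair.image.shape} uint8, "
      f"mask {pair.mask.shape} with "
      f"{100 * pair.mask.mean():.2f}% vessel pixels")
print("same seed regenerates bit-identical tiles, so no data files need "
      "to be shipped with experiments")
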
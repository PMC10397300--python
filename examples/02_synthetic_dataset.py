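"""Generate a small labeled synthetic burn dataset and augment one image.

Writes PNGs plus a CSV manifest under ./scratch/example_dataset and prints
the per-class lesion color means — the separable cue the classifier learns.
"""

import numpy as np

from burnganext import SynthConfig, augment, generate_dataset, save_dataset
from burnganext.data import DEFAULT_PALETTES

cfg = SynthConfig(n_per_class=10, seed=7)
records, manifest = generate_dataset(cfg)
out = save_dataset(records, "scratch/example_dataset")
print(f"wrote {len(records)} images, manifest at {out}")

print("\nMean image color per class (R, G, B):")
for label in DEFAULT_PALETTES:
    px = np.stack([r.pixels for r in records if r.label == label])
    print(f"  {label:>14s}: {px.reshape(-1, 3).mean(axis=0).round(1)}")

aug = augment(records[0])
print(f"\naugment() on {records[0].id!r} -> {len(aug)} images:")
print("  " + ", ".join(a.id.split(':')[-1] if ':' in a.id else 'original' for a in aug))
# Superficial lesions are red/pink, deep dermal blotchy red-white, full
# thickness darker white/brown/red: the class means separate accordingly.
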
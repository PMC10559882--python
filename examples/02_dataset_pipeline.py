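"""From sequence to supervised data set.

Windows a 6,000-base synthetic genome into 60-base data points, splits
70/15/15 chronologically, normalizes on training statistics only, and
frames lookback samples.  The printed sizes follow the same rules that
reproduce the published partitions of the six study genomes
(e.g. 35,937 bases -> 598 points -> 420/89/89).
"""

import numpy as np

from btsforecast import SyntheticSpec, derive_six_series, generate_dna, make_supervised, split_series, window_series

seq = generate_dna(SyntheticSpec(length=6000, seed=0))
six = derive_six_series(seq)
print(f"{seq.n} bases -> {six['spectral_minmax']['points'].size} data points per channel")
print("channels:", ", ".join(six))

split = six["spectral_minmax"]["split"]
print(f"split sizes (train/val/test): {split.sizes}")

# the published partition check, recomputed
for label, length, expected in [("A", 35937, (420, 89, 89)), ("F", 49316, (575, 123, 123))]:
    pts = window_series(np.zeros(length), 60)
    print(f"genome {label}: {length} bases -> {pts.size} points -> {split_series(pts).sizes} "
          f"(published {expected})")

mat = np.stack([six[name]["norm_split"].train for name in six])
sup = make_supervised(mat, lookback=8)
print(f"supervised training set: {sup.n_samples} samples, "
      f"{sup.channels} channels, lookback {sup.lookback}")
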
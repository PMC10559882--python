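"""Encode one DNA sequence three ways and inspect the series.

Builds a short synthetic genome, applies the spectral, chaos-game and
Z-curve encoders, and prints the head of each series.  All three are
length-preserving: residue i maps to sample i.
"""

import numpy as np

from btsforecast import (
    SyntheticSpec, cgr_scalar, encode_cgr, encode_spectral, encode_z, generate_dna,
)

seq = generate_dna(SyntheticSpec(length=30, seed=4))
print(f"sequence ({seq.n} bases): {seq.bases}")

spectral = encode_spectral(seq)
print("\nspectral (a=1 g=2 c=3 t=4):")
print(" ", spectral.values[:10].astype(int))

cgr = encode_cgr(seq)
print("\nCGR points (first 5; every point strictly inside [-1,1]^2):")
for i in range(5):
    print(f"  {seq.bases[i]} -> ({cgr.values[0, i]: .4f}, {cgr.values[1, i]: .4f})")
print("scalar projection (Euclidean norm):", np.round(cgr_scalar(cgr).values[:5], 4))

z = encode_z(seq)
print("\nZ-curve scalar (signed root of X+Y+Z = 4*A_i - i):")
print(" ", np.round(z.values[:10], 4))
print("\nA larger A-share pushes the Z series up; purine- or GC-rich")
print("prefixes push it negative under the signed-root convention.")
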
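"""Encoders turning a DNA sequence into biological time sequences (BTS).

Three classical numeric representations are provided:

* spectral — direct base-to-integer map a→1, g→2, c→3, t→4;
* CGR — chaos game representation: iterated midpoint map toward the corner
  of the unit square assigned to each base, starting from the origin;
* Z-curve — prefix disparities between purine/pyrimidine (X), amino/keto (Y)
  and weak/strong (Z) base classes, combined into one scalar channel.

All encoders are length-preserving: residue i of the sequence yields sample
i of the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .sequence_io import DnaSequence

#: Default chaos-game corner assignment (square [-1,1]^2).
DEFAULT_CGR_VERTICES: Mapping[str, tuple[float, float]] = {
    "A": (1.0, 1.0),
    "C": (-1.0, -1.0),
    "G": (-1.0, 1.0),
    "T": (1.0, -1.0),
}

#: Alternative corner reading with C and T exchanged.
ALT_CGR_VERTICES: Mapping[str, tuple[float, float]] = {
    "A": (1.0, 1.0),
    "C": (1.0, -1.0),
    "G": (-1.0, 1.0),
    "T": (-1.0, -1.0),
}

_SPECTRAL = {"A": 1, "G": 2, "C": 3, "T": 4}
_SPECTRAL_INV = {v: k for k, v in _SPECTRAL.items()}


@dataclass(frozen=True)
class BioTimeSeries:
    """A numeric series derived from a biological sequence.

    ``values`` is 1-D for scalar encodings and (2, n) channel-major for CGR.
    ``normalization`` records any rescaling applied downstream ('none' here).
    """

    values: np.ndarray
    encoding: str
    source_id: str
    normalization: str = "none"

    @property
    def n(self) -> int:
        return self.values.shape[-1]

    @property
    def channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[0]


def _require_nonempty(seq: DnaSequence) -> None:
    if seq.n == 0:
        raise ValueError("cannot encode an empty sequence")


def encode_spectral(seq: DnaSequence) -> BioTimeSeries:
    """Map each base to its spectral integer: A→1, G→2, C→3, T→4."""
    _require_nonempty(seq)
    vals = np.fromiter((_SPECTRAL[b] for b in seq.bases), dtype=float, count=seq.n)
    return BioTimeSeries(values=vals, encoding="spectral", source_id=seq.id)


def decode_spectral(series: BioTimeSeries) -> DnaSequence:
    """Invert :func:`encode_spectral` (values must be exactly 1..4)."""
    bases = "".join(_SPECTRAL_INV[int(v)] for v in series.values)
    return DnaSequence(id=series.source_id, bases=bases)


def encode_cgr(
    seq: DnaSequence,
    vertex_map: Mapping[str, tuple[float, float]] = DEFAULT_CGR_VERTICES,
) -> BioTimeSeries:
    """Chaos game representation: CGR_0 = (0,0); CGR_i is the midpoint of
    CGR_{i-1} and the corner assigned to base i.

    Every point lies strictly inside the square; successive points contract
    the distance to the current corner by exactly one half.
    """
    _require_nonempty(seq)
    corners = {b: np.asarray(v, dtype=float) for b, v in vertex_map.items()}
    if set(corners) != set("ACGT"):
        raise ValueError("vertex map must cover exactly A, C, G, T")
    if len({tuple(v) for v in corners.values()}) != 4:
        raise ValueError("vertex map corners must be distinct")
    allowed = {(1.0, 1.0), (1.0, -1.0), (-1.0, 1.0), (-1.0, -1.0)}
    if {tuple(v) for v in corners.values()} != allowed:
        raise ValueError("corners must be the four vertices of [-1,1]^2")

    pts = np.empty((2, seq.n))
    cur = np.zeros(2)
    for i, b in enumerate(seq.bases):
        cur = cur - (cur - corners[b]) / 2.0
        pts[:, i] = cur
    return BioTimeSeries(values=pts, encoding="cgr", source_id=seq.id)


def cgr_scalar(series2d: BioTimeSeries, mode: Literal["norm", "x", "y"] = "norm") -> BioTimeSeries:
    """Project a 2-channel CGR series to one channel.

    'norm' takes the Euclidean length of each point (default — symmetric in
    both coordinates); 'x'/'y' take that coordinate.
    """
    if series2d.channels != 2:
        raise ValueError("cgr_scalar expects a 2-channel series")
    xy = series2d.values
    if mode == "norm":
        vals = np.hypot(xy[0], xy[1])
    elif mode == "x":
        vals = xy[0].copy()
    elif mode == "y":
        vals = xy[1].copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BioTimeSeries(values=vals, encoding=f"cgr_{mode}", source_id=series2d.source_id)


def z_components(seq: DnaSequence) -> dict[str, np.ndarray]:
    """Cumulative base counts and Z-curve disparity components per prefix.

    X_i = (A_i+G_i)-(C_i+T_i) separates purines from pyrimidines,
    Y_i = (A_i+C_i)-(G_i+T_i) amino from keto bases, and
    Z_i = (A_i+T_i)-(C_i+G_i) weak from strong (hydrogen-bond) pairs.
    """
    _require_nonempty(seq)
    arr = np.frombuffer(seq.bases.encode(), dtype=np.uint8)
    counts = {b: np.cumsum(arr == ord(b)).astype(np.int64) for b in "ACGT"}
    A, C, G, T = counts["A"], counts["C"], counts["G"], counts["T"]
    return {
        "A": A, "C": C, "G": G, "T": T,
        "X": (A + G) - (C + T),
        "Y": (A + C) - (G + T),
        "Z": (A + T) - (C + G),
    }


def encode_z(
    seq: DnaSequence,
    negative_policy: Literal["signed_root", "clamp"] = "signed_root",
) -> BioTimeSeries:
    """Z-curve scalar series: the square root of X_i + Y_i + Z_i per prefix.

    The radicand equals 4*A_i - i and is negative whenever the prefix is less
    than 25% A, so a real-valued policy is needed: 'signed_root' (default)
    maps v to sign(v)*sqrt(|v|), preserving the direction of the disparity;
    'clamp' truncates negative radicands to 0.
    """
    comp = z_components(seq)
    v = (comp["X"] + comp["Y"] + comp["Z"]).astype(float)
    if negative_policy == "signed_root":
        vals = np.sign(v) * np.sqrt(np.abs(v))
    elif negative_policy == "clamp":
        vals = np.sqrt(np.clip(v, 0.0, None))
    else:
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    return BioTimeSeries(values=vals, encoding="z", source_id=seq.id)
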
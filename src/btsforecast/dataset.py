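"""Windowing, chronological splitting, normalization and supervised framing.

A raw encoded series (one value per base) is condensed into "data points" by
averaging consecutive non-overlapping windows of ``window_len`` bases
(default 60; with that window every published genome length maps onto its
published data-point total as floor(length / 60)).  Points are then split
chronologically 70/15/15 with validation and test sizes floor(0.15*n) and
the remainder assigned to training, normalized with statistics fitted on the
training segment only, and framed into lookback samples for the forecasters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .encoders import BioTimeSeries, cgr_scalar, encode_cgr, encode_spectral, encode_z
from .sequence_io import DnaSequence

TRAIN_FRAC, VAL_FRAC, TEST_FRAC = 0.70, 0.15, 0.15


@dataclass(frozen=True)
class DataSplit:
    """Contiguous chronological train/validation/test partition."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))

    @property
    def total(self) -> int:
        return sum(self.sizes)

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.train, self.validation, self.test])


@dataclass(frozen=True)
class NormalizationParams:
    """Statistics recorded when a normalization was fitted.

    minmax stores (min, max) of the fitted segment; variance stores
    (mean, sample sd).  ``inverse`` undoes ``forward`` exactly.
    """

    mode: Literal["minmax", "variance"]
    stat_a: float  # min or mean
    stat_b: float  # max or sd

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.mode == "minmax":
            return (x - self.stat_a) / (self.stat_b - self.stat_a)
        return (x - self.stat_a) / self.stat_b

    def inverse(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.mode == "minmax":
            return x * (self.stat_b - self.stat_a) + self.stat_a
        return x * self.stat_b + self.stat_a


@dataclass(frozen=True)
class SupervisedSet:
    """Lookback blocks and one-step-ahead targets.

    inputs has shape (samples, channels, T); targets has shape (samples,).
    Sample j covers positions j..j+T-1 and predicts position j+T of the
    target channel.
    """

    inputs: np.ndarray
    targets: np.ndarray
    lookback: int
    target_channel: int = 0

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    @property
    def channels(self) -> int:
        return self.inputs.shape[1]


def window_series(
    series: BioTimeSeries | np.ndarray,
    window_len: int = 60,
    aggregate: Literal["mean", "first"] = "mean",
) -> np.ndarray:
    """Condense a per-base series into data points.

    Consecutive non-overlapping windows of ``window_len`` values each yield
    one point via the aggregate function; a trailing incomplete window is
    discarded, so the point count is floor(n / window_len).
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    vals = series.values if isinstance(series, BioTimeSeries) else np.asarray(series, dtype=float)
    if vals.ndim != 1:
        raise ValueError("window_series expects a single-channel series")
    k = vals.size // window_len
    if k == 0:
        warnings.warn("series shorter than one window: zero data points", stacklevel=2)
        return np.empty(0)
    blocks = vals[: k * window_len].reshape(k, window_len)
    return blocks.mean(axis=1) if aggregate == "mean" else blocks[:, 0].copy()


def split_series(points: np.ndarray) -> DataSplit:
    """Chronological 70/15/15 split: n_val = n_test = floor(0.15*n)."""
    pts = np.asarray(points, dtype=float)
    n = pts.size
    if n < 3:
        raise ValueError("need at least 3 points to split")
    n_val = n_test = int(np.floor(VAL_FRAC * n))
    n_train = n - n_val - n_test
    return DataSplit(
        train=pts[:n_train].copy(),
        validation=pts[n_train : n_train + n_val].copy(),
        test=pts[n_train + n_val :].copy(),
    )


def fit_normalization(train: np.ndarray, mode: Literal["minmax", "variance"]) -> NormalizationParams:
    """Fit normalization statistics on the training segment only."""
    x = np.asarray(train, dtype=float)
    if x.size == 0:
        raise ValueError("cannot fit normalization on an empty segment")
    if mode == "minmax":
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            raise ValueError("degenerate series: max equals min")
        return NormalizationParams("minmax", lo, hi)
    if mode == "variance":
        mu = float(x.mean())
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        if sd == 0.0:
            raise ValueError("degenerate series: zero standard deviation")
        return NormalizationParams("variance", mu, sd)
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize(
    series: np.ndarray, mode: Literal["minmax", "variance"]
) -> tuple[np.ndarray, NormalizationParams]:
    params = fit_normalization(series, mode)
    return params.forward(series), params


def inverse_normalize(series: np.ndarray, params: NormalizationParams) -> np.ndarray:
    return params.inverse(series)


def derive_six_series(
    seq: DnaSequence,
    window_len: int = 60,
    aggregate: Literal["mean", "first"] = "mean",
    cgr_mode: Literal["norm", "x", "y"] = "norm",
) -> dict[str, dict]:
    """Derive the six standard channels from one sequence.

    {spectral, CGR-scalar, Z} x {minmax, variance}, all windowed identically
    and normalized with train-segment statistics.  Each entry carries the
    windowed points, the split, the normalized split and the fitted params.
    """
    encoded = {
        "spectral": encode_spectral(seq),
        "cgr": cgr_scalar(encode_cgr(seq), mode=cgr_mode),
        "z": encode_z(seq),
    }
    out: dict[str, dict] = {}
    for enc_name, bts in encoded.items():
        points = window_series(bts, window_len=window_len, aggregate=aggregate)
        split = split_series(points)
        for mode in ("minmax", "variance"):
            params = fit_normalization(split.train, mode)
            out[f"{enc_name}_{mode}"] = {
                "points": points,
                "split": split,
                "norm_split": DataSplit(
                    train=params.forward(split.train),
                    validation=params.forward(split.validation),
                    test=params.forward(split.test),
                ),
                "params": params,
            }
    return out


def make_supervised(
    channels: Sequence[np.ndarray] | np.ndarray,
    lookback: int,
    target_channel: int = 0,
) -> SupervisedSet:
    """Frame aligned channels into lookback blocks with one-step targets."""
    mat = np.atleast_2d(np.asarray(channels, dtype=float))
    n_ch, L = mat.shape
    if lookback < 1:
        raise ValueError("lookback must be >= 1")
    if L <= lookback:
        raise ValueError(f"series length {L} must exceed lookback {lookback}")
    if not 0 <= target_channel < n_ch:
        raise ValueError("target_channel out of range")
    n = L - lookback
    inputs = np.empty((n, n_ch, lookback))
    for j in range(n):
        inputs[j] = mat[:, j : j + lookback]
    targets = mat[target_channel, lookback:].copy()
    return SupervisedSet(inputs=inputs, targets=targets, lookback=lookback, target_channel=target_channel)


def rolling_summary(points: np.ndarray, window: int = 30) -> dict[str, np.ndarray]:
    """Rolling mean/sd summary used in place of visual stationarity checks."""
    import pandas as pd

    s = pd.Series(np.asarray(points, dtype=float))
    return {
        "rolling_mean": s.rolling(window).mean().to_numpy(),
        "rolling_sd": s.rolling(window).std(ddof=1).to_numpy(),
    }
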
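"""Train/validation/test partitioning and band standardization.

The classifier consumes tabular per-pixel spectra (columns band_R..band_NIR
plus label/date/treatment metadata). Tables are split 60/20/20 by simple
random shuffling, and each band is standardized by the mean and standard
deviation of the *training* partition only — the same scaler is reused for
validation, test, and every acquisition date at inference time, so the model
always sees inputs on one consistent scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scene import BAND_COLUMNS


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class ScalerParams:
    """Per-band standardization parameters fit on the training partition."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != sd.shape:
            raise ValueError("mean and sd shapes differ")
        if np.any(sd <= 0):
            raise ValueError("scaler sd must be strictly positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(), "sd": self.sd.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ScalerParams":
        d = json.loads(text)
        return cls(mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]))


def shuffle_split(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Randomly partition rows into (train, validation, test).

    Partition sizes are ``round(f * n)`` for validation and test with any
    rounding remainder assigned to the training partition, so the three
    partitions are disjoint and their union is the input. Deterministic
    given ``spec.seed``.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cannot split an empty sample table")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    _, f_val, f_test = spec.fractions
    n_val = round(f_val * n)
    n_test = round(f_test * n)
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("training partition would be empty")
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    return (
        table.iloc[idx_train].reset_index(drop=True),
        table.iloc[idx_val].reset_index(drop=True),
        table.iloc[idx_test].reset_index(drop=True),
    )


def fit_scaler(train: pd.DataFrame) -> ScalerParams:
    """Per-band sample mean and standard deviation (n-1 denominator) of the
    training partition. A constant band is rejected by name: it carries no
    information and would divide by zero."""
    if len(train) < 2:
        raise ValueError("need at least 2 training rows to fit a scaler")
    x = train[list(BAND_COLUMNS)].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        names = ", ".join(BAND_COLUMNS[i] for i in flat)
        raise ValueError(f"constant band(s) cannot be standardized: {names}")
    return ScalerParams(mean=mean, sd=sd)


def apply_scaler(table: pd.DataFrame, scaler: ScalerParams) -> pd.DataFrame:
    """Standardize each band as (x - mean) / sd; labels and metadata pass
    through untouched."""
    out = table.copy()
    x = out[list(BAND_COLUMNS)].to_numpy(dtype=float)
    out[list(BAND_COLUMNS)] = (x - scaler.mean) / scaler.sd
    return out


def invert_scaler(table: pd.DataFrame, scaler: ScalerParams) -> pd.DataFrame:
    """Undo :func:`apply_scaler` (x * sd + mean)."""
    out = table.copy()
    x = out[list(BAND_COLUMNS)].to_numpy(dtype=float)
    out[list(BAND_COLUMNS)] = x * scaler.sd + scaler.mean
    return out
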
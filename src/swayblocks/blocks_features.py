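"""Overlapping block extraction and the three-index sway descriptor.

Each statokinesigram is cut into fixed-length blocks with a configurable
overlap (50% by default).  Every block is summarised by the classical
posturographic 3-vector ``Z = (s95, v_mean, sigma_x)``:

* ``s95`` — surface of the 95% confidence (prediction) ellipse of the CoP
  point cloud, ``pi * chi2_{0.95,2} * sqrt(det(S))`` with ``S`` the 2x2 sample
  covariance of (x, y), in cm^2;
* ``v_mean`` — mean magnitude of the CoP velocity from first differences,
  in cm/s;
* ``sigma_x`` — sample standard deviation of the medio-lateral displacement,
  in cm.

Descriptors are z-normalized per index with statistics fitted on the pooled
training blocks of one condition, so the three indices enter the mixture
model on a common scale.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence

import numpy as np
from scipy import stats

from .cop_data import Condition, Statokinesigram
from .exceptions import (
    DegenerateNormalizerError,
    InsufficientDataError,
    ValidationError,
)

#: 95% quantile of the chi-square distribution with 2 degrees of freedom.
CHI2_95_2DF = float(stats.chi2.ppf(0.95, df=2))

DEFAULT_OVERLAP = 0.5


@dataclasses.dataclass
class Block:
    """A contiguous slice of a statokinesigram."""

    condition: Condition
    start_index: int
    x: np.ndarray
    y: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValidationError("block x and y must have equal length")
        if len(self.x) < 2:
            raise InsufficientDataError("a block needs at least 2 samples")

    def __len__(self) -> int:
        return len(self.x)


@dataclasses.dataclass
class BlockDescriptor:
    """The 3-index description of one block, raw or normalized."""

    s95: float
    v_mean: float
    sigma_x: float
    normalized: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.s95, self.v_mean, self.sigma_x], dtype=float)


@dataclasses.dataclass
class NormStats:
    """Per-index mean and standard deviation used for z-normalization."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.sd = np.asarray(self.sd, dtype=float).reshape(3)
        if not np.all(self.sd > 0):
            raise DegenerateNormalizerError("normalizer sd must be strictly positive")


def block_samples(block_length_s: float, rate: float) -> int:
    """Block length in samples: floor(block_length_s * rate)."""
    return int(np.floor(block_length_s * rate + 1e-9))


def block_stride(length_samples: int, overlap: float) -> int:
    """Stride between block starts; round half away from zero, at least 1."""
    return max(1, int(np.floor(length_samples * (1.0 - overlap) + 0.5)))


def split_blocks(
    traj: Statokinesigram,
    block_length_s: float,
    overlap: float = DEFAULT_OVERLAP,
) -> List[Block]:
    """Cut a statokinesigram into fixed-length overlapping blocks.

    Blocks start at indices ``0, s, 2s, ...`` with stride
    ``s = max(1, round(L * (1 - overlap)))`` (L in samples); a trailing
    partial block is discarded, so the count is ``floor((N - L)/s) + 1``.
    """
    if not 0 <= overlap < 1:
        raise ValidationError("overlap must be in [0, 1)")
    length = block_samples(block_length_s, traj.rate)
    if length < 2:
        raise ValidationError("block length must cover at least 2 samples")
    n = len(traj)
    if length > n:
        raise InsufficientDataError(
            f"block of {length} samples does not fit in trajectory of {n}"
        )
    stride = block_stride(length, overlap)
    blocks = []
    for start in range(0, n - length + 1, stride):
        blocks.append(
            Block(
                condition=traj.condition,
                start_index=start,
                x=traj.x[start : start + length],
                y=traj.y[start : start + length],
                rate=traj.rate,
            )
        )
    return blocks


def whole_signal_block(traj: Statokinesigram) -> Block:
    """The entire statokinesigram as a single block (no-split baseline)."""
    return Block(
        condition=traj.condition, start_index=0, x=traj.x, y=traj.y, rate=traj.rate
    )


# ---------------------------------------------------------------------------
# The three indices
# ---------------------------------------------------------------------------

def ellipse_area_95(block: Block) -> float:
    """Surface of the 95% confidence ellipse of the block's point cloud (cm^2).

    A numerically degenerate covariance (det <= 0) yields area 0.
    """
    if len(block) < 3:
        raise InsufficientDataError("ellipse area needs at least 3 samples")
    cov = np.cov(block.x, block.y, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0:
        return 0.0
    return float(np.pi * CHI2_95_2DF * np.sqrt(det))


def mean_velocity(block: Block) -> float:
    """Mean magnitude of the first-difference CoP velocity (cm/s)."""
    steps = np.hypot(np.diff(block.x), np.diff(block.y))
    return float(np.mean(steps) * block.rate)


def ml_std(block: Block) -> float:
    """Sample standard deviation (n-1 denominator) of the ML displacement (cm)."""
    return float(np.std(block.x, ddof=1))


def _descriptor_matrix(X: np.ndarray, Y: np.ndarray, rate: float) -> np.ndarray:
    """Vectorized raw descriptors for stacked same-length blocks.

    X, Y have shape (n_blocks, L); returns (n_blocks, 3) columns
    (s95, v_mean, sigma_x).
    """
    L = X.shape[1]
    xc = X - X.mean(axis=1, keepdims=True)
    yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc) / (L - 1)
    syy = np.einsum("ij,ij->i", yc, yc) / (L - 1)
    sxy = np.einsum("ij,ij->i", xc, yc) / (L - 1)
    det = sxx * syy - sxy * sxy
    s95 = np.pi * CHI2_95_2DF * np.sqrt(np.clip(det, 0.0, None))
    steps = np.hypot(np.diff(X, axis=1), np.diff(Y, axis=1))
    v_mean = steps.mean(axis=1) * rate
    sigma_x = np.sqrt(sxx)
    return np.column_stack([s95, v_mean, sigma_x])


def describe_blocks(blocks: Sequence[Block]) -> List[BlockDescriptor]:
    """Raw 3-index descriptor for every block, order preserved."""
    if len(blocks) == 0:
        return []
    lengths = {len(b) for b in blocks}
    if len(lengths) == 1 and lengths.pop() >= 3:
        X = np.stack([b.x for b in blocks])
        Y = np.stack([b.y for b in blocks])
        Z = _descriptor_matrix(X, Y, blocks[0].rate)
        return [BlockDescriptor(*row, normalized=False) for row in Z]
    return [
        BlockDescriptor(
            s95=ellipse_area_95(b),
            v_mean=mean_velocity(b),
            sigma_x=ml_std(b),
            normalized=False,
        )
        for b in blocks
    ]


def descriptors_to_array(descriptors: Sequence[BlockDescriptor]) -> np.ndarray:
    """(n, 3) array of descriptor values in the canonical index order."""
    if len(descriptors) == 0:
        return np.empty((0, 3))
    return np.stack([d.as_array() for d in descriptors])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def fit_normalizer(train_descriptors: Sequence[BlockDescriptor]) -> NormStats:
    """Per-index mean/sd over the pooled training blocks (n-1 denominator)."""
    if len(train_descriptors) < 2:
        raise InsufficientDataError("normalizer needs at least 2 descriptors")
    return fit_normalizer_array(descriptors_to_array(train_descriptors))


def fit_normalizer_array(Z: np.ndarray) -> NormStats:
    """Array-based variant of :func:`fit_normalizer`."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 2:
        raise InsufficientDataError("normalizer needs at least 2 descriptors")
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [name for name, s in zip(("s95", "v_mean", "sigma_x"), sd) if s <= 0]
        raise DegenerateNormalizerError(f"zero variance in indices {bad}")
    return NormStats(mean=Z.mean(axis=0), sd=sd)


def apply_normalizer(
    stats: NormStats, descriptors: Sequence[BlockDescriptor]
) -> List[BlockDescriptor]:
    """Z-score each descriptor with the given statistics."""
    Z = normalize_array(stats, descriptors_to_array(descriptors))
    return [BlockDescriptor(*row, normalized=True) for row in Z]


def normalize_array(stats: NormStats, Z: np.ndarray) -> np.ndarray:
    return (np.asarray(Z, dtype=float) - stats.mean) / stats.sd


def denormalize_array(stats: NormStats, Z: np.ndarray) -> np.ndarray:
    return np.asarray(Z, dtype=float) * stats.sd + stats.mean
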
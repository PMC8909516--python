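"""From masked index stacks to fixed-length per-pixel feature sequences.

Cloud gaps are closed by per-index linear interpolation along the shared
date grid, with nearest-valid extrapolation at the sequence ends; a pixel
that has no valid observation at all for some index cannot be reconstructed
and is dropped (and counted, so the loss of cloud-covered pixels stays
observable). A stratified, seeded train/test split and train-fitted
standardization prepare the sequences for the classifier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .spectral_indices import INDICES, IndexStack
from .synthetic_scene import LabelRaster


class EmptyDatasetError(ValueError):
    """All candidate pixels were dropped; no sequences remain."""


@dataclass
class IndexSeriesSet:
    """Per-sample feature sequences on a shared date grid.

    ``sequences`` has shape (n_samples, n_dates, 8); ``coords`` holds the
    (row, col) origin of each sample; ``gap_fraction`` the share of cells
    that were gap-filled rather than observed.
    """

    sequences: np.ndarray
    coords: np.ndarray
    labels: np.ndarray
    gap_fraction: np.ndarray
    dates: np.ndarray
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, idx: np.ndarray) -> "IndexSeriesSet":
        return dataclasses.replace(
            self,
            sequences=self.sequences[idx],
            coords=self.coords[idx],
            labels=self.labels[idx],
            gap_fraction=self.gap_fraction[idx],
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition: 80% training by default, stratified by class."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def build_series(indices: IndexStack, labels: LabelRaster,
                 pixel_mask: np.ndarray | None = None) -> IndexSeriesSet:
    """Extract one feature sequence per mask-valid pixel, gap-filling clouds.

    Invalid cells are filled per index by linear interpolation in time
    against the date grid; leading/trailing gaps take the nearest valid
    value. Pixels with zero valid observations for any index are dropped
    and counted in ``n_dropped``. Originally valid cells are never altered.
    """
    n_rows, n_cols = indices.shape
    if labels.labels.shape != (n_rows, n_cols):
        raise ValueError("label grid does not match index grid")
    if pixel_mask is None:
        pixel_mask = np.ones((n_rows, n_cols), dtype=bool)
    elif pixel_mask.shape != (n_rows, n_cols):
        raise ValueError("pixel mask does not match index grid")

    rows, cols = np.nonzero(pixel_mask)
    if len(rows) == 0:
        raise EmptyDatasetError("pixel mask excludes every pixel")

    dates = np.asarray(indices.dates, dtype=float)
    # (n_candidates, n_dates, n_indices)
    seq = np.transpose(indices.values[:, :, rows, cols], (2, 0, 1))
    ok = np.transpose(indices.valid[:, :, rows, cols], (2, 0, 1))

    keep = ok.any(axis=1).all(axis=1)  # every index observed at least once
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise EmptyDatasetError("every candidate pixel lacks valid observations")
    seq, ok = seq[keep], ok[keep]
    rows, cols = rows[keep], cols[keep]

    filled = seq.copy()
    gaps = ~ok
    for i in np.nonzero(gaps.any(axis=(1, 2)))[0]:
        for j in range(len(INDICES)):
            good = ok[i, :, j]
            if good.all():
                continue
            # np.interp clamps outside the valid range -> nearest-valid ends.
            filled[i, ~good, j] = np.interp(
                dates[~good], dates[good], seq[i, good, j]
            )

    return IndexSeriesSet(
        sequences=filled,
        coords=np.column_stack([rows, cols]),
        labels=labels.labels[rows, cols].astype(np.int64),
        gap_fraction=gaps.mean(axis=(1, 2)),
        dates=dates.copy(),
        n_dropped=n_dropped,
    )


def split_dataset(series: IndexSeriesSet,
                  spec: SplitSpec) -> tuple[IndexSeriesSet, IndexSeriesSet]:
    """Disjoint, exhaustive, seeded (optionally stratified) train/test split."""
    spec.validate()
    if spec.stratified:
        _, counts = np.unique(series.labels, return_counts=True)
        if counts.min() < 2:
            raise ValueError("stratified split needs >= 2 samples in every class")
    idx_train, idx_test = train_test_split(
        np.arange(len(series)),
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=series.labels if spec.stratified else None,
    )
    return series.subset(np.sort(idx_train)), series.subset(np.sort(idx_test))


@dataclass(frozen=True)
class Standardizer:
    """Per-index offsets/scales fitted on training sequences only."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, series: IndexSeriesSet) -> IndexSeriesSet:
        scaled = (series.sequences - self.mean) / self.scale
        return dataclasses.replace(series, sequences=scaled)


def standardize(train: IndexSeriesSet,
                test: IndexSeriesSet) -> tuple[IndexSeriesSet, IndexSeriesSet, Standardizer]:
    """Scale each index channel to train-set mean 0 / sd 1 (sd 0 -> scale 1).

    Fitting on the training set only avoids test-set leakage; test-set
    channel statistics need not come out as 0/1.
    """
    if len(train) == 0:
        raise EmptyDatasetError("cannot standardize an empty training set")
    mean = train.sequences.mean(axis=(0, 1))
    sd = train.sequences.std(axis=(0, 1))
    scale = np.where(sd > 0, sd, 1.0)
    scaler = Standardizer(mean=mean, scale=scale)
    return scaler.transform(train), scaler.transform(test), scaler
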
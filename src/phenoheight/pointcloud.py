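"""Point-cloud container with LAS-style classification codes.

Clouds are persisted as gzipped whitespace-delimited text
(``x y z class [truth_class]``), an interchange form any LiDAR toolkit can
ingest. Classification codes follow the ASPRS LAS convention.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

# ASPRS LAS classification codes
UNCLASSIFIED = 1
GROUND = 2
NON_GROUND = 5  # LAS "high vegetation"
NOISE = 7


@dataclass
class PointCloud:
    """3-D returns with per-point class labels.

    ``classification`` is the working label set by the processing chain;
    ``truth_class`` (optional) carries the simulator's ground-truth labels
    and is used only for evaluation.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    classification: np.ndarray | None = None
    truth_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ValueError("x, y, z must have identical shapes")
        if not (
            np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
            and np.all(np.isfinite(self.z))
        ):
            raise ValueError("point coordinates must be finite")
        if self.classification is None:
            self.classification = np.full(self.x.shape, UNCLASSIFIED, dtype=np.int8)
        else:
            self.classification = np.asarray(self.classification, dtype=np.int8)
        if self.truth_class is not None:
            self.truth_class = np.asarray(self.truth_class, dtype=np.int8)

    def __len__(self) -> int:
        return self.x.size

    def subset(self, keep: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.x[keep],
            self.y[keep],
            self.z[keep],
            self.classification[keep],
            None if self.truth_class is None else self.truth_class[keep],
        )

    def bounds(self) -> tuple[float, float, float, float]:
        if len(self) == 0:
            raise ValueError("empty cloud has no extent")
        return (self.x.min(), self.y.min(), self.x.max(), self.y.max())


def write_xyz(cloud: PointCloud, path: str) -> None:
    """Write a cloud as gzipped ``x y z class [truth]`` text."""
    cols = [cloud.x, cloud.y, cloud.z, cloud.classification]
    fmt = ["%.4f", "%.4f", "%.4f", "%d"]
    if cloud.truth_class is not None:
        cols.append(cloud.truth_class)
        fmt.append("%d")
    data = np.column_stack(cols)
    with gzip.open(path, "wt") as fh:
        np.savetxt(fh, data, fmt=" ".join(fmt))


def read_xyz(path: str) -> PointCloud:
    with gzip.open(path, "rt") as fh:
        data = np.loadtxt(fh, ndmin=2)
    truth = data[:, 4].astype(np.int8) if data.shape[1] >= 5 else None
    return PointCloud(
        data[:, 0], data[:, 1], data[:, 2], data[:, 3].astype(np.int8), truth
    )
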
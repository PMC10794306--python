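"""Topological features of embedded EEG point clouds.

Each 2-s multichannel epoch is read as a point cloud in channel space: the
sample at time t is a point in R^(n_channels). The Vietoris-Rips filtration
of that cloud is summarised by its dimension-0/1 persistence diagram, from
which six scalar features are computed per epoch:

* ``total_cycles``   - number of dimension-1 intervals,
* ``max_cycles``     - peak of the Betti-1 curve (most simultaneously
  alive cycles),
* ``max_persistence``- longest cycle lifetime (death - birth),
* ``npe``            - normalised persistence entropy of the lifetime
  distribution, in [0, 1],
* ``max_persistence_ratio`` / ``median_persistence_ratio`` - dimensionless
  death/birth ratios per cycle, summarised by max and median.

Cycle-rich, coherent signals (large loops traced in channel space) give
many long-lived cycles with large ratios; incoherent noise gives many
short-lived ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._ripser import rips_dims01

__all__ = [
    "EmbeddedPointCloud",
    "PersistenceDiagram",
    "TDAFeatureVector",
    "FEATURE_NAMES",
    "build_point_cloud",
    "rips_diagram",
    "betti1_curve",
    "persistence_ratio",
    "compute_features",
    "epoch_features",
    "feature_table",
]

FEATURE_NAMES = (
    "total_cycles",
    "max_cycles",
    "max_persistence",
    "npe",
    "max_persistence_ratio",
    "median_persistence_ratio",
)


@dataclass
class EmbeddedPointCloud:
    """Samples of a multichannel window as points in channel space."""

    points: np.ndarray  # (n_points, n_channels)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite values")


@dataclass
class PersistenceDiagram:
    """Birth-death intervals of a filtration, keyed by homology dimension."""

    intervals: dict  # dim -> (m, 2) array of (birth, death)

    def pairs(self, dim: int) -> np.ndarray:
        return self.intervals.get(dim, np.empty((0, 2)))

    def lifetimes(self, dim: int = 1) -> np.ndarray:
        p = self.pairs(dim)
        return p[:, 1] - p[:, 0] if p.size else np.empty(0)


@dataclass(frozen=True)
class TDAFeatureVector:
    total_cycles: int
    max_cycles: int
    max_persistence: float
    npe: float
    max_persistence_ratio: float
    median_persistence_ratio: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def build_point_cloud(epoch: np.ndarray, zscore: bool = False,
                      meta: dict | None = None) -> EmbeddedPointCloud:
    """Embed a (n_channels, n_samples) epoch as n_samples points in R^n_channels.

    No delay embedding and, by default, no amplitude normalisation; with
    ``zscore=True`` each channel is standardised first (sensitivity
    analyses only).
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be (n_channels, n_samples)")
    pts = epoch.T.copy()
    if zscore:
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd
    return EmbeddedPointCloud(pts, meta=dict(meta or {}))


def rips_diagram(epc: EmbeddedPointCloud | np.ndarray,
                 max_dimension: int = 1,
                 threshold: float | None = None) -> PersistenceDiagram:
    """Vietoris-Rips persistence (Euclidean metric, Z/2 coefficients).

    The filtration is capped at the enclosing radius, which provably
    leaves the dimension-0/1 diagrams unchanged; an explicit smaller
    ``threshold`` is honoured.
    """
    if max_dimension not in (0, 1):
        raise ValueError("only homology dimensions 0 and 1 are supported")
    pts = epc.points if isinstance(epc, EmbeddedPointCloud) else np.asarray(epc, float)
    if len(pts) == 0:
        raise ValueError("empty point cloud")
    D = squareform(pdist(pts)) if len(pts) > 1 else np.zeros((1, 1))
    h0, h1 = rips_dims01(D, threshold=threshold)
    intervals = {0: h0}
    if max_dimension >= 1:
        intervals[1] = h1
    return PersistenceDiagram(intervals)


def betti1_curve(diagram: PersistenceDiagram):
    """Step function t -> number of 1-cycles alive at filtration value t.

    Returns ``(grid, counts)`` where grid holds the sorted interval
    endpoints and ``counts[i]`` is the Betti-1 number on
    ``[grid[i], grid[i+1])``. The peak of the curve is the ``max_cycles``
    feature.
    """
    pairs = diagram.pairs(1)
    if pairs.size == 0:
        return np.array([0.0]), np.array([0])
    events = np.concatenate([
        np.column_stack([pairs[:, 0], np.ones(len(pairs), dtype=int)]),
        np.column_stack([pairs[:, 1], -np.ones(len(pairs), dtype=int)]),
    ])
    events = events[np.lexsort((events[:, 1], events[:, 0]))]
    grid, counts = [], []
    alive = 0
    for t, delta in events:
        alive += int(delta)
        if grid and grid[-1] == t:
            counts[-1] = alive
        else:
            grid.append(t)
            counts.append(alive)
    return np.array(grid), np.array(counts, dtype=int)


def persistence_ratio(pairs: np.ndarray) -> np.ndarray:
    """Per-cycle death/birth ratio (dimensionless, scale-invariant).

    Isolated so that alternative ratio conventions (lifetime/birth, ...)
    can be swapped in one place.
    """
    return pairs[:, 1] / pairs[:, 0]


def compute_features(diagram: PersistenceDiagram) -> TDAFeatureVector:
    """The six per-epoch topological features from the dim-1 diagram.

    With lifetimes l_i = death_i - birth_i and L = sum l_i:
    npe = -sum (l_i/L) log(l_i/L) / log(#cycles), defined as 0 when
    #cycles <= 1. With no cycles, all six features are 0.
    """
    pairs = diagram.pairs(1)
    pairs = pairs[np.isfinite(pairs[:, 1])] if pairs.size else pairs
    total = len(pairs)
    if total == 0:
        return TDAFeatureVector(0, 0, 0.0, 0.0, 0.0, 0.0)
    lifetimes = pairs[:, 1] - pairs[:, 0]
    _, counts = betti1_curve(PersistenceDiagram({1: pairs}))
    max_cycles = int(counts.max())
    if total > 1:
        p = lifetimes / lifetimes.sum()
        npe = float(-(p * np.log(p)).sum() / np.log(total))
    else:
        npe = 0.0
    ratios = persistence_ratio(pairs)
    return TDAFeatureVector(
        total_cycles=total,
        max_cycles=max_cycles,
        max_persistence=float(lifetimes.max()),
        npe=npe,
        max_persistence_ratio=float(ratios.max()),
        median_persistence_ratio=float(np.median(ratios)),
    )


def epoch_features(epoch: np.ndarray, zscore: bool = False) -> TDAFeatureVector:
    """Convenience: epoch matrix -> point cloud -> diagram -> features."""
    return compute_features(rips_diagram(build_point_cloud(epoch, zscore=zscore)))


def feature_table(epoch_sets, zscore: bool = False,
                  progress: bool = False) -> pd.DataFrame:
    """Study-wide feature table from an iterable of EpochSets.

    Columns: subject_id, group, moca, condition, session + the six
    features; one row per epoch.
    """
    rows = []
    for es in epoch_sets:
        for ep in es.epochs:
            feats = epoch_features(ep.data, zscore=zscore)
            rows.append({
                "subject_id": es.subject_id,
                "group": es.group,
                "moca": es.moca,
                "condition": ep.condition,
                "session": ep.session_index,
                **feats.as_dict(),
            })
    return pd.DataFrame(rows)
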
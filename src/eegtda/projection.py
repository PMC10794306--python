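"""Seeded 2-D manifold projections (UMAP / t-SNE) of the feature table.

Strictly unsupervised: the projector receives only the six standardised
feature columns, never the group labels or MoCA scores; those are
returned alongside the coordinates purely for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tda import FEATURE_NAMES

__all__ = ["Projection2D", "project"]


@dataclass
class Projection2D:
    coordinates: np.ndarray  # (n_epochs, 2)
    method: str
    condition: str
    seed: int
    labels: pd.DataFrame     # group / moca / subject_id, for plotting only


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def project(features: pd.DataFrame, method: str = "umap",
            condition: str = "ALL", seed: int = 0,
            **kwargs) -> Projection2D:
    """Project the per-epoch feature vectors to two dimensions.

    Feature columns are z-scored first (counts and entropies live on very
    different scales). Deterministic given ``seed``. Method defaults are
    the library defaults (UMAP n_neighbors=15, min_dist=0.1; t-SNE
    perplexity=30, lowered automatically for small inputs).
    """
    sub = features if condition == "ALL" else \
        features[features["condition"] == condition]
    x = _standardize(sub.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float))
    n = len(x)
    if method == "umap":
        if n < 3:
            raise ValueError("UMAP needs at least 3 points")
        from umap import UMAP  # deferred: heavy import
        coords = UMAP(n_components=2, random_state=seed,
                      **kwargs).fit_transform(x)
    elif method == "tsne":
        from sklearn.manifold import TSNE
        perplexity = kwargs.pop("perplexity", 30.0)
        perplexity = min(perplexity, (n - 1) / 3.0)
        if n < 4 or perplexity <= 0:
            raise ValueError("too few points for t-SNE")
        coords = TSNE(n_components=2, random_state=seed,
                      perplexity=perplexity, init="pca",
                      **kwargs).fit_transform(x)
    else:
        raise ValueError(f"unknown method {method!r}")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("projection produced non-finite coordinates")
    label_cols = [c for c in ("subject_id", "group", "moca") if c in sub]
    return Projection2D(
        coordinates=coords, method=method, condition=condition, seed=seed,
        labels=sub.loc[:, label_cols].reset_index(drop=True))
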
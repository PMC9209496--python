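"""Dimensionality reduction: PCA to a compact analysis space (default 50
components) and UMAP to 2-D for visualization.

PCA output is made deterministic by canonicalizing each component's sign
so that its largest-magnitude loading is positive. UMAP is reproducible
for a fixed seed but orientation-arbitrary, as usual for nonlinear
embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import RepresentationMatrix

#: column count above which randomized (seeded) SVD is used instead of exact
_RANDOMIZED_SVD_THRESHOLD = 2000


@dataclass(frozen=True)
class ProjectionConfig:
    """PCA / UMAP parameters (defaults: 50 components, 50 neighbors,
    min_dist 0.3)."""

    pca_components: int = 50
    umap_neighbors: int = 50
    umap_min_dist: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pca_components < 1 or self.umap_neighbors < 1:
            raise ValueError("pca_components and umap_neighbors must be positive")
        if not 0.0 <= self.umap_min_dist <= 1.0:
            raise ValueError("umap_min_dist must lie in [0, 1]")


def pca_reduce(m: RepresentationMatrix, c: ProjectionConfig = ProjectionConfig()
               ) -> tuple[RepresentationMatrix, np.ndarray]:
    """Center and project onto the top principal components.

    Returns the reduced matrix (provenance ``pca-reduced``) and the
    per-component explained-variance ratios (nonincreasing, each in
    [0, 1]). Exact SVD is used up to 2,000 input columns, seeded
    randomized SVD above.
    """
    n, d = m.vectors.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    if c.pca_components > min(n, d):
        raise ValueError(
            f"pca_components={c.pca_components} exceeds min(rows={n}, cols={d})"
        )
    solver = "full" if d <= _RANDOMIZED_SVD_THRESHOLD else "randomized"
    pca = PCA(n_components=c.pca_components, svd_solver=solver, random_state=c.seed)
    scores = pca.fit_transform(m.vectors)
    # canonical sign: largest-magnitude loading of each component positive
    flip = np.sign(
        pca.components_[np.arange(c.pca_components),
                        np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    reduced = RepresentationMatrix(m.ids, scores, "pca-reduced")
    return reduced, pca.explained_variance_ratio_.copy()


def umap_project(m: RepresentationMatrix, c: ProjectionConfig = ProjectionConfig()
                 ) -> pd.DataFrame:
    """Project rows to 2-D with UMAP; returns a DataFrame (id, x, y).

    Requires at least ``umap_neighbors + 1`` rows; all UMAP parameters
    other than n_neighbors, min_dist and the seed stay at library
    defaults.
    """
    n = len(m.ids)
    if n < c.umap_neighbors + 1:
        raise ValueError(
            f"{n} rows is too few for umap_neighbors={c.umap_neighbors}; "
            "use a smaller umap_neighbors"
        )
    import umap  # deferred: umap import is slow

    reducer = umap.UMAP(n_neighbors=c.umap_neighbors, min_dist=c.umap_min_dist,
                        n_components=2, random_state=c.seed)
    coords = reducer.fit_transform(m.vectors)
    return pd.DataFrame({"id": m.ids, "x": coords[:, 0], "y": coords[:, 1]})
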
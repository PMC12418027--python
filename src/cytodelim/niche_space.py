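"""Two-dimensional niche space by principal component analysis.

The pruned, z-scored environmental matrix is projected onto its first two
principal components; since the input is standardized this is equivalent to
correlation-matrix PCA on the raw predictors. Eigenvector sign is arbitrary,
so a deterministic convention (largest-magnitude loading positive) is applied
to keep scores reproducible across runs and BLAS builds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .extraction import EnvMatrix


@dataclass
class PcaResult:
    scores: pd.DataFrame          # records x components, columns PC1..PCk
    loadings: pd.DataFrame        # variables x components
    explained_variance_ratio: np.ndarray  # per retained component
    species: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_by_species(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for sp in pd.unique(self.species):
            out[str(sp)] = self.scores.loc[self.species == sp].to_numpy()
        return out


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude element positive (first on ties)."""
    fixed = components.copy()
    for k in range(fixed.shape[0]):
        j = int(np.argmax(np.abs(fixed[k])))
        if fixed[k, j] < 0:
            fixed[k] = -fixed[k]
    return fixed


def pca_fit(m: EnvMatrix, n_components: int = 2) -> PcaResult:
    """Fit PCA on a standardized environmental matrix, retaining ``n_components``.

    Components are eigenvectors of the sample covariance matrix ordered by
    eigenvalue; scores are the centered data projected onto them.
    """
    if not m.standardized:
        raise ValueError("pca_fit expects a standardized (z-scored) matrix")
    X = m.data.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 records for PCA")
    if X.shape[1] < n_components:
        raise ValueError(
            f"{X.shape[1]} variables cannot support {n_components} components"
        )
    # degenerate (constant) columns cannot span the requested projection
    if np.sum(X.var(axis=0) > 1e-12) < n_components:
        raise ValueError("fewer than requested non-degenerate dimensions")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(X)
    comps = _fix_signs(pca.components_[:n_components])
    scores = (X - X.mean(axis=0)) @ comps.T
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.data.index, columns=cols),
        loadings=pd.DataFrame(comps.T, index=m.data.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_[:n_components].copy(),
        species=m.species.copy(),
    )


def plot_scores(result: PcaResult, ax=None):
    """Minimal PC1/PC2 scatter colored by species (helper, not publication art)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for sp, pts in result.scores_by_species().items():
        ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.7, label=sp)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.legend()
    return ax
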
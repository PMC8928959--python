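"""Class-separability diagnostics for feature, latent, decoded and residual spaces.

Embeddings (PCA for linear, t-SNE for non-linear structure) visualise how
the two classes distribute in a representation; the generalized
contrast-to-noise ratio (GCNR) quantifies it.  GCNR is one minus the
overlap of the two class distributions' normalised histograms: 1 means
the classes are perfectly separable along the measured axis, 0 means the
distributions coincide.  For multivariate representations the score is
taken along the first principal component ("1D-PCA-GCNR").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "EmbeddingResult",
    "SeparabilityReport",
    "pca_project",
    "tsne_project",
    "gcnr",
    "pca1d_gcnr",
    "residual_report",
    "plot_embedding",
]

SourceSpace = Literal["feature", "latent", "decoded", "residual", "embedding"]


@dataclass(frozen=True)
class EmbeddingResult:
    coordinates: np.ndarray  # rows x dims, dims in {1, 2}
    method: Literal["pca", "tsne"]
    labels: Optional[np.ndarray] = None
    source_space: SourceSpace = "feature"

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != self.coordinates.shape[0]:
            raise ValueError("labels must align with embedding rows")


@dataclass(frozen=True)
class SeparabilityReport:
    gcnr: float
    bins: int
    n_pos: int
    n_neg: int
    source_space: SourceSpace = "feature"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gcnr <= 1.0 + 1e-12:
            raise ValueError(f"gcnr must lie in [0, 1], got {self.gcnr}")


def _fix_sign(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude loading is positive."""
    flipped = components.copy()
    for i, comp in enumerate(flipped):
        j = np.argmax(np.abs(comp))
        if comp[j] < 0:
            flipped[i] = -comp
    return flipped


def pca_project(matrix: np.ndarray, dims: int = 2, labels: Optional[Sequence[int]] = None,
                source_space: SourceSpace = "feature") -> EmbeddingResult:
    """Project onto the top principal components of the mean-centred data.

    Component signs are fixed (largest-magnitude loading forced positive)
    so scores are reproducible across runs and libraries.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(matrix, dtype=np.float64)
    if dims not in (1, 2):
        raise ValueError("dims must be 1 or 2")
    if X.ndim != 2 or X.shape[0] < dims + 1:
        raise ValueError(f"need at least {dims + 1} rows for a {dims}-D projection")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("matrix has no variance; PCA undefined")

    pca = PCA(n_components=dims, svd_solver="full")
    pca.fit(X)
    comps = _fix_sign(pca.components_)
    coords = (X - pca.mean_) @ comps.T
    lab = None if labels is None else np.asarray(labels)
    return EmbeddingResult(coordinates=coords, method="pca", labels=lab, source_space=source_space)


def tsne_project(matrix: np.ndarray, seed: int, perplexity: float = 30.0,
                 labels: Optional[Sequence[int]] = None,
                 source_space: SourceSpace = "feature") -> EmbeddingResult:
    """2-D t-SNE embedding, reproducible under a fixed seed.

    Perplexity defaults to 30 and is clamped to (rows - 1) / 3; purely a
    visualisation aid, never used for scoring decisions.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 5:
        raise ValueError("t-SNE needs at least 5 rows")
    perp = min(perplexity, (X.shape[0] - 1) / 3)
    if perp < 1:
        raise ValueError(
            f"too few rows ({X.shape[0]}) for any valid perplexity; provide >= 7 rows"
        )
    coords = TSNE(n_components=2, perplexity=perp, random_state=seed, init="pca").fit_transform(X)
    lab = None if labels is None else np.asarray(labels)
    return EmbeddingResult(coordinates=np.asarray(coords, dtype=np.float64), method="tsne",
                           labels=lab, source_space=source_space)


def gcnr(samples_pos: np.ndarray, samples_neg: np.ndarray, bins: int = 100) -> float:
    """Generalized contrast-to-noise ratio of two 1-D sample sets.

    Histograms share `bins` equal-width bins over the pooled min-max
    range; each histogram is normalised to sum 1; the score is
    ``1 - sum_i min(h_pos_i, h_neg_i)``.
    """
    p = np.asarray(samples_pos, dtype=np.float64).ravel()
    n = np.asarray(samples_neg, dtype=np.float64).ravel()
    if p.size == 0 or n.size == 0:
        raise ValueError("both sample sets must be non-empty")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    lo = min(p.min(), n.min())
    hi = max(p.max(), n.max())
    if lo == hi:  # all mass in one point: full overlap
        return 0.0
    hp, _ = np.histogram(p, bins=bins, range=(lo, hi))
    hn, _ = np.histogram(n, bins=bins, range=(lo, hi))
    overlap = np.minimum(hp / p.size, hn / n.size).sum()
    return float(1.0 - overlap)


def pca1d_gcnr(matrix: np.ndarray, labels: Sequence[int], bins: int = 100,
               source_space: SourceSpace = "feature") -> SeparabilityReport:
    """GCNR of the two label groups along the first principal component."""
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    scores = pca_project(matrix, dims=1).coordinates[:, 0]
    value = gcnr(scores[y == 1], scores[y == 0], bins=bins)
    return SeparabilityReport(gcnr=value, bins=bins, n_pos=n_pos, n_neg=n_neg,
                              source_space=source_space)


def plot_embedding(embedding: EmbeddingResult, path=None, title: Optional[str] = None):
    """Scatter plot of a 2-D embedding coloured by class (requires matplotlib).

    Returns the matplotlib Axes; saves to *path* (PNG/SVG by extension)
    when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = embedding.coordinates
    if coords.shape[1] != 2:
        raise ValueError("plotting requires a 2-D embedding")
    fig, ax = plt.subplots(figsize=(5, 4))
    if embedding.labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=8, alpha=0.6)
    else:
        y = np.asarray(embedding.labels)
        for value, name, color in ((0, "negative", "tab:blue"), (1, "positive", "tab:red")):
            sel = y == value
            ax.scatter(coords[sel, 0], coords[sel, 1], s=8, alpha=0.6, label=name, c=color)
        ax.legend(frameon=False)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(title or f"{embedding.method} / {embedding.source_space}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def residual_report(results, features: np.ndarray, labels: Sequence[int],
                    bins: int = 100) -> dict[str, SeparabilityReport]:
    """Separability of the input X, decoded X' and residual X - X' spaces.

    All three reports use the same labels and bin count.  An informative
    latent space keeps the decoded space about as separable as the input,
    while the residual should carry little class information.
    """
    X = np.asarray(features, dtype=np.float64)
    decoded, residual = results.reconstruct(X)
    return {
        "feature": pca1d_gcnr(X, labels, bins=bins, source_space="feature"),
        "decoded": pca1d_gcnr(decoded, labels, bins=bins, source_space="decoded"),
        "residual": pca1d_gcnr(residual, labels, bins=bins, source_space="residual"),
    }
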
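"""PCA of a reference panel and projection of query genotypes.

The principal axes are defined by the reference samples only; queries are
projected through the reference model (centered by the *reference* locus
means, multiplied by the reference loadings) and can never alter the axes.
Missing dosages are mean-imputed per locus, always with the reference means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from feralmix.genotype_io import GenotypeMatrix


@dataclass
class PCAModel:
    """Reference-defined principal axes for genotype dosage data."""

    locus_means: np.ndarray  # length L, mean dosage over reference samples
    locus_scales: np.ndarray | None  # length L when fitted with scale=True
    loadings: np.ndarray  # L x C, orthonormal columns
    reference_scores: np.ndarray  # n_ref x C
    explained_variance: np.ndarray  # length C
    marker_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _imputed_centered(
    g: GenotypeMatrix, means: np.ndarray, scales: np.ndarray | None
) -> np.ndarray:
    X = g.dosage.astype(np.float64)
    obs = g.observed_mask()
    X = np.where(obs, X, means[None, :])
    X -= means[None, :]
    if scales is not None:
        X /= scales[None, :]
    return X


def fit_reference_pca(
    panel: GenotypeMatrix, n_components: int, scale: bool = False
) -> PCAModel:
    """Principal components of the reference dosage matrix.

    Missing dosages are mean-imputed per locus; the matrix is column-centered
    (and optionally scaled by per-locus SD).  Components follow the sign
    convention that each column's largest-magnitude loading is positive.
    """
    n, L = panel.n_samples, panel.n_markers
    if not 1 <= n_components <= min(n - 1, L):
        raise ValueError(f"n_components must be in [1, min(n_ref - 1, L)] = "
                         f"[1, {min(n - 1, L)}]")
    obs = panel.observed_mask()
    X = panel.dosage.astype(np.float64)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        raise ValueError("a locus has no observed genotypes")
    means = np.where(obs, X, 0.0).sum(axis=0) / n_obs
    Xc = np.where(obs, X, means[None, :]) - means[None, :]
    scales = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        scales = np.where(sd > 0, sd, 1.0)
        Xc = Xc / scales[None, :]
    if not np.any(Xc):
        raise ValueError("zero-variance panel: PCA undefined")

    # eigendecomposition of the sample covariance via thin SVD
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:n_components].T  # L x C
    # sign convention: largest-magnitude loading positive in each component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[None, :]
    scores = Xc @ loadings
    explained = (s[:n_components] ** 2) / (n - 1)
    return PCAModel(
        locus_means=means,
        locus_scales=scales,
        loadings=loadings,
        reference_scores=scores,
        explained_variance=explained,
        marker_ids=panel.marker_ids,
    )


def project_queries(model: PCAModel, queries: GenotypeMatrix) -> np.ndarray:
    """Project query genotypes onto the reference axes.

    Queries are mean-imputed and centered with the *model's* locus means
    (never query means) and multiplied by the reference loadings; a marker
    mismatch with the fitted model is an error.
    """
    if queries.marker_ids != model.marker_ids:
        raise ValueError("query markers do not match the fitted PCA model")
    X = _imputed_centered(queries, model.locus_means, model.locus_scales)
    return X @ model.loadings


def plot_projection(
    model: PCAModel,
    queries: GenotypeMatrix | None,
    reference_groups: list[str],
    query_groups: list[str] | None,
    path: str,
    components: tuple[int, int] = (0, 1),
) -> None:
    """Two-panel reference/query scatter (reference triangles, query circles)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cx, cy = components
    fig, ax = plt.subplots(figsize=(7, 6))
    ref = model.reference_scores
    for grp in dict.fromkeys(reference_groups):
        idx = [i for i, g in enumerate(reference_groups) if g == grp]
        ax.scatter(ref[idx, cx], ref[idx, cy], marker="^", s=24, alpha=0.7,
                   label=f"ref: {grp}")
    if queries is not None:
        qs = project_queries(model, queries)
        qgroups = query_groups or ["query"] * queries.n_samples
        for grp in dict.fromkeys(qgroups):
            idx = [i for i, g in enumerate(qgroups) if g == grp]
            ax.scatter(qs[idx, cx], qs[idx, cy], marker="o", s=18, alpha=0.7,
                       label=grp)
    tot = model.explained_variance.sum()
    ax.set_xlabel(f"PC{cx + 1} ({100 * model.explained_variance[cx] / tot:.1f}%)")
    ax.set_ylabel(f"PC{cy + 1} ({100 * model.explained_variance[cy] / tot:.1f}%)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
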
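"""2-D t-SNE embedding of mesh shapes with an out-of-sample extension.

Each mesh is represented by its centroid-centred, flattened node coordinates
(no scale normalisation: the radius scale is physically informative).  The
training set is embedded in 2-D by t-SNE; unseen meshes are placed by a
deterministic k-nearest-neighbour Gaussian-kernel interpolation in the
high-dimensional input space, which returns the training coordinate exactly
when the query coincides with a training mesh.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

from .geometry import VesselGeometry

__all__ = ["shape_vectors", "ShapeEmbedding"]


def shape_vectors(geoms: list[VesselGeometry]) -> np.ndarray:
    """Stack the centroid-centred flattened coordinates of each mesh (M x D)."""
    return np.vstack([g.shape_vector() for g in geoms])


class ShapeEmbedding(BaseEstimator):
    """t-SNE shape embedding with k-NN Gaussian-kernel out-of-sample placement.

    Parameters
    ----------
    perplexity : float
        t-SNE effective neighbourhood size (must be < number of samples).
    n_neighbors : int
        Neighbour count for out-of-sample interpolation.
    bandwidth : float or None
        Gaussian kernel bandwidth h; None uses, per query, the median of the
        distances to its ``n_neighbors`` nearest training meshes.
    random_state : int
        Seed; the embedding is reproducible bit-for-bit under a fixed seed.

    Attributes
    ----------
    embedding_ : (M, 2) ndarray — t-SNE coordinates of the training meshes.
    """

    def __init__(
        self,
        perplexity: float = 30.0,
        n_neighbors: int = 5,
        bandwidth: float | None = None,
        random_state: int = 0,
    ):
        self.perplexity = perplexity
        self.n_neighbors = n_neighbors
        self.bandwidth = bandwidth
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 4:
            raise ValueError("need an M x D matrix with M >= 4 shape vectors")
        if not self.perplexity < X.shape[0]:
            raise ValueError("perplexity must be smaller than the sample count")
        tsne = TSNE(
            n_components=2,
            perplexity=self.perplexity,
            init="pca",
            learning_rate="auto",
            random_state=self.random_state,
        )
        self.X_fit_ = X
        self.embedding_ = np.asarray(tsne.fit_transform(X), dtype=float)
        self._nn = NearestNeighbors(
            n_neighbors=min(self.n_neighbors, X.shape[0])
        ).fit(X)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X) -> np.ndarray:
        """Place unseen shape vectors in the trained 2-D space.

        Each query is mapped to the Gaussian-kernel-weighted mean of the
        embeddings of its nearest training meshes,
        ``w_j = exp(-||x - x_j||^2 / (2 h^2))`` normalised to sum to one.  A
        query identical to a training mesh returns that mesh's coordinate.
        """
        check_is_fitted(self, "embedding_")
        Q = np.atleast_2d(np.asarray(X, dtype=float))
        if Q.shape[1] != self.X_fit_.shape[1]:
            raise ValueError(
                f"query length {Q.shape[1]} != training length {self.X_fit_.shape[1]}"
            )
        dist, idx = self._nn.kneighbors(Q)
        out = np.empty((Q.shape[0], 2))
        for i, (d, j) in enumerate(zip(dist, idx)):
            exact = [jj for jj in j if np.array_equal(Q[i], self.X_fit_[jj])]
            if exact:                            # exact-match shortcut
                out[i] = self.embedding_[exact[0]]
                continue
            h = self.bandwidth if self.bandwidth is not None else float(np.median(d))
            w = np.exp(-(d**2) / (2.0 * h**2))
            s = w.sum()
            if s == 0.0:                         # all neighbours beyond kernel reach
                nearest = int(np.argmin(d))
                out[i] = self.embedding_[j[nearest]]
            else:
                out[i] = (w / s) @ self.embedding_[j]
        return out

    def cluster_separation(self, labels) -> tuple[float, float]:
        """Mean intra-label vs inter-label pairwise distance in the embedding.

        Diagnostic for whether phantoms cluster around their parent vessels;
        a well-formed embedding has intra < inter.
        """
        check_is_fitted(self, "embedding_")
        labels = np.asarray(labels)
        E = self.embedding_
        diff = E[:, None, :] - E[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(E), k=1)
        intra = d[iu][same[iu]]
        inter = d[iu][~same[iu]]
        return float(intra.mean()), float(inter.mean())
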
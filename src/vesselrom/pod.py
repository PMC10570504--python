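"""Mesh-domain common-base proper orthogonal decomposition (cPOD).

Steady solutions computed on distinct but topologically identical meshes are
stacked row-wise into an M x N matrix (M meshes, N nodes) and factored by SVD,
A = U D V^T.  The rows of V^T are the spatial modes shared by all meshes; the
rows of U D are each mesh's principal coefficients.  Because the ensemble
dimension M is far below the node count N, the decomposition is computed by
the snapshot method (eigendecomposition of the M x M matrix A A^T) by default.

Mode-truncation follows the singular-value *sum* energy criterion: the energy
fraction of the k leading modes is sum(sigma_1..k) / sum(sigma), and modes are
retained until a chosen fraction (e.g. 0.95) of that total is captured.  The
conventional sigma^2 (variance) fraction is exposed alongside for comparison.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .solver import FlowSolution

__all__ = ["assemble", "CommonBasePOD"]


def assemble(solutions: list[FlowSolution], field: str) -> np.ndarray:
    """Stack one field of each solution into the M x N solution matrix.

    ``field`` routes "pressure" to the volume-node values and "wss" to the
    surface-node values.  Row order follows the input order; values are copied
    unmodified.  Raises on fewer than two solutions or inconsistent node
    counts (the common basis requires identical mesh topology).
    """
    if field not in ("pressure", "wss"):
        raise ValueError("field must be 'pressure' or 'wss'")
    if len(solutions) < 2:
        raise ValueError("need at least 2 solutions")
    rows = [getattr(s, field) for s in solutions]
    n = rows[0].size
    for s, row in zip(solutions, rows):
        if row.size != n:
            raise ValueError(
                f"mesh {s.mesh_id!r} has {row.size} nodes, expected {n}: "
                "all meshes must share one topology"
            )
    return np.vstack(rows)


class CommonBasePOD(TransformerMixin, BaseEstimator):
    """Common-base POD of a solution matrix, sklearn transformer style.

    Parameters
    ----------
    n_modes : int or None
        Number of modes to retain.  If None, ``energy_threshold`` decides.
    energy_threshold : float or None
        Retain the smallest k whose singular-value-sum energy fraction meets
        this threshold (in (0, 1]).  If both are None, full rank is kept.
    center : bool
        Subtract the ensemble mean before factoring.  Off by default: the
        stacked matrix is factored directly, so mode 1 carries the ensemble
        mean pattern.
    method : {"auto", "snapshot", "direct"}
        "snapshot" solves the M x M eigenproblem of A A^T (preferred when
        N >> M); "direct" calls the dense SVD; "auto" picks by shape.

    Attributes
    ----------
    components_ : (rank, N) ndarray
        Orthonormal spatial modes (all of them; ``transform`` uses the first
        ``n_modes_``).  Sign convention: the largest-magnitude entry of each
        mode is non-negative, making the factorisation backend-independent.
    singular_values_ : (rank,) ndarray
        Full non-increasing spectrum (kept for energy accounting).
    coefficients_ : (M, rank) ndarray
        Principal coefficients of the training meshes, rows of U D.
    n_modes_ : int
        Retained mode count used by transform/inverse_transform.
    """

    def __init__(
        self,
        n_modes: int | None = None,
        energy_threshold: float | None = None,
        center: bool = False,
        method: str = "auto",
    ):
        self.n_modes = n_modes
        self.energy_threshold = energy_threshold
        self.center = center
        self.method = method

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        A = np.asarray(X, dtype=float)
        if A.ndim != 2:
            raise ValueError("expected an M x N solution matrix")
        if not np.all(np.isfinite(A)):
            raise ValueError("solution matrix contains non-finite values")
        self.mean_ = A.mean(axis=0) if self.center else np.zeros(A.shape[1])
        A0 = A - self.mean_ if self.center else A

        method = self.method
        if method == "auto":
            method = "snapshot" if A0.shape[1] > 4 * A0.shape[0] else "direct"
        if method == "snapshot":
            u0, _ = _snapshot_left_factors(A0)
            # project onto the snapshot subspace and polish with a small SVD:
            # A0 = u0 (u0^T A0) exactly, so the polish restores orthonormal
            # modes to machine precision even for near-noise trailing modes
            w, sigma, vt = np.linalg.svd(u0.T @ A0, full_matrices=False)
            u = u0 @ w
            keep = sigma > max(A0.shape) * np.finfo(float).eps * (sigma[0] if sigma.size else 1.0)
            u, sigma, vt = u[:, keep], sigma[keep], vt[keep]
        elif method == "direct":
            u, sigma, vt = np.linalg.svd(A0, full_matrices=False)
            keep = sigma > max(A0.shape) * np.finfo(float).eps * (sigma[0] if sigma.size else 1.0)
            u, sigma, vt = u[:, keep], sigma[keep], vt[keep]
        else:
            raise ValueError(f"unknown method {self.method!r}")

        # fix signs: largest-magnitude entry of each mode non-negative
        flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
        flip[flip == 0] = 1.0
        vt = vt * flip[:, None]
        u = u * flip[None, :]

        self.components_ = vt
        self.singular_values_ = sigma
        self.coefficients_ = u * sigma[None, :]
        self.n_features_in_ = A.shape[1]
        self.n_modes_ = self._resolve_k()
        return self

    def _resolve_k(self) -> int:
        rank = self.singular_values_.size
        if self.n_modes is not None:
            if not 1 <= self.n_modes:
                raise ValueError("n_modes must be >= 1")
            return min(self.n_modes, rank)
        if self.energy_threshold is not None:
            t = self.energy_threshold
            if not 0 < t <= 1:
                raise ValueError("energy_threshold must lie in (0, 1]")
            frac = np.cumsum(self.singular_values_) / self.singular_values_.sum()
            return int(np.searchsorted(frac, t - 1e-12) + 1)
        return rank

    # -- queries -----------------------------------------------------------

    def energy_fraction(self, k: int, squared: bool = False) -> float:
        """Energy fraction of the k leading modes.

        By default the singular-value sum criterion sum(sigma_1..k)/sum(sigma);
        with ``squared=True`` the conventional variance fraction on sigma^2.
        """
        check_is_fitted(self, "singular_values_")
        sigma = self.singular_values_
        if not 1 <= k <= sigma.size:
            raise ValueError(f"k must lie in [1, {sigma.size}]")
        w = sigma**2 if squared else sigma
        return float(w[:k].sum() / w.sum())

    def truncate(self, n_modes: int | None = None, energy_threshold: float | None = None):
        """Return a copy of this fitted basis restricted to k modes.

        The full singular-value spectrum is kept for energy accounting; the
        retained mode count changes what transform/inverse_transform use.
        """
        check_is_fitted(self, "components_")
        out = CommonBasePOD(
            n_modes=n_modes,
            energy_threshold=energy_threshold,
            center=self.center,
            method=self.method,
        )
        out.mean_ = self.mean_
        out.components_ = self.components_
        out.singular_values_ = self.singular_values_
        out.coefficients_ = self.coefficients_
        out.n_features_in_ = self.n_features_in_
        out.n_modes_ = out._resolve_k()
        return out

    # -- projection / reconstruction ---------------------------------------

    def transform(self, X) -> np.ndarray:
        """Project field vectors onto the retained modes: c = f . V_k."""
        check_is_fitted(self, "components_")
        F = np.atleast_2d(np.asarray(X, dtype=float))
        if F.shape[1] != self.n_features_in_:
            raise ValueError(
                f"field length {F.shape[1]} != fitted node count {self.n_features_in_}"
            )
        return (F - self.mean_) @ self.components_[: self.n_modes_].T

    def inverse_transform(self, C) -> np.ndarray:
        """Reconstruct field vectors from coefficients: f_hat = c . V_k^T."""
        check_is_fitted(self, "components_")
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[1] != self.n_modes_:
            raise ValueError(f"expected {self.n_modes_} coefficients, got {C.shape[1]}")
        return C @ self.components_[: self.n_modes_] + self.mean_

    def reconstruct_training(self) -> np.ndarray:
        """Reconstruct every training row from its retained coefficients."""
        check_is_fitted(self, "coefficients_")
        return self.inverse_transform(self.coefficients_[:, : self.n_modes_])


def _snapshot_left_factors(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Left singular vectors and singular values via the M x M correlation matrix."""
    C = A @ A.T
    evals, evecs = np.linalg.eigh(C)          # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]
    tol = max(A.shape) * np.finfo(float).eps * max(evals[0], 0.0)
    keep = evals > tol
    return evecs[:, keep], np.sqrt(evals[keep])
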
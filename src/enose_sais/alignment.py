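"""PCA subspaces and closed-form subspace alignment (the SAIS core).

The carrier of a bacterial specimen (culture solution vs an infected wound)
adds its own background odor, so the same sensor array produces feature
distributions that differ between carriers.  SAIS models the two domains by
the subspaces spanned by their top-D principal directions, S_S and S_T
(both d × D with orthonormal columns), and aligns the target subspace to the
source one with the D × D map M minimizing the Bregman matrix divergence

    F(M) = || S_S - S_T M ||_F^2 .

Because the bases are orthonormal the minimizer is closed-form,
M* = S_T^T S_S, and the aligned target coordinate system is
S_a = S_T M* = S_T S_T^T S_S.  Source samples are represented as X_S S_S and
target samples as X_T S_a; a classifier trained on the former can then be
applied to the latter.  No target labels are needed anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import InvalidParameterError, RankError, ShapeMismatchError
from .preprocessing import DomainDataset, zscore_standardize

_ORTHO_TOL = 1e-10


@dataclass
class Subspace:
    """Orthonormal basis of one domain's top-D principal directions.

    ``basis`` is d × D with orthonormal columns (checked to 1e-10);
    ``eigenvalues`` are the matching covariance eigenvalues, non-increasing.
    """

    basis: np.ndarray
    eigenvalues: np.ndarray
    domain_tag: str = "source"

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.basis.ndim != 2:
            raise ShapeMismatchError("basis must be a (d, D) matrix")
        d, D = self.basis.shape
        if self.eigenvalues.shape != (D,):
            raise ShapeMismatchError("one eigenvalue per basis column required")
        gram = self.basis.T @ self.basis
        if np.abs(gram - np.eye(D)).max() > _ORTHO_TOL:
            raise InvalidParameterError("basis columns are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise InvalidParameterError("eigenvalues must be non-increasing")
        if np.any(self.eigenvalues < -1e-12):
            raise InvalidParameterError("eigenvalues must be non-negative")

    @property
    def n_features(self) -> int:
        return self.basis.shape[0]

    @property
    def size(self) -> int:
        return self.basis.shape[1]

    def save_csv(self, path) -> None:
        """Matrix dump with a shape/eigenvalue header comment."""
        d, D = self.basis.shape
        header = (
            f"subspace domain={self.domain_tag} d={d} D={D}\n"
            "eigenvalues=" + ",".join(f"{v:.12g}" for v in self.eigenvalues)
        )
        np.savetxt(path, self.basis, delimiter=",", header=header)


@dataclass
class AlignmentResult:
    """Optimal map M*, aligned target basis S_a = S_T M*, and residual F(M*)."""

    m_star: np.ndarray
    aligned_basis: np.ndarray
    residual: float


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|.| entry is positive (determinism)."""
    idx = np.argmax(np.abs(basis), axis=0)
    flip = np.sign(basis[idx, np.arange(basis.shape[1])])
    flip[flip == 0] = 1.0
    return basis * flip


def _pca_basis(X: np.ndarray, D: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-D principal directions and eigenvalues of (defensively centered) X."""
    pca = PCA(n_components=D, svd_solver="full")
    pca.fit(X)
    return _fix_signs(pca.components_.T), pca.explained_variance_.copy()


def effective_rank(X: np.ndarray) -> int:
    """Numerical rank of the centered data matrix (caps the usable D)."""
    Xc = X - X.mean(axis=0)
    return int(np.linalg.matrix_rank(Xc))


def pca_subspace(dataset: DomainDataset, D: int) -> Subspace:
    """Fit the top-D principal subspace of a (standardized) feature matrix.

    The basis columns are the eigenvectors of the sample covariance for the
    D largest eigenvalues; data are re-centered defensively even though
    z-scored input is already column-centered.  Eigenvector signs follow the
    largest-entry-positive convention so results are deterministic.
    """
    X = dataset.features
    N, d = X.shape
    if not 1 <= D <= min(d, N - 1):
        raise InvalidParameterError(
            f"D must be in [1, {min(d, N - 1)}] for {N} samples of dimension {d}"
        )
    rank = effective_rank(X)
    if D > rank:
        raise RankError(
            f"requested D={D} exceeds the effective rank {rank} of the data",
            achievable=rank,
        )
    basis, eigenvalues = _pca_basis(X, D)
    return Subspace(basis=basis, eigenvalues=eigenvalues, domain_tag=dataset.domain_tag)


def bregman_divergence(source_sub: Subspace, target_sub: Subspace, M: np.ndarray) -> float:
    """F(M) = ||S_S − S_T·M||_F², the alignment objective."""
    M = np.asarray(M, dtype=float)
    if source_sub.basis.shape != target_sub.basis.shape:
        raise ShapeMismatchError("subspaces must share d and D")
    D = source_sub.size
    if M.shape != (D, D):
        raise ShapeMismatchError(f"M must be {D} x {D}")
    diff = source_sub.basis - target_sub.basis @ M
    return float(np.linalg.norm(diff, "fro") ** 2)


def alignment_matrix(source_sub: Subspace, target_sub: Subspace) -> AlignmentResult:
    """Closed-form minimizer M* = S_T^T S_S of the alignment objective.

    With orthonormal bases no regularization is needed; M* is the global
    least-squares solution and S_a = S_T M* = S_T S_T^T S_S is the
    source-aligned target coordinate system.
    """
    if source_sub.n_features != target_sub.n_features or source_sub.size != target_sub.size:
        raise ShapeMismatchError("subspaces must share d and D")
    m_star = target_sub.basis.T @ source_sub.basis
    aligned = target_sub.basis @ m_star
    residual = bregman_divergence(source_sub, target_sub, m_star)
    return AlignmentResult(m_star=m_star, aligned_basis=aligned, residual=residual)


def _subset_for_subspace(
    target: DomainDataset,
    n_target_for_subspace,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Row indices of the target samples used to fit the target subspace.

    ``"all"`` uses every sample.  An integer n is a per-class count when the
    target carries labels (simulation/sweep design; the labels steer only the
    draw, never the transform) and otherwise simply the first n rows, as in
    unlabeled deployment.
    """
    N = target.n_samples
    if n_target_for_subspace in (None, "all"):
        return np.arange(N)
    n = int(n_target_for_subspace)
    if n < 2:
        raise InvalidParameterError("n_target_for_subspace must be >= 2 or 'all'")
    if target.labels is None:
        return np.arange(min(n, N))
    idx: list[np.ndarray] = []
    for c in np.unique(target.labels):
        rows = np.flatnonzero(target.labels == c)
        take = min(n, rows.size)
        if rng is not None:
            rows = rng.choice(rows, size=take, replace=False)
        else:
            rows = rows[:take]
        idx.append(np.sort(rows))
    return np.concatenate(idx)


def sais_transform(
    source: DomainDataset,
    target: DomainDataset,
    D: int = 25,
    n_target_for_subspace="all",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, AlignmentResult]:
    """Full SAIS pipeline: standardize, fit subspaces, align, project.

    Each domain is z-scored with its own statistics (all available target
    samples contribute to the target statistics even when only a subset fits
    the subspace).  When the requested D exceeds what either domain's rank
    supports, both subspaces are capped at the common achievable size with a
    warning — e.g. a 5-per-class target subset cannot support D = 25.

    Returns
    -------
    projected_source : ndarray (N_S, D_eff) — X_S·S_S
    projected_target : ndarray (N_T, D_eff) — X_T·S_a (all target rows)
    result : AlignmentResult
    """
    if source.n_features != target.n_features:
        raise ShapeMismatchError("source and target must share the sensor dimension")
    zs, _, _ = zscore_standardize(source)
    zt, _, _ = zscore_standardize(target)

    subset = _subset_for_subspace(zt, n_target_for_subspace, rng)
    Xt_fit = zt.features[subset]

    max_d = min(
        source.n_features,
        zs.n_samples - 1,
        Xt_fit.shape[0] - 1,
        effective_rank(zs.features),
        effective_rank(Xt_fit),
    )
    D_eff = min(D, max_d)
    if D_eff < 1:
        raise InvalidParameterError("not enough samples to fit any subspace")
    if D_eff < D:
        warnings.warn(
            f"subspace size capped at {D_eff} (requested {D}) by the data rank",
            stacklevel=2,
        )

    basis_s, eig_s = _pca_basis(zs.features, D_eff)
    basis_t, eig_t = _pca_basis(Xt_fit, D_eff)
    source_sub = Subspace(basis_s, eig_s, "source")
    target_sub = Subspace(basis_t, eig_t, "target")
    result = alignment_matrix(source_sub, target_sub)

    projected_source = zs.features @ source_sub.basis
    projected_target = zt.features @ result.aligned_basis
    return projected_source, projected_target, result
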
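"""Dominant-variance axis (first principal component) and projections.

Near a continuous symmetry-breaking transition the distribution of states
first becomes bimodal along the direction of largest variance, so the
candidate bistable dimension is the top eigenvector of the sample
covariance.  Everything downstream (Landau fit, relevance ranking) works
in the 1-D projection onto this axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import ExpressionGroup

__all__ = ["PrincipalAxis", "principal_axis", "project", "DegenerateAxisWarning"]


class DegenerateAxisWarning(UserWarning):
    """Top two eigenvalues nearly tied; the axis is ill-determined."""


@dataclass(frozen=True)
class PrincipalAxis:
    """First principal component of an expression group.

    Attributes
    ----------
    mean : ndarray, shape (n_genes,)
        Per-gene sample mean (log units).
    loadings : ndarray, shape (n_genes,)
        Unit-norm top eigenvector of the sample covariance.
    lambda1 : float
        Top eigenvalue of the unbiased (n-1 denominator) sample covariance.
    j_nu : float
        Inverse variance along the axis, ``1 / lambda1``.
    """

    mean: np.ndarray
    loadings: np.ndarray
    lambda1: float
    j_nu: float

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.loadings) - 1.0) > 1e-12:
            raise ValueError("loadings must be a unit vector")
        if not self.lambda1 > 0:
            raise ValueError("lambda1 must be positive")
        if abs(self.j_nu * self.lambda1 - 1.0) > 1e-10:
            raise ValueError("j_nu must equal 1/lambda1")

    def flipped(self) -> "PrincipalAxis":
        """Return the same axis with reversed orientation."""
        return PrincipalAxis(
            mean=self.mean,
            loadings=-self.loadings,
            lambda1=self.lambda1,
            j_nu=self.j_nu,
        )


def principal_axis(
    group: ExpressionGroup,
    orient_gene: str | None = None,
    orient_sign: int = 1,
) -> PrincipalAxis:
    """Dominant variance axis of a group, via SVD of the centered matrix.

    The unbiased (n-1) sample covariance convention is used throughout, so
    ``lambda1`` equals the variance of the projected coordinates and
    ``j_nu = 1/lambda1`` is their inverse variance.  The eigenvector sign
    is fixed so its largest-magnitude loading is positive; pass
    ``orient_gene`` to instead require a named gene's loading to have sign
    ``orient_sign``.

    Works unchanged in the high-dimension-low-sample-size regime
    (n_samples < n_genes): only the top singular direction is needed and
    the rank-deficient covariance is never formed.
    """
    x = group.values
    n = x.shape[0]
    mean = x.mean(axis=0)
    centered = x - mean
    # economy SVD: singular values relate to covariance eigenvalues by
    # lambda_k = s_k^2 / (n - 1)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (n - 1)
    lambda1 = float(eigvals[0])
    if lambda1 <= 0:
        raise ValueError(
            f"group {group.group_label!r} has zero total variance; "
            "no principal axis is defined"
        )
    if len(eigvals) > 1 and eigvals[0] - eigvals[1] < 1e-9 * eigvals[0]:
        warnings.warn(
            f"group {group.group_label!r}: top two eigenvalues nearly tied "
            f"({eigvals[0]:.6g} vs {eigvals[1]:.6g}); the bistable axis is "
            "ill-determined",
            DegenerateAxisWarning,
            stacklevel=2,
        )
    nu = vt[0]
    if orient_gene is not None:
        try:
            j = group.gene_ids.index(orient_gene)
        except ValueError:
            raise ValueError(f"orientation gene {orient_gene!r} not in gene_ids")
        ref = nu[j]
        if ref == 0:
            raise ValueError(
                f"orientation gene {orient_gene!r} has zero loading; "
                "cannot orient the axis by it"
            )
        if np.sign(ref) != np.sign(orient_sign):
            nu = -nu
    else:
        # deterministic sign: largest-|loading| entry positive
        if nu[np.argmax(np.abs(nu))] < 0:
            nu = -nu
    return PrincipalAxis(mean=mean, loadings=nu, lambda1=lambda1, j_nu=1.0 / lambda1)


def project(group: ExpressionGroup, axis: PrincipalAxis) -> np.ndarray:
    """Project samples onto the axis: ``y_k = (x_k - mean) . loadings``.

    The result has sample mean zero (up to round-off) when the axis was
    derived from the same group.
    """
    if group.values.shape[1] != axis.loadings.shape[0]:
        raise ValueError(
            f"dimension mismatch: group has {group.values.shape[1]} genes, "
            f"axis has {axis.loadings.shape[0]} loadings"
        )
    return (group.values - axis.mean) @ axis.loadings
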
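"""Per-gene association with the bistable axis and Landau marginals.

Ranks genes by ``s_i = lambda1 * nu_i^2 / Sigma_ii``, the fraction of gene
i's variance that lies along the dominant-variance axis, and by the
Pearson correlation of each gene with the projected coordinate.  When the
axis is the exact top eigenvector of the covariance used, the two agree
exactly: |corr_i| = sqrt(s_i).

Also computes the per-gene marginal density implied by a fitted Landau
model, by integrating the conditional Gaussian of the off-axis residual
against the 1-D Landau weight along the axis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .axis import PrincipalAxis, project
from .data import ExpressionGroup
from .landau import LandauFit

__all__ = [
    "variance_fraction",
    "axis_correlation",
    "relevance_table",
    "gene_marginal",
    "HIGHLIGHT_S",
]

#: default threshold for highlighting strongly axis-aligned genes
HIGHLIGHT_S = 2.0 / 3.0


def variance_fraction(
    axis: PrincipalAxis, gene_variances: np.ndarray
) -> np.ndarray:
    """Fraction ``s_i`` of each gene's variance lying along the axis.

    ``s_i = nu_i^2 / (J_nu * Sigma_ii) = lambda1 * nu_i^2 / Sigma_ii``,
    a number in [0, 1].  Zero-variance genes get NaN (undefined), not 0.
    """
    var = np.asarray(gene_variances, dtype=float)
    s = np.full(var.shape, np.nan)
    ok = var > 0
    s[ok] = axis.lambda1 * axis.loadings[ok] ** 2 / var[ok]
    return s


def axis_correlation(group: ExpressionGroup, axis: PrincipalAxis) -> np.ndarray:
    """Pearson correlation of each gene's expression with the projection.

    Genes with zero variance get NaN.
    """
    y = project(group, axis)
    x = group.values - group.values.mean(axis=0)
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    sx = np.sqrt(np.sum(x**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (x.T @ yc) / (sx * sy)
    corr[sx == 0] = np.nan
    return corr


def relevance_table(
    group: ExpressionGroup,
    axis: PrincipalAxis,
    highlight_s: float = HIGHLIGHT_S,
) -> pd.DataFrame:
    """Per-gene relevance ranking, sorted by descending ``s``.

    Columns: gene_id, s, axis_corr, direction ("up"/"down" in the
    positive-axis state, by the sign of the loading), rank (1 = most
    aligned), highlighted (s > ``highlight_s``).
    """
    gene_var = group.values.var(axis=0, ddof=1)
    s = variance_fraction(axis, gene_var)
    corr = axis_correlation(group, axis)
    direction = np.where(axis.loadings > 0, "up", "down")
    df = pd.DataFrame(
        {
            "gene_id": group.gene_ids,
            "s": s,
            "axis_corr": corr,
            "direction": direction,
            "highlighted": s > highlight_s,
        }
    )
    df = df.sort_values("s", ascending=False, kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def gene_marginal(
    i: int,
    fit: LandauFit,
    axis: PrincipalAxis,
    covariance: np.ndarray,
    x_grid: np.ndarray | None = None,
    n_eta: int = 401,
    n_grid: int = 513,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal density of gene ``i`` under the fitted Landau model.

    The joint model is Gaussian off the axis and Landau-shaped along it;
    marginalizing all other genes gives

        p(x_i) ~ integral N(x_i; mu_i + eta * nu_i, Sigma'_ii)
                          * exp[-(c/2) J (eta-mu_nu)^2 - (d/4) J^2 (eta-mu_nu)^4] d eta

    with Sigma' = Sigma - lambda1 * nu nu^T (the covariance with the
    on-axis variance removed).  The eta integral uses Gauss-Legendre
    quadrature over mu_nu +/- 8 sqrt(lambda1) and the result is normalized
    on the returned grid.  Returns ``(x_grid, density)``.

    If the gene has no residual off-axis variance the marginal is the
    exact pushforward of the 1-D Landau density through
    ``x_i = mu_i + eta * nu_i``.
    """
    nu = axis.loadings
    mu_i = float(axis.mean[i])
    nu_i = float(nu[i])
    sigma_ii = float(covariance[i, i])
    resid = sigma_ii - axis.lambda1 * nu_i**2
    if resid < 0:
        if resid > -1e-10:
            warnings.warn(
                f"gene {i}: residual variance {resid:.2e} clamped to 0",
                stacklevel=2,
            )
            resid = 0.0
        else:
            raise ValueError(
                f"gene {i}: negative residual off-axis variance {resid:.3e}"
            )

    scale = np.sqrt(axis.lambda1)
    if x_grid is None:
        half = 8.0 * scale * max(abs(nu_i), 0.125) + 5.0 * np.sqrt(max(resid, 1e-300))
        x_grid = np.linspace(mu_i - half, mu_i + half, n_grid)

    if resid == 0.0:
        if nu_i == 0.0:
            raise ValueError(
                f"gene {i} has zero loading and zero residual variance; "
                "its marginal is a point mass"
            )
        eta = (x_grid - mu_i) / nu_i
        dens = fit.pdf(eta) / abs(nu_i)
    else:
        nodes, wts = np.polynomial.legendre.leggauss(n_eta)
        eta = fit.mu_nu + 8.0 * scale * nodes
        w_landau = np.exp(
            -(fit.c / 2.0) * fit.j_nu * (eta - fit.mu_nu) ** 2
            - (fit.d / 4.0) * fit.j_nu**2 * (eta - fit.mu_nu) ** 4
        )
        w = wts * w_landau  # overall scale dropped; normalized post hoc
        means = mu_i + eta * nu_i
        z = (x_grid[:, None] - means[None, :]) / np.sqrt(resid)
        gauss = np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi * resid)
        dens = gauss @ w
    norm = np.trapezoid(dens, x_grid)
    if norm <= 0:
        raise ValueError("marginal density vanished on the evaluation grid")
    return x_grid, dens / norm
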
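"""Model / Results interface for the bistability test.

``BistabilityModel`` wraps one expression group; ``fit()`` runs the whole
procedure — principal axis, projection, Gaussian / Landau / mixture fits,
BIC comparison — and returns a ``BistabilityResults`` carrying the
estimates, verdicts, per-gene relevance, and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .axis import PrincipalAxis, principal_axis, project
from .data import ExpressionGroup
from .landau import (
    BIC_THRESHOLD,
    D_MIN,
    GaussianFit1D,
    LandauFit,
    MixtureFit,
    ModelComparison,
    compare_models,
)
from .relevance import HIGHLIGHT_S, gene_marginal, relevance_table

__all__ = ["BistabilityModel", "BistabilityResults"]


class BistabilityModel:
    """Test one group of expression profiles for bistability along PC1.

    Parameters
    ----------
    data : ExpressionGroup or DataFrame or ndarray
        Samples x genes expression values.  DataFrames use their index /
        columns as sample / gene identifiers.
    value_scale : {"log", "raw"}
        ``"raw"`` applies the natural-log transform on construction.
    group_label : str
        Label carried through to reports.

    Examples
    --------
    >>> model = BistabilityModel(df, value_scale="raw", group_label="day15")
    >>> res = model.fit()
    >>> res.is_bistable, res.delta_bic_landau
    """

    def __init__(
        self,
        data,
        value_scale: str = "log",
        group_label: str = "",
        gene_ids: list[str] | None = None,
        sample_ids: list[str] | None = None,
    ) -> None:
        if isinstance(data, ExpressionGroup):
            self.group = data
        elif isinstance(data, pd.DataFrame):
            self.group = ExpressionGroup.from_dataframe(
                data, group_label=group_label, value_scale=value_scale
            )
        else:
            values = np.asarray(data, dtype=float)
            n, g = values.shape
            gene_ids = gene_ids or [f"g{j + 1:03d}" for j in range(g)]
            sample_ids = sample_ids or [f"s{i + 1:03d}" for i in range(n)]
            df = pd.DataFrame(values, index=sample_ids, columns=gene_ids)
            self.group = ExpressionGroup.from_dataframe(
                df, group_label=group_label, value_scale=value_scale
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BistabilityModel":
        return cls(df, **kwargs)

    def fit(
        self,
        threshold: float = BIC_THRESHOLD,
        d_min: float = D_MIN,
        orient_gene: str | None = None,
        orient_sign: int = 1,
        mixture_seed: int = 0,
    ) -> "BistabilityResults":
        """Run the full per-group analysis and return the results object."""
        ax = principal_axis(self.group, orient_gene=orient_gene, orient_sign=orient_sign)
        y = project(self.group, ax)
        gauss, landau, mixture, comparison = compare_models(
            y, ax.j_nu, threshold=threshold, d_min=d_min, mixture_seed=mixture_seed
        )
        return BistabilityResults(
            model=self,
            axis=ax,
            projected=y,
            gaussian=gauss,
            landau=landau,
            mixture=mixture,
            comparison=comparison,
        )


class BistabilityResults:
    """Fitted per-group bistability analysis.

    Attributes
    ----------
    axis : PrincipalAxis
    projected : ndarray
        Sample coordinates along the axis (mean ~ 0).
    gaussian, landau, mixture
        The three fitted 1-D models.
    comparison : ModelComparison
        BIC differences and verdicts.
    """

    def __init__(
        self,
        model: BistabilityModel,
        axis: PrincipalAxis,
        projected: np.ndarray,
        gaussian: GaussianFit1D,
        landau: LandauFit,
        mixture: MixtureFit,
        comparison: ModelComparison,
    ) -> None:
        self.model = model
        self.axis = axis
        self.projected = projected
        self.gaussian = gaussian
        self.landau = landau
        self.mixture = mixture
        self.comparison = comparison

    # -- convenience accessors -------------------------------------------
    @property
    def group(self) -> ExpressionGroup:
        return self.model.group

    @property
    def n_samples(self) -> int:
        return self.group.n_samples

    @property
    def sd_pc1(self) -> float:
        """Standard deviation of expression along the principal component."""
        return float(np.sqrt(self.axis.lambda1))

    @property
    def delta_bic_landau(self) -> float:
        return self.comparison.delta_bic_landau

    @property
    def delta_bic_mixture(self) -> float:
        return self.comparison.delta_bic_mixture

    @property
    def is_bistable(self) -> bool:
        """Strong BIC evidence and a genuinely double-welled fit."""
        return self.comparison.verdict_landau and self.landau.is_bistable

    # -- derived outputs --------------------------------------------------
    def relevance(self, highlight_s: float = HIGHLIGHT_S) -> pd.DataFrame:
        """Per-gene relevance table (fraction of variance along the axis)."""
        return relevance_table(self.group, self.axis, highlight_s=highlight_s)

    def gene_marginal(self, gene: str | int, **kwargs):
        """Marginal density (grid, values) of one gene under the Landau fit."""
        if isinstance(gene, str):
            gene = self.group.gene_ids.index(gene)
        cov = np.cov(self.group.values, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        return gene_marginal(gene, self.landau, self.axis, cov, **kwargs)

    def to_report(self) -> dict:
        """JSON-serializable report of the fit (the flat-file payload)."""
        return {
            "group_label": self.group.group_label,
            "n_samples": int(self.n_samples),
            "n_genes": int(self.group.n_genes),
            "value_convention": "natural-log expression",
            "low_sample_warning": bool(self.n_samples < 10),
            "lambda1": float(self.axis.lambda1),
            "sd_pc1": self.sd_pc1,
            "gaussian": {
                "mean": self.gaussian.mean,
                "variance": self.gaussian.variance,
                "log_likelihood": self.gaussian.log_likelihood,
            },
            "landau": {
                "c": self.landau.c,
                "d": self.landau.d,
                "mu_nu": self.landau.mu_nu,
                "j_nu": self.landau.j_nu,
                "log_likelihood": self.landau.log_likelihood,
                "d_at_floor": bool(self.landau.d <= D_MIN * (1 + 1e-9)),
            },
            "mixture": {
                "loc1": self.mixture.loc1,
                "loc2": self.mixture.loc2,
                "width": self.mixture.width,
                "weight": self.mixture.weight,
                "log_likelihood": self.mixture.log_likelihood,
            },
            "delta_bic_landau": self.delta_bic_landau,
            "delta_bic_mixture": self.delta_bic_mixture,
            "threshold": self.comparison.threshold,
            "verdict_landau": bool(self.comparison.verdict_landau),
            "verdict_mixture": bool(self.comparison.verdict_mixture),
            "is_bistable": bool(self.is_bistable),
            "projected": {
                sid: float(v)
                for sid, v in zip(self.group.sample_ids, self.projected)
            },
        }

    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        c = self.comparison
        lines = [
            "Bistability test (Landau vs Gaussian along PC1)",
            "=" * 55,
            f"group: {self.group.group_label or '<unnamed>'}",
            f"n_samples: {self.n_samples:>6d}    n_genes: {self.group.n_genes}",
            f"sd along PC1:       {self.sd_pc1:>10.4f}",
            f"lambda1 (var PC1):  {self.axis.lambda1:>10.4f}",
            "-" * 55,
            f"Landau fit:   c = {self.landau.c:8.3f}   d = {self.landau.d:8.3f}"
            f"   mu_nu = {self.landau.mu_nu:8.3f}",
            f"Mixture fit:  loc1 = {self.mixture.loc1:.3f}  loc2 = {self.mixture.loc2:.3f}"
            f"  width = {self.mixture.width:.3f}  weight = {self.mixture.weight:.3f}",
            "-" * 55,
            f"dBIC (Landau  vs Gaussian): {c.delta_bic_landau:10.3f}"
            f"   verdict: {'bistable' if c.verdict_landau else 'unimodal'}",
            f"dBIC (mixture vs Gaussian): {c.delta_bic_mixture:10.3f}"
            f"   verdict: {'bimodal' if c.verdict_mixture else 'unimodal'}",
            f"threshold: {c.threshold:g}",
        ]
        if self.n_samples < 10:
            lines.append(
                "WARNING: fewer than 10 samples; model selection unreliable"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<BistabilityResults {self.group.group_label!r}: "
            f"dBIC_landau={self.delta_bic_landau:.2f}, "
            f"bistable={self.is_bistable}>"
        )

    def plot_fit(self, ax=None, bins: int = 20):
        """Histogram of projected data with the fitted densities (optional)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.projected
        ax.hist(y, bins=bins, density=True, alpha=0.4, label="projected data")
        span = np.ptp(y)
        grid = np.linspace(y.min() - span / 4, y.max() + span / 4, 400)
        ax.plot(grid, self.landau.pdf(grid), label="Landau fit")
        ax.plot(grid, self.mixture.pdf(grid), "--", label="mixture fit")
        ax.set_xlabel("projection on PC1 (log units)")
        ax.set_ylabel("density")
        ax.legend()
        return ax
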
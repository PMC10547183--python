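"""Stochastic gene-regulatory-network simulator and detection-power study.

The model is an all-to-all coupled relaxation network with saturating
interactions,

    dx_i/dt = -x_i + alpha * sum_j w_ij tanh(x_j) + xi_i(t),

integrated by Euler-Maruyama from x(0) = 0 with additive white noise of
amplitude ``noise_scale``.  With w_ij = 1 the symmetric state x = 0
destabilizes at the mean-field critical coupling alpha_crit = 1/N_genes:
the drift Jacobian at the origin, -I + alpha W, has top eigenvalue
``alpha N - 1``.  Above threshold the equilibrium ensemble is bistable
along the uniform direction, which is what the Landau fitting pipeline is
designed to detect.  This module doubles as the package's synthetic-data
generator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize as _optimize

from .axis import principal_axis, project
from .data import ExpressionGroup
from .landau import (
    BIC_THRESHOLD,
    delta_bic_landau,
    fit_gaussian_1d,
    fit_landau,
)

__all__ = [
    "SimConfig",
    "Ensemble",
    "DetectionCurve",
    "simulate_trial",
    "sample_ensemble",
    "mean_field_alpha_crit",
    "drift_jacobian_top_eigenvalue",
    "critical_alpha_numeric",
    "detection_power",
    "EquilibrationWarning",
]


class EquilibrationWarning(UserWarning):
    """Simulation time is shorter than the equilibration rule requires."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one ensemble of equilibrium network simulations.

    Defaults integrate to ``t_final = 100`` with Euler step ``dt = 1e-3``
    and unit noise; the slowest relaxation time near criticality scales
    like sqrt(n_genes), so ``t_final`` must exceed ``10 * sqrt(n_genes)``
    (shorter runs are allowed for scaled-down studies but warn).
    """

    n_genes: int
    alpha: float
    n_samples: int = 100
    dt: float = 1e-3
    t_final: float = 100.0
    noise_scale: float = 1.0
    seed: int = 0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if not 0 < self.dt <= 0.01:
            raise ValueError("dt must be in (0, 0.01] for stable integration")
        if self.t_final <= 0:
            raise ValueError("t_final must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.n_genes, self.n_genes):
                raise ValueError("weights must be (n_genes, n_genes)")
            object.__setattr__(self, "weights", w)
        if self.t_final < 10.0 * math.sqrt(self.n_genes):
            warnings.warn(
                f"t_final={self.t_final} is below the equilibration rule "
                f"10*sqrt(n_genes)={10.0 * math.sqrt(self.n_genes):.1f}; "
                "the ensemble may not be fully equilibrated",
                EquilibrationWarning,
                stacklevel=2,
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final / self.dt))


@dataclass(frozen=True)
class Ensemble:
    """Equilibrium states from independent trials (n_samples x n_genes)."""

    states: np.ndarray
    config: SimConfig

    def to_group(self, group_label: str = "") -> ExpressionGroup:
        n, g = self.states.shape
        return ExpressionGroup(
            values=self.states,
            gene_ids=[f"g{j + 1:03d}" for j in range(g)],
            sample_ids=[f"s{i + 1:03d}" for i in range(n)],
            group_label=group_label or f"alpha={self.config.alpha:g}",
        )


@dataclass(frozen=True)
class DetectionCurve:
    """Fraction of simulated studies in which bistability was detected."""

    alpha_values: np.ndarray
    detection_fraction: np.ndarray
    stderr: np.ndarray
    n_trials: int
    n_samples_per_trial: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "alpha": self.alpha_values,
                "detection_fraction": self.detection_fraction,
                "stderr": self.stderr,
            }
        )


def _step_block(
    x: np.ndarray,
    noise: np.ndarray | None,
    alpha: np.floating,
    dt: np.floating,
    sqrt_dt_sigma: np.floating,
    weights: np.ndarray | None,
    n_steps: int,
) -> np.ndarray:
    """Advance all trials through one block of precomputed noise."""
    for k in range(n_steps):
        th = np.tanh(x)
        if weights is None:
            drive = alpha * th.sum(axis=-1, keepdims=True)
        else:
            drive = alpha * (th @ weights.T)
        x += dt * (drive - x)
        if noise is not None:
            x += sqrt_dt_sigma * noise[:, k, :]
    return x


def simulate_trial(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Integrate one trial from x(0) = 0; returns the state at t_final.

    Noise increments are drawn from ``rng`` in step order (one
    ``(n_genes,)`` standard-normal vector per step), so a trial is
    bit-reproducible given the same stream.
    """
    states = _simulate_batch(config, [rng], block=1024)
    return states[0]


def _simulate_batch(
    config: SimConfig, rngs: list[np.random.Generator], block: int | None = None
) -> np.ndarray:
    """Integrate one trial per generator, vectorized across trials.

    Each trial consumes noise only from its own stream, so results are
    independent of how trials are batched.  ``block`` controls how many
    steps of noise are buffered at once (bounded to ~300 MB).
    """
    n_trials = len(rngs)
    g = config.n_genes
    if block is None:
        block = int(max(1, min(1024, 4e7 / max(n_trials * g, 1))))
    # integration runs in single precision: the equilibrium state is O(1)
    # and noise-dominated, so float32 round-off is far below the Monte
    # Carlo and Euler discretization errors, at about half the cost
    f32 = np.float32
    x = np.zeros((n_trials, g), dtype=f32)
    dt = f32(config.dt)
    alpha = f32(config.alpha)
    sqrt_dt_sigma = f32(math.sqrt(config.dt) * config.noise_scale)
    weights = None if config.weights is None else config.weights.astype(f32)
    noisy = config.noise_scale > 0
    noise = np.empty((n_trials, block, g), dtype=f32) if noisy else None
    remaining = config.n_steps
    while remaining > 0:
        b = min(block, remaining)
        if noisy:
            for i, rng in enumerate(rngs):
                noise[i, :b] = rng.standard_normal((b, g), dtype=f32)
        x = _step_block(x, noise, alpha, dt, sqrt_dt_sigma, weights, b)
        if not np.all(np.isfinite(x)) or np.abs(x).max() > 1e6:
            raise FloatingPointError(
                f"simulation blew up (|x| > 1e6) at alpha={config.alpha}, "
                f"dt={config.dt}; parameters are unstable"
            )
        remaining -= b
    return x.astype(np.float64)


def sample_ensemble(config: SimConfig) -> Ensemble:
    """Run ``n_samples`` independent trials with per-trial noise streams.

    Trial i uses the i-th child of ``SeedSequence(seed)``, so identical
    configs reproduce ensembles bitwise and growing ``n_samples`` never
    reshuffles earlier trials.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_samples)
    rngs = [np.random.default_rng(c) for c in children]
    states = _simulate_batch(config, rngs)
    return Ensemble(states=states, config=config)


def mean_field_alpha_crit(n_genes: int) -> float:
    """Critical coupling 1/n_genes of the all-to-all network (mean field)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return 1.0 / n_genes


def drift_jacobian_top_eigenvalue(
    alpha: float, n_genes: int, weights: np.ndarray | None = None
) -> float:
    """Top eigenvalue of the noise-free drift Jacobian at the origin.

    The Jacobian of ``-x + alpha W tanh(x)`` at x = 0 is ``-I + alpha W``;
    its top eigenvalue crossing zero marks the loss of stability of the
    symmetric state.
    """
    w = np.ones((n_genes, n_genes)) if weights is None else np.asarray(weights)
    jac = -np.eye(n_genes) + alpha * w
    if np.allclose(w, w.T):
        return float(np.linalg.eigvalsh(jac)[-1])
    return float(np.max(np.linalg.eigvals(jac).real))


def critical_alpha_numeric(
    n_genes: int, bracket: tuple[float, float] | None = None
) -> float:
    """Numerically locate the coupling where the origin destabilizes.

    Root of the top Jacobian eigenvalue in ``alpha``, by bisection; agrees
    with the mean-field value 1/n_genes for the all-to-all network.
    """
    if bracket is None:
        bracket = (0.0, 2.0 / n_genes + 1e-6)
    return float(
        _optimize.brentq(
            lambda a: drift_jacobian_top_eigenvalue(a, n_genes),
            *bracket,
            xtol=1e-15,
        )
    )


def _detect_once(config: SimConfig, threshold: float) -> bool:
    """One simulated study: ensemble -> PC1 projection -> Landau vs Gaussian."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        group = sample_ensemble(config).to_group()
        ax = principal_axis(group)
        y = project(group, ax)
    gauss = fit_gaussian_1d(y)
    landau = fit_landau(y, ax.j_nu)
    dbic = delta_bic_landau(gauss.log_likelihood, landau.log_likelihood, y.size)
    return dbic > threshold


def detection_power(
    alpha_values: np.ndarray,
    config: SimConfig,
    n_trials: int = 100,
    threshold: float = BIC_THRESHOLD,
) -> DetectionCurve:
    """Detection fraction over a grid of couplings.

    For each alpha, ``n_trials`` independent studies are simulated from
    ``config`` (its ``alpha`` and ``seed`` fields are overridden); each
    study samples an equilibrium ensemble, projects onto PC1, and tests
    Landau vs Gaussian at ``threshold``.  The standard error is the
    binomial sqrt(f(1-f)/n_trials).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    alpha_values = np.asarray(alpha_values, dtype=float)
    master = np.random.SeedSequence(config.seed)
    fractions = np.empty(alpha_values.size)
    for a_idx, alpha in enumerate(alpha_values):
        hits = 0
        for t in range(n_trials):
            # stable per-(alpha, trial) seed, independent of grid ordering
            sub_seed = int(
                np.random.SeedSequence(
                    entropy=master.entropy, spawn_key=(a_idx, t)
                ).generate_state(1)[0]
                % (2**31)
            )
            cfg = replace(config, alpha=float(alpha), seed=sub_seed)
            hits += _detect_once(cfg, threshold)
        fractions[a_idx] = hits / n_trials
    stderr = np.sqrt(fractions * (1.0 - fractions) / n_trials)
    return DetectionCurve(
        alpha_values=alpha_values,
        detection_fraction=fractions,
        stderr=stderr,
        n_trials=n_trials,
        n_samples_per_trial=config.n_samples,
    )
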
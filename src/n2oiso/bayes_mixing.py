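"""Dirichlet-prior Bayesian isotope mixing model with MCMC.

The mixture (the flux-weighted average modern N₂O source) is modelled as
a convex combination of K source endmembers observed on J isotope
tracers (δ¹⁵N_bulk, δ¹⁸O, optionally SP):

    mixture_j ~ Normal( Σ_k p_k·μ_kj , sqrt(Σ_k p_k²·σ_kj² + τ_j²) )
    p ~ Dirichlet(α)

where μ_kj, σ_kj are the per-source tracer mean and SD, τ_j the mixture
measurement SD, and p the source proportions on the simplex.  This is
the fully-specified weighted-variance mixing likelihood; hierarchical
process/residual error structures are deliberately out of scope.

Sampling is random-walk Metropolis on additive-log-ratio coordinates
(z_k = log(p_k/p_K)), i.e. the softmax parameterization of the simplex,
with step-size adaptation during burn-in and independent per-chain
streams spawned from one master seed.  Convergence is monitored with the
Gelman-Rubin potential scale reduction factor and the Geweke z score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .isotope_data import Dataset

__all__ = [
    "MixingProblem",
    "McmcSettings",
    "MixingPosterior",
    "fit_mixing_model",
    "gelman_rubin",
    "geweke",
    "summarize_posterior",
]

QUANTILES = (2.5, 5.0, 25.0, 50.0, 75.0, 95.0, 97.5)

TRACER_FIELDS = ("d15N_bulk", "d18O", "site_preference")


@dataclass
class MixingProblem:
    """Sources, mixture and prior of one mixing analysis.

    ``source_means`` / ``source_sds`` are (K sources × J tracers);
    ``mixture_mean`` / ``mixture_sd`` are length-J; ``prior_alpha`` is the
    length-K Dirichlet concentration (all ones = uniform on the simplex).
    """

    source_names: Sequence[str]
    source_means: np.ndarray
    source_sds: np.ndarray
    mixture_mean: np.ndarray
    mixture_sd: np.ndarray
    prior_alpha: Optional[np.ndarray] = None

    def __post_init__(self):
        self.source_means = np.atleast_2d(np.asarray(self.source_means, dtype=float))
        self.source_sds = np.atleast_2d(np.asarray(self.source_sds, dtype=float))
        self.mixture_mean = np.atleast_1d(np.asarray(self.mixture_mean, dtype=float))
        self.mixture_sd = np.atleast_1d(np.asarray(self.mixture_sd, dtype=float))
        k, j = self.source_means.shape
        if k < 2:
            raise ValueError("need at least 2 sources")
        if len(self.source_names) != k:
            raise ValueError("source_names length must match source_means rows")
        if self.source_sds.shape != (k, j):
            raise ValueError("source_sds shape must match source_means")
        if self.mixture_mean.shape != (j,) or self.mixture_sd.shape != (j,):
            raise ValueError("mixture mean/sd must have one entry per tracer")
        if (self.source_sds < 0).any() or (self.mixture_sd < 0).any():
            raise ValueError("standard deviations must be non-negative")
        if self.prior_alpha is None:
            self.prior_alpha = np.ones(k)
        else:
            self.prior_alpha = np.asarray(self.prior_alpha, dtype=float)
            if self.prior_alpha.shape != (k,) or (self.prior_alpha <= 0).any():
                raise ValueError("prior_alpha must be positive, one per source")
        zero_var = (self.source_sds == 0).all(axis=0) & (self.mixture_sd == 0)
        if zero_var.any():
            raise ValueError("tracer with zero variance everywhere: likelihood degenerate")

    @property
    def n_sources(self) -> int:
        return self.source_means.shape[0]

    @property
    def n_tracers(self) -> int:
        return self.source_means.shape[1]

    @classmethod
    def from_dataset(
        cls,
        dataset: Dataset,
        mixture_mean,
        mixture_sd,
        source_names: Sequence[str] = ("soil", "freshwater", "marine"),
        tracers: Sequence[str] = ("d15N_bulk", "d18O"),
        prior_alpha=None,
    ) -> "MixingProblem":
        """Build a problem from per-category sample statistics of a dataset."""
        means, sds = [], []
        for name in source_names:
            row_m, row_s = [], []
            for tracer in tracers:
                vals = np.asarray(dataset.column(tracer, category=name), dtype=float)
                if vals.size < 2:
                    raise ValueError(f"category {name!r} has <2 values for tracer {tracer!r}")
                row_m.append(float(vals.mean()))
                row_s.append(float(vals.std(ddof=1)))
            means.append(row_m)
            sds.append(row_s)
        return cls(
            source_names=list(source_names),
            source_means=np.array(means),
            source_sds=np.array(sds),
            mixture_mean=mixture_mean,
            mixture_sd=mixture_sd,
            prior_alpha=prior_alpha,
        )


@dataclass
class McmcSettings:
    """Chain configuration.

    Defaults mirror the study configuration: 300 000 iterations, 200 000
    burn-in, thinning 50 (two tracers) or 100 (three tracers), 3 chains.
    """

    chain_length: int = 300_000
    burn_in: int = 200_000
    thinning: int = 50
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for R-hat")

    @classmethod
    def default_for(cls, n_tracers: int, seed: int = 0) -> "McmcSettings":
        return cls(thinning=100 if n_tracers >= 3 else 50, seed=seed)

    @property
    def draws_per_chain(self) -> int:
        return (self.chain_length - self.burn_in) // self.thinning


@dataclass
class MixingPosterior:
    """Retained posterior draws of source proportions plus diagnostics."""

    source_names: Sequence[str]
    chains: np.ndarray  # (n_chains, draws_per_chain, K)
    diagnostics: dict = field(default_factory=dict)

    @property
    def draws(self) -> np.ndarray:
        """All retained draws pooled across chains, shape (n, K)."""
        return self.chains.reshape(-1, self.chains.shape[-1])

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    def quantiles(self, q=QUANTILES) -> np.ndarray:
        return np.percentile(self.draws, q, axis=0)


def _log_target(z: np.ndarray, problem: MixingProblem, prior_only: bool) -> tuple[float, np.ndarray]:
    """Log posterior density in ALR coordinates (up to a constant).

    Includes the log-Jacobian Σ log p of the softmax transform, so the
    prior-only target marginalizes to exactly Dirichlet(α) on p.
    """
    z_full = np.append(z, 0.0)
    z_full -= z_full.max()
    log_p = z_full - np.log(np.exp(z_full).sum())
    p = np.exp(log_p)
    # Dirichlet(alpha) density + ALR Jacobian: sum((alpha-1)*log p) + sum(log p)
    logpost = float(np.dot(problem.prior_alpha, log_p))
    if not prior_only:
        mu = p @ problem.source_means
        var = (p**2) @ (problem.source_sds**2) + problem.mixture_sd**2
        resid = problem.mixture_mean - mu
        logpost += float(-0.5 * np.sum(np.log(2 * np.pi * var) + resid**2 / var))
    return logpost, p


def _run_chain(
    problem: MixingProblem, settings: McmcSettings, rng: np.random.Generator, prior_only: bool
) -> np.ndarray:
    k = problem.n_sources
    dim = k - 1
    z = np.zeros(dim)
    logpost, p = _log_target(z, problem, prior_only)
    step = 0.5
    kept = np.empty((settings.draws_per_chain, k))
    n_kept = 0
    accepted_window = 0
    adapt_every = 200
    for t in range(1, settings.chain_length + 1):
        proposal = z + step * rng.standard_normal(dim)
        logpost_new, p_new = _log_target(proposal, problem, prior_only)
        if np.log(rng.random()) < logpost_new - logpost:
            z, logpost, p = proposal, logpost_new, p_new
            accepted_window += 1
        if t <= settings.burn_in and t % adapt_every == 0:
            rate = accepted_window / adapt_every
            step = float(np.clip(step * np.exp(rate - 0.30), 1e-3, 10.0))
            accepted_window = 0
        if t > settings.burn_in and (t - settings.burn_in) % settings.thinning == 0:
            if n_kept < kept.shape[0]:
                kept[n_kept] = p
                n_kept += 1
    return kept[:n_kept]


def fit_mixing_model(
    problem: MixingProblem,
    settings: Optional[McmcSettings] = None,
    prior_only: bool = False,
) -> MixingPosterior:
    """Sample the posterior of source proportions.

    Runs ``settings.n_chains`` independent random-walk Metropolis chains;
    retains ``(chain_length − burn_in)/thinning`` draws per chain.
    ``prior_only=True`` switches off the likelihood (prior calibration
    runs).  Deterministic for a fixed ``settings.seed``.
    """
    if settings is None:
        settings = McmcSettings.default_for(problem.n_tracers)
    streams = [
        np.random.default_rng(s) for s in np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    ]
    chains = np.stack(
        [_run_chain(problem, settings, rng, prior_only) for rng in streams]
    )

    k = problem.n_sources
    r_hat = {}
    geweke_z = {}
    warn_list = []
    for j, name in enumerate(problem.source_names):
        r = gelman_rubin(chains[:, :, j])
        r_hat[name] = r
        geweke_z[name] = geweke(chains[0, :, j]) if chains.shape[1] >= 100 else float("nan")
        if r > 1.1:
            warn_list.append(f"R-hat for {name} is {r:.3f} (> 1.1): chains may not have converged")
    for message in warn_list:
        warnings.warn(message)
    return MixingPosterior(
        source_names=list(problem.source_names),
        chains=chains,
        diagnostics={"r_hat": r_hat, "geweke_z": geweke_z, "warnings": warn_list},
    )


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R-hat of one scalar parameter.

    ``chains`` is (m chains × n draws).  Uses the classic between/within
    variance formula sqrt(((n−1)/n·W + B/n)/W); degenerate cases (zero
    within- or between-chain variance) are defined as 1.0.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 10:
        raise ValueError("need >= 2 chains of equal length >= 10")
    n = x.shape[1]
    within = float(np.mean(np.var(x, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    if within == 0.0 or b_over_n == 0.0:
        return 1.0
    v_hat = (n - 1) / n * within + b_over_n
    return float(np.sqrt(v_hat / within))


def _spectrum0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via Bartlett-windowed autocovariance."""
    x = x - x.mean()
    n = x.size
    if n < 2:
        return 0.0
    max_lag = min(n - 1, int(round(2 * n ** (1.0 / 3.0))))
    acov = np.correlate(x, x, mode="full")[n - 1 : n + max_lag] / n
    weights = 1.0 - np.arange(1, max_lag + 1) / (max_lag + 1)
    s0 = acov[0] + 2.0 * float(np.dot(weights, acov[1:]))
    return max(s0, 0.0)


def geweke(chain, frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """Geweke convergence z score of one chain.

    Compares the mean of the first ``frac_a`` of the chain with the last
    ``frac_b``, with standard errors from the spectral density at zero.
    A well-mixed stationary chain gives |z| ≲ 2–3.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValueError("chain must have at least 100 draws")
    a = x[: int(frac_a * x.size)]
    b = x[int((1.0 - frac_b) * x.size) :]
    var_a = _spectrum0(a) / a.size
    var_b = _spectrum0(b) / b.size
    denom = np.sqrt(var_a + var_b)
    diff = a.mean() - b.mean()
    if denom == 0.0:
        return 0.0
    return float(diff / denom)


def summarize_posterior(posterior: MixingPosterior) -> pd.DataFrame:
    """Posterior summary table: mean, σ and seven quantiles per source."""
    if posterior.draws.shape[0] < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    q = posterior.quantiles()
    table = pd.DataFrame(
        {
            "mean": posterior.mean(),
            "sd": posterior.sd(),
            **{f"q{qq:g}%": q[i] for i, qq in enumerate(QUANTILES)},
        },
        index=list(posterior.source_names),
    )
    table.index.name = "source"
    return table
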
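"""Parametric model of the annihilation-minus-prompt time-difference spectrum.

The measured time-difference distribution (TDD) in a voxel is described by a
Gaussian detector-resolution kernel convolved with a three-component
exponential decay mixture — para-positronium (pPs), direct annihilation, and
ortho-positronium (oPs) — sitting on a fixed flat background ``b``:

    mu_i = b + N * w * sum_k BR_k * f(t_i; tau_k, sigma, Delta)

where ``f`` is the exponentially modified Gaussian (EMG) density

    f(t; tau, sigma, Delta) = 1/(2 tau) * exp(sigma^2/(2 tau^2) - u/tau)
                              * erfc((sigma/tau - u/sigma) / sqrt(2)),
    u = t - Delta,

``w`` is the histogram bin width, ``t_i`` the bin centre, and ``N`` the total
number of signal events.  The pPs and direct lifetimes are fixed at their
material-independent literature values (125 ps and 388 ps); the oPs lifetime
``tau3`` carries the environmental (pick-off) information and is the imaging
quantity of interest.

The Bayesian fit uses the priors

    tau3  ~ Normal(1.78 ns, 0.8 ns), truncated at 0
    BR    ~ Dirichlet(0.75, 3.1, 1.15)
    sigma ~ Normal(0.1 ns, 0.05 ns), truncated at 0
    Delta ~ Normal(0 ns, 0.5 ns)
    N     ~ Normal(A, 0.1 A),  A = sum over fit-range bins of (y_i - b)

with an independent-Gaussian likelihood per bin whose scale is the Poisson
approximation s_i = sqrt(max(mu_i, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "TAU_PPS",
    "TAU_DIRECT",
    "BIN_WIDTH",
    "FIT_RANGE",
    "HIST_RANGE",
    "BACKGROUND_CUTOFF",
    "LifetimeParams",
    "PriorSpec",
    "emg_density",
    "mixture_density",
    "model_expectation",
    "compute_A",
    "log_prior",
    "log_likelihood",
    "log_posterior",
]

#: fixed para-positronium lifetime (ns)
TAU_PPS = 0.125
#: fixed direct-annihilation lifetime (ns)
TAU_DIRECT = 0.388
#: TDD bin width (ns) — slightly above the scanner pair time resolution
BIN_WIDTH = 0.133
#: fit window for the spectrum model (ns)
FIT_RANGE = (-2.0, 8.0)
#: full histogram window; bins below the cutoff feed the background estimate
HIST_RANGE = (-5.0, 8.0)
#: time differences below this value define the flat-background region (ns)
BACKGROUND_CUTOFF = -2.5

_SQRT2 = float(np.sqrt(2.0))
_LOG_2PI = float(np.log(2.0 * np.pi))


def emg_density(t, tau, sigma, delta=0.0):
    """Exponentially modified Gaussian density, numerically stable.

    This is the density of ``X + Y`` with ``X ~ Normal(delta, sigma^2)`` and
    ``Y ~ Exp(tau)``.  The textbook erfc expression overflows once
    ``sigma/tau`` or ``|t|/sigma`` is large, so two equivalent forms are used:
    for non-negative erfc argument ``z`` the scaled ``erfcx(z) *
    exp(-u^2/(2 sigma^2))`` form, otherwise the direct form (whose exponent is
    then guaranteed negative).

    Parameters
    ----------
    t : array_like
        Evaluation points (ns).
    tau : array_like
        Exponential lifetime (ns), > 0.
    sigma : array_like
        Gaussian resolution width (ns), > 0.
    delta : array_like, optional
        Time offset of the resolution function (ns).

    Returns
    -------
    Density per ns, broadcast over the inputs.
    """
    tau = np.asarray(tau, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(tau <= 0.0) or np.any(sigma <= 0.0):
        raise ValueError("tau and sigma must be strictly positive")
    t = np.asarray(t, dtype=float)
    delta = np.asarray(delta, dtype=float)
    u, tau_b, sig_b = np.broadcast_arrays(t - delta, tau, sigma)
    z = (sig_b / tau_b - u / sig_b) / _SQRT2
    out = np.empty(z.shape, dtype=float)
    pos = z >= 0.0
    # stable branch: erfc(z) = erfcx(z) exp(-z^2) and the exponents combine
    # to exactly -u^2 / (2 sigma^2)
    out[pos] = special.erfcx(z[pos]) * np.exp(-0.5 * (u[pos] / sig_b[pos]) ** 2)
    neg = ~pos
    if neg.any():
        expo = 0.5 * (sig_b[neg] / tau_b[neg]) ** 2 - u[neg] / tau_b[neg]
        out[neg] = special.erfc(z[neg]) * np.exp(expo)
    out /= 2.0 * tau_b
    if out.ndim == 0:
        return float(out)
    return out


def mixture_density(t, tau3, br, sigma, delta=0.0, tau1=TAU_PPS, tau2=TAU_DIRECT):
    """Three-component lifetime mixture density (pPs, direct, oPs).

    ``br`` holds the branching fractions on the unit simplex; its last axis
    has length 3.  All other parameters broadcast against ``t``.
    """
    br = np.asarray(br, dtype=float)
    if br.shape[-1] != 3:
        raise ValueError("br must have 3 components on its last axis")
    f1 = emg_density(t, tau1, sigma, delta)
    f2 = emg_density(t, tau2, sigma, delta)
    f3 = emg_density(t, tau3, sigma, delta)
    if br.ndim == 1:
        return br[0] * f1 + br[1] * f2 + br[2] * f3
    # leading sample axis on br: keep the component axis for broadcasting
    return br[..., 0:1] * f1 + br[..., 1:2] * f2 + br[..., 2:3] * f3


@dataclass
class LifetimeParams:
    """Full parameter vector of the TDD model.

    ``tau1``/``tau2`` are fixed by convention; ``b`` (flat background per bin)
    is fixed from the pre-signal region of the histogram and is not sampled.
    """

    tau3: float
    br: np.ndarray
    sigma: float = 0.1
    delta: float = 0.0
    n_total: float = 0.0
    b: float = 0.0
    tau1: float = TAU_PPS
    tau2: float = TAU_DIRECT

    def __post_init__(self):
        self.br = np.asarray(self.br, dtype=float)
        if self.br.shape != (3,):
            raise ValueError("br must be a 3-vector")
        if not np.isclose(self.br.sum(), 1.0, atol=1e-8):
            raise ValueError("br must sum to 1")
        if np.any(self.br < 0.0):
            raise ValueError("br components must be non-negative")
        for name in ("tau1", "tau2", "tau3", "sigma"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.n_total < 0.0 or self.b < 0.0:
            raise ValueError("n_total and b must be non-negative")

    def is_valid(self) -> bool:
        try:
            LifetimeParams(
                self.tau3, self.br, self.sigma, self.delta,
                self.n_total, self.b, self.tau1, self.tau2,
            )
        except ValueError:
            return False
        return True


@dataclass(frozen=True)
class PriorSpec:
    """Hyper-parameters of the fit priors (see module docstring)."""

    tau3_mean: float = 1.78
    tau3_sd: float = 0.8
    br_alpha: tuple = (0.75, 3.1, 1.15)
    sigma_mean: float = 0.1
    sigma_sd: float = 0.05
    delta_mean: float = 0.0
    delta_sd: float = 0.5
    n_rel_sd: float = 0.1

    def br_prior_mean(self) -> np.ndarray:
        a = np.asarray(self.br_alpha, dtype=float)
        return a / a.sum()


def _fit_bin_mask(hist, fit_range):
    edges = hist.bin_edges
    lo, hi = fit_range
    if lo < edges[0] - 1e-9 or hi > edges[-1] + hist.bin_width + 1e-9:
        raise ValueError("fit_range outside histogram support")
    centers = hist.centers
    sel = (centers >= lo) & (centers <= hi)
    if not sel.any():
        raise ValueError("fit_range contains no bin centers")
    return sel


def model_expectation(hist, params: LifetimeParams, fit_range=FIT_RANGE):
    """Expected counts ``mu_i`` per fit-range bin of ``hist``.

    Bins are those whose centres fall inside ``fit_range``; the bin integral
    is approximated by midpoint density times bin width.
    """
    sel = _fit_bin_mask(hist, fit_range)
    t = hist.centers[sel]
    dens = mixture_density(
        t, params.tau3, params.br, params.sigma, params.delta,
        params.tau1, params.tau2,
    )
    return params.b + params.n_total * hist.bin_width * dens


def compute_A(hist, fit_range=FIT_RANGE) -> float:
    """Background-subtracted total counts in the fit range.

    This is the data-driven centre of the Normal prior on ``N``.  A voxel
    with ``A <= 0`` carries no usable signal and is marked unfittable by the
    caller.
    """
    if hist.background_b is None:
        raise ValueError("background must be estimated before computing A")
    sel = _fit_bin_mask(hist, fit_range)
    return float(np.sum(hist.counts[sel] - hist.background_b))


def _truncnorm0_logpdf(x, mean, sd):
    """Log-density of Normal(mean, sd) truncated to x > 0 (vectorized)."""
    z = (x - mean) / sd
    log_norm = special.log_ndtr(mean / sd)  # mass above zero
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI - log_norm


def _normal_logpdf(x, mean, sd):
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _dirichlet_logpdf(br, alpha):
    alpha = np.asarray(alpha, dtype=float)
    const = special.gammaln(alpha.sum()) - special.gammaln(alpha).sum()
    return const + np.sum((alpha - 1.0) * np.log(br), axis=-1)


def log_prior(tau3, br, sigma, delta, n_total, A, prior: PriorSpec):
    """Sum of the log-prior terms; vectorized over a leading sample axis.

    Assumes the inputs already satisfy the support constraints
    (positivity, simplex); out-of-support states are handled by the caller.
    """
    lp = _truncnorm0_logpdf(np.asarray(tau3, float), prior.tau3_mean, prior.tau3_sd)
    lp = lp + _dirichlet_logpdf(np.asarray(br, float), prior.br_alpha)
    lp = lp + _truncnorm0_logpdf(np.asarray(sigma, float), prior.sigma_mean, prior.sigma_sd)
    lp = lp + _normal_logpdf(np.asarray(delta, float), prior.delta_mean, prior.delta_sd)
    lp = lp + _normal_logpdf(np.asarray(n_total, float), A, prior.n_rel_sd * A)
    return lp


def log_likelihood(y, mu):
    """Gaussian log-likelihood with Poisson-approximate scale per bin.

    ``s_i^2 = max(mu_i, 1)``; the floor avoids a degenerate zero-variance
    bin when the model predicts (near-)zero counts.  Sums over the last axis.
    """
    s2 = np.maximum(mu, 1.0)
    resid = np.asarray(y, float) - mu
    return -0.5 * np.sum(resid * resid / s2 + np.log(s2) + _LOG_2PI, axis=-1)


def log_posterior(params: LifetimeParams, hist, prior: PriorSpec | None = None,
                  fit_range=FIT_RANGE) -> float:
    """Log-posterior of one parameter vector for one histogram.

    Invalid parameter states return ``-inf`` (a rejected MCMC state) rather
    than raising.  Requires a previously estimated background and ``A > 0``.
    """
    prior = prior or PriorSpec()
    A = compute_A(hist, fit_range)
    if A <= 0.0:
        raise ValueError("A <= 0: voxel is unfittable")
    if not params.is_valid():
        return -np.inf
    if params.tau3 <= 0 or params.sigma <= 0 or np.any(params.br <= 0):
        return -np.inf
    mu = model_expectation(hist, params, fit_range)
    sel = _fit_bin_mask(hist, fit_range)
    lp = log_prior(params.tau3, params.br, params.sigma, params.delta,
                   params.n_total, A, prior)
    return float(lp + log_likelihood(hist.counts[sel], mu))
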
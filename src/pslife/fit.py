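"""Posterior sampling for TDD lifetime fits and voxel-wise orchestration.

The six free quantities (tau3, BR1..3 on the simplex, sigma, Delta, N) are
sampled with an affine-invariant ensemble sampler (emcee) in an
unconstrained parameterization:

    theta = (log tau3, z1, z2, log sigma, Delta, log N)

where (z1, z2) is a stick-breaking transform of the branching-fraction
simplex.  The log-Jacobian of the transform is added to the log-posterior so
the chain targets the stated priors in the constrained space.  Walkers are
treated as chains for the split-Rhat / ESS diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
from scipy.special import expit, logit

from . import model as _m
from .histo import TDDHistogram, with_background
from .model import FIT_RANGE, PriorSpec

__all__ = [
    "SamplerConfig",
    "PosteriorSummary",
    "fit_tdd",
    "hdi",
    "sample_prior",
    "fit_volume",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    ``n_ensembles`` independent ensembles are run from different seeds;
    walkers within an ensemble interact, so split-Rhat is computed *across
    ensembles* (each ensemble's pooled draws form one chain) while the
    effective sample size uses the per-walker autocorrelation.  Each fit
    yields ``n_ensembles * n_walkers * n_keep`` posterior draws.
    """

    n_ensembles: int = 4
    n_walkers: int = 16
    n_warmup: int = 600
    n_keep: int = 400
    rhat_max: float = 1.01
    ess_min: float = 400.0


@dataclass
class PosteriorSummary:
    """Point estimates, uncertainties and convergence diagnostics."""

    tau3_mean: float
    tau3_sd: float
    br_mean: np.ndarray
    br_hdi68: np.ndarray  # (3, 2)
    sigma_mean: float
    delta_mean: float
    n_mean: float
    rhat_max: float
    ess_min: float
    n_divergent: int
    converged: bool


def _unpack(theta):
    """Constrained parameters and log-Jacobian from unconstrained theta.

    ``theta`` has shape ``(..., 6)``.  Returns
    (tau3, br[..., 3], sigma, delta, n_total, log_jac).
    """
    th = np.asarray(theta, float)
    tau3 = np.exp(th[..., 0])
    v1 = expit(th[..., 1])
    v2 = expit(th[..., 2])
    br1 = v1
    br2 = (1.0 - v1) * v2
    br3 = (1.0 - v1) * (1.0 - v2)
    br = np.stack((br1, br2, br3), axis=-1)
    sigma = np.exp(th[..., 3])
    delta = th[..., 4]
    n_total = np.exp(th[..., 5])
    with np.errstate(divide="ignore"):
        log_jac = (th[..., 0] + th[..., 3] + th[..., 5]
                   + np.log(v1) + np.log1p(-v1)       # d br1 / d z1
                   + np.log1p(-v1)                     # stick length
                   + np.log(v2) + np.log1p(-v2))       # d v2 / d z2
    return tau3, br, sigma, delta, n_total, log_jac


def _pack(tau3, br, sigma, delta, n_total):
    br = np.asarray(br, float)
    v1 = br[0]
    v2 = br[1] / (1.0 - v1)
    return np.array([np.log(tau3), logit(v1), logit(v2),
                     np.log(sigma), delta, np.log(n_total)])


def _log_prob_batch(theta, y, centers, width, b, A, prior, tau1, tau2,
                    use_likelihood=True):
    """Vectorized log-posterior over a batch of walkers."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        tau3, br, sigma, delta, n_total, log_jac = _unpack(theta)
        lp = _m.log_prior(tau3, br, sigma, delta, n_total, A, prior) + log_jac
        if use_likelihood:
            dens = _m.mixture_density(centers, tau3[..., None], br,
                                      sigma[..., None], delta[..., None],
                                      tau1, tau2)
            mu = b + n_total[..., None] * width * dens
            lp = lp + _m.log_likelihood(y, mu)
    return np.where(np.isfinite(lp), lp, -np.inf)


def _seed_int(seed) -> int:
    if seed is None:
        seed = 0
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))


def _run_ensembles(log_prob, prior, A, config: SamplerConfig, seed, args=()):
    """Run independent ensembles; returns chain (ensemble, walker, step, dim)."""
    ss = np.random.SeedSequence(_seed_int(seed))
    children = ss.spawn(2 * config.n_ensembles)
    chains = []
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    for e in range(config.n_ensembles):
        rng = np.random.default_rng(children[2 * e])
        p0 = _initial_walkers(prior, A, config, rng)
        sampler = emcee.EnsembleSampler(config.n_walkers, p0.shape[1],
                                        log_prob, args=args, vectorize=True,
                                        moves=moves)
        sampler._random = np.random.RandomState(
            int(children[2 * e + 1].generate_state(1)[0] % (2 ** 31)))
        sampler.run_mcmc(p0, config.n_warmup + config.n_keep, progress=False,
                         skip_initial_state_check=True)
        chain = sampler.get_chain(discard=config.n_warmup)  # (step, walker, dim)
        chains.append(np.swapaxes(chain, 0, 1))
    return np.stack(chains)


def _initial_walkers(prior: PriorSpec, A, config: SamplerConfig, rng):
    center = _pack(prior.tau3_mean, prior.br_prior_mean(), prior.sigma_mean,
                   prior.delta_mean, max(A, 1.0))
    p0 = center + 0.05 * rng.standard_normal((config.n_walkers, 6))
    p0[:, 4] = prior.delta_mean + 0.05 * rng.standard_normal(config.n_walkers)
    return p0


def _diagnostics(chain_params: dict, config: SamplerConfig):
    """Max split-Rhat across ensembles and min per-walker-chain ESS."""
    ne, nw, nk = config.n_ensembles, config.n_walkers, config.n_keep

    def _reshape(a, chains):
        return a.reshape((chains, -1) + a.shape[3:])

    rhat_max = -np.inf
    ess_min = np.inf
    for name, a in chain_params.items():
        i_r = az.from_dict(posterior={name: _reshape(a, ne)})
        i_e = az.from_dict(posterior={name: a.reshape((ne * nw, nk) + a.shape[3:])})
        rhat_max = max(rhat_max, float(np.nanmax(az.rhat(i_r)[name].values)))
        ess_min = min(ess_min, float(np.nanmin(az.ess(i_e)[name].values)))
    return rhat_max, ess_min


def _summarize(chain, config: SamplerConfig) -> tuple[PosteriorSummary, dict]:
    tau3, br, sigma, delta, n_total, _ = _unpack(chain)
    rhat_max, ess_min = _diagnostics({
        "tau3": tau3, "br": br, "sigma": sigma, "delta": delta,
        "n_total": n_total,
    }, config)
    flat = {
        "tau3": tau3.reshape(-1),
        "br": br.reshape(-1, 3),
        "sigma": sigma.reshape(-1),
        "delta": delta.reshape(-1),
        "n_total": n_total.reshape(-1),
    }
    br_hdi = np.array([hdi(flat["br"][:, k], 0.68) for k in range(3)])
    summary = PosteriorSummary(
        tau3_mean=float(flat["tau3"].mean()),
        tau3_sd=float(flat["tau3"].std(ddof=1)),
        br_mean=flat["br"].mean(axis=0),
        br_hdi68=br_hdi,
        sigma_mean=float(flat["sigma"].mean()),
        delta_mean=float(flat["delta"].mean()),
        n_mean=float(flat["n_total"].mean()),
        rhat_max=rhat_max,
        ess_min=ess_min,
        n_divergent=0,  # ensemble moves have no divergence concept
        converged=bool(rhat_max < config.rhat_max and ess_min > config.ess_min),
    )
    return summary, flat


def fit_tdd(hist: TDDHistogram, prior: PriorSpec | None = None,
            sampler_config: SamplerConfig | None = None, seed=0,
            fit_range=FIT_RANGE):
    """Sample the lifetime-model posterior for one TDD.

    The histogram must carry a background estimate (``with_background``) and
    a positive background-subtracted signal ``A``.  Returns
    ``(PosteriorSummary, samples)`` where ``samples`` maps parameter names to
    flattened post-warmup draws.  Non-convergence is reported through
    ``summary.converged``, never raised.
    """
    prior = prior or PriorSpec()
    config = sampler_config or SamplerConfig()
    if hist.background_b is None:
        hist = with_background(hist)
    A = _m.compute_A(hist, fit_range)
    if A <= 0:
        raise ValueError("A <= 0: histogram holds no fittable signal")
    sel = _m._fit_bin_mask(hist, fit_range)
    y = hist.counts[sel].astype(float)
    centers = hist.centers[sel]
    chain = _run_ensembles(
        _log_prob_batch, prior, A, config, seed,
        args=(y, centers, hist.bin_width, hist.background_b, A, prior,
              _m.TAU_PPS, _m.TAU_DIRECT))
    summary, flat = _summarize(chain, config)
    if not summary.converged:
        log.warning("fit_tdd: not converged (rhat=%.3f, ess=%.0f)",
                    summary.rhat_max, summary.ess_min)
    return summary, flat


def sample_prior(prior: PriorSpec | None = None, A: float = 1000.0,
                 sampler_config: SamplerConfig | None = None, seed=0):
    """Prior-only sampling through the same MCMC machinery.

    Switches the likelihood off so the chain targets exactly the declared
    priors; used to audit the unconstrained transform and its Jacobian.
    """
    prior = prior or PriorSpec()
    config = sampler_config or SamplerConfig()
    chain = _run_ensembles(
        _log_prob_batch, prior, A, config, seed,
        args=(None, None, None, None, A, prior, _m.TAU_PPS, _m.TAU_DIRECT,
              False))
    _, flat = _summarize(chain, config)
    return flat


def hdi(samples, mass: float = 0.68):
    """Shortest contiguous interval holding ``mass`` of the draws.

    Brute force over the sorted sample: the interval of ``ceil(mass * n)``
    consecutive order statistics with the smallest width.
    """
    x = np.sort(np.asarray(samples, float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def voxel_seed(global_seed, flat_index: int) -> int:
    """Deterministic per-voxel seed below 2**31."""
    ss = np.random.SeedSequence([_seed_int(global_seed), int(flat_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def fit_volume(voxel_hists: dict, grid, prior: PriorSpec | None = None,
               sampler_config: SamplerConfig | None = None, seed=0,
               fit_range=FIT_RANGE, include_nonconverged: bool = False):
    """Voxel-wise posterior fits assembled into a lifetime image.

    Voxels failing background QC or with non-positive signal are masked.
    Non-converged fits are masked by default (set ``include_nonconverged`` to
    keep them).  Returns a :class:`pslife.imaging.LifetimeImage`; the
    per-voxel summaries are available on its ``summaries`` attribute.
    """
    from .imaging import LifetimeImage  # avoid a hard import cycle

    prior = prior or PriorSpec()
    config = sampler_config or SamplerConfig()
    dims = tuple(grid.dims)
    tau3 = np.full(dims, np.nan)
    relsd = np.full(dims, np.nan)
    br3 = np.full(dims, np.nan)
    qc = np.zeros(dims, dtype=bool)
    summaries = {}
    n_qc_fail = n_unfittable = n_nonconv = n_fit = 0
    for idx, h in sorted(voxel_hists.items()):
        if h.qc_pass is None:
            h = with_background(h)
        if not h.qc_pass:
            n_qc_fail += 1
            continue
        if _m.compute_A(h, fit_range) <= 0:
            n_unfittable += 1
            continue
        flat_idx = int(np.ravel_multi_index(idx, dims))
        summary, _ = fit_tdd(h, prior, config,
                             seed=voxel_seed(seed, flat_idx),
                             fit_range=fit_range)
        summaries[idx] = summary
        n_fit += 1
        if not summary.converged:
            n_nonconv += 1
            if not include_nonconverged:
                continue
        tau3[idx] = summary.tau3_mean
        relsd[idx] = summary.tau3_sd / summary.tau3_mean
        br3[idx] = summary.br_mean[2]
        qc[idx] = True
    log.info("fit_volume: fitted=%d qc_fail=%d unfittable=%d nonconverged=%d",
             n_fit, n_qc_fail, n_unfittable, n_nonconv)
    image = LifetimeImage(
        grid=grid, tau3_map=tau3, tau3_relsd_map=relsd, br3_map=br3,
        qc_mask=qc,
        provenance={
            "seed": int(_seed_int(seed)),
            "n_fitted": n_fit,
            "n_qc_fail": n_qc_fail,
            "n_unfittable": n_unfittable,
            "n_nonconverged": n_nonconv,
        },
    )
    image.summaries = summaries
    return image
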
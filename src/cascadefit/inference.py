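"""Negative-binomial log-posterior evaluation and ensemble MCMC.

The count likelihood is NB(mu, phi) in the mean/dispersion parameterization
(variance mu + mu^2/phi).  A response curve f(t) in fit space is mapped to a
per-cell mean through the inverse log-normalization
mu_t = (e^{f(t)} - 1) * M_t / Mtilde, floored at a small epsilon because the
pmf is undefined at mu = 0 while the curves may touch zero.

Sampling uses the affine-invariant ensemble ("stretch move") sampler with
four walkers per parameter.  After the run, iterations before the burn-in
are discarded and the half of the walkers with the lowest acceptance
fraction is pruned — low acceptance is the signature of a walker stuck in an
irrelevant local optimum.  Convergence is summarized by the per-parameter
integrated autocorrelation time and the effective sample size
ESS = M * N / tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy.special import gammaln

from .inflection import _dsig_gate_matrix
from .models import (ParameterVector, PriorSpec, evaluate_family, get_family,
                     initial_guesses)
from .normalization import lognormalize

logger = logging.getLogger(__name__)

__all__ = [
    "nb_log_pmf",
    "log_likelihood",
    "log_posterior",
    "ChainEnsemble",
    "PosteriorSample",
    "DiagnosticsReport",
    "run_ensemble",
    "prune_walkers",
    "diagnostics",
]

MU_FLOOR = 1e-10  # count-space floor for the NB mean


def nb_log_pmf(y, mu, phi):
    """Log pmf of NB(mu, phi): C(y + phi - 1, y) (mu/(mu+phi))^y (phi/(mu+phi))^phi.

    Evaluated with log-gamma arithmetic; vectorized over any argument.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    yf = y.astype(float)
    out = (gammaln(yf + phi) - gammaln(phi) - gammaln(yf + 1.0)
           + yf * (np.log(mu) - np.log(mu + phi))
           + phi * (np.log(phi) - np.log(mu + phi)))
    return float(out) if out.ndim == 0 else out


class _NBLogPosterior:
    """Vectorized log posterior for one gene and family (emcee callable)."""

    def __init__(self, family, counts, umi_totals, size_factor, phi, priors,
                 gate_dt=1.0):
        self.family = get_family(family)
        self.y = np.asarray(counts, dtype=float)
        n = self.y.size
        self.t = np.arange(1, n + 1, dtype=float)
        self.scale = np.asarray(umi_totals, dtype=float) / float(size_factor)
        self.phi = float(phi)
        self.priors = priors
        self.gate_dt = gate_dt
        self.const = (gammaln(self.y + self.phi) - gammaln(self.phi)
                      - gammaln(self.y + 1.0))
        self.const_sum = float(self.const.sum())
        self.log_phi = np.log(self.phi)

    def _support_mask(self, params):
        lp = self.priors.log_prior_matrix(params)
        ok = np.isfinite(lp)
        if self.family.name == "double_sigmoidal" and ok.any():
            ok[ok] &= _dsig_gate_matrix(params[ok], dt=self.gate_dt)
            lp[~ok] = -np.inf
        return lp, ok

    def _mu(self, params):
        f = evaluate_family(self.family, params, self.t)
        return np.maximum(np.expm1(f) * self.scale, MU_FLOOR)

    def log_likelihood_terms(self, params):
        """Per-cell log-likelihood terms, shape (W, N).  No prior, no gate."""
        params = np.atleast_2d(np.asarray(params, dtype=float))
        mu = self._mu(params)
        lmp = np.log(mu + self.phi)
        return (self.const + self.y * (np.log(mu) - lmp)
                + self.phi * (self.log_phi - lmp))

    def log_likelihood(self, params):
        return self.log_likelihood_terms(params).sum(axis=1)

    def __call__(self, params):
        params = np.atleast_2d(np.asarray(params, dtype=float))
        lp, ok = self._support_mask(params)
        out = np.full(params.shape[0], -np.inf)
        if ok.any():
            out[ok] = lp[ok] + self.log_likelihood(params[ok])
        return out


def _posterior_for(td, gene, family, phi, priors=None, gate_dt=1.0):
    y = td.gene_counts(gene)
    if priors is None:
        profile = lognormalize(y, td.umi_totals, td.size_factor)
        priors = PriorSpec.default(family, td.n_cells, float(np.max(profile)))
    return _NBLogPosterior(family, y, td.umi_totals, td.size_factor, phi,
                           priors, gate_dt=gate_dt)


def log_likelihood(pv: ParameterVector, td, gene, phi):
    """Summed NB log likelihood of one gene's counts under curve pv."""
    pv.validate(n_cells=td.n_cells)
    lpost = _posterior_for(td, gene, pv.family, phi)
    return float(lpost.log_likelihood(pv.values[None, :])[0])


def log_posterior(pv: ParameterVector, td, gene, phi, ps: PriorSpec):
    """Log prior + log likelihood; -inf outside the support or (for the
    double sigmoid) when the inflection-existence gate fails."""
    lpost = _posterior_for(td, gene, pv.family, phi, priors=ps)
    return float(lpost(pv.values[None, :])[0])


@dataclass
class ChainEnsemble:
    """Full MCMC output for one gene and family."""

    family: object
    chain: np.ndarray            # (n_iterations, n_walkers, ndim)
    log_prob: np.ndarray         # (n_iterations, n_walkers)
    acceptance_fraction: np.ndarray  # per walker, over all iterations
    burn_in: int
    seed: int
    priors: PriorSpec = None

    def __post_init__(self):
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")

    @property
    def n_iterations(self) -> int:
        return self.chain.shape[0]

    @property
    def n_walkers(self) -> int:
        return self.chain.shape[1]

    @property
    def ndim(self) -> int:
        return self.chain.shape[2]


@dataclass
class PosteriorSample:
    """Post-burn-in draws from the retained (unpruned) walkers."""

    family: object
    draws: np.ndarray            # (n_draws, ndim)
    log_probs: np.ndarray        # (n_draws,)
    retained_walkers: np.ndarray
    mean_params: np.ndarray = field(init=False)

    def __post_init__(self):
        self.family = get_family(self.family)
        self.mean_params = self.draws.mean(axis=0)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean_parameter_vector(self) -> ParameterVector:
        return ParameterVector(self.family, self.mean_params.copy())


def run_ensemble(family, td, gene, phi, priors=None, n_iterations=10_000,
                 burn_in=5_000, seed=0, init=None, gate_dt=1.0) -> ChainEnsemble:
    """Run the affine-invariant ensemble sampler for one gene and family.

    Walkers (four per parameter) start from :func:`models.initial_guesses`;
    the stretch-move scale is the sampler default a = 2.  Acceptance
    fractions cover all iterations including burn-in.  Bit-identical output
    is guaranteed for equal seeds.
    """
    family = get_family(family)
    if not burn_in < n_iterations:
        raise ValueError("burn_in must be smaller than n_iterations")
    y = td.gene_counts(gene)
    profile = lognormalize(y, td.umi_totals, td.size_factor)
    if priors is None:
        priors = PriorSpec.default(family, td.n_cells, float(np.max(profile)))
    lpost = _posterior_for(td, gene, family, phi, priors=priors, gate_dt=gate_dt)
    if init is None:
        init = initial_guesses(family, profile, seed=seed, priors=priors)
    init = np.array(init, dtype=float)

    lp0 = lpost(init)
    if not np.any(np.isfinite(lp0)):
        raise RuntimeError(
            f"all {init.shape[0]} walkers start at log-posterior -inf for "
            f"{family} on gene {gene!r}; review priors and initialization"
        )
    if np.any(~np.isfinite(lp0)):
        # restart failed walkers near the best finite one
        rng = np.random.default_rng(seed + 1)
        best = init[int(np.argmax(lp0))]
        for w in np.where(~np.isfinite(lp0))[0]:
            for _ in range(100):
                cand = best * (1 + 1e-3 * rng.standard_normal(best.size))
                if np.isfinite(lpost(cand[None, :])[0]):
                    init[w] = cand
                    break

    sampler = emcee.EnsembleSampler(
        init.shape[0], family.parameter_count, lpost, vectorize=True,
        moves=emcee.moves.StretchMove(a=2.0),
    )
    sampler.random_state = np.random.RandomState(seed % (2 ** 32)).get_state()
    sampler.run_mcmc(init, n_iterations, skip_initial_state_check=True,
                     store=True, progress=False)
    return ChainEnsemble(
        family=family,
        chain=sampler.get_chain(),
        log_prob=sampler.get_log_prob(),
        acceptance_fraction=sampler.acceptance_fraction.copy(),
        burn_in=burn_in,
        seed=seed,
        priors=priors,
    )


def prune_walkers(ce: ChainEnsemble) -> PosteriorSample:
    """Discard burn-in iterations and the floor(M/2) walkers with the lowest
    acceptance fraction (ties broken by walker index); mean parameters are
    the arithmetic mean over all retained draws."""
    m = ce.n_walkers
    n_keep = int(np.ceil(m / 2))
    # stable sort on descending acceptance keeps lower walker index on ties
    order = np.argsort(-ce.acceptance_fraction, kind="stable")
    retained = np.sort(order[:n_keep])
    post = ce.chain[ce.burn_in:, retained, :]
    lps = ce.log_prob[ce.burn_in:, retained]
    return PosteriorSample(
        family=ce.family,
        draws=post.reshape(-1, ce.ndim),
        log_probs=lps.reshape(-1),
        retained_walkers=retained,
    )


@dataclass
class DiagnosticsReport:
    """Per-parameter autocorrelation diagnostics of a chain ensemble."""

    parameter_names: tuple
    rho: np.ndarray              # (ndim, t_max + 1), rho[:, 0] = 1
    tau: np.ndarray              # integrated autocorrelation time per parameter
    ess: np.ndarray              # effective sample size per parameter
    acceptance_fraction: np.ndarray
    t_max: int
    n_walkers: int
    n_retained_iterations: int


def _autocorrelation(x, t_max):
    """Normalized autocorrelation of a 1-d trace out to lag t_max (FFT)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    nf = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nf)
    acov = np.fft.irfft(f * np.conj(f), nf)[: t_max + 1] / n
    if acov[0] <= 0:
        return None  # constant (stuck) trace
    return acov / acov[0]


def diagnostics(ce: ChainEnsemble, t_max=1000) -> DiagnosticsReport:
    """Autocorrelation function, integrated autocorrelation time and ESS.

    rho_f(tau) is computed per walker on mean-centered post-burn-in traces
    and averaged across walkers; tau_hat is the maximum over window lengths
    T <= t_max of 1 + 2 sum_{tau<=T} <rho_f(tau)>, and
    ESS = M * N_retained / tau_hat.
    """
    post = ce.chain[ce.burn_in:]
    n_post, m, ndim = post.shape
    if n_post <= t_max:
        logger.warning("chain shorter than t_max; reducing %d -> %d",
                       t_max, n_post - 1)
        t_max = n_post - 1
    rho = np.zeros((ndim, t_max + 1))
    tau = np.empty(ndim)
    for j in range(ndim):
        acfs = [a for w in range(m)
                if (a := _autocorrelation(post[:, w, j], t_max)) is not None]
        rho_j = np.mean(acfs, axis=0) if acfs else np.zeros(t_max + 1)
        if acfs:
            rho_j[0] = 1.0
        rho[j] = rho_j
        partial = 1.0 + 2.0 * np.cumsum(rho_j[1:])
        tau[j] = max(1.0, float(partial.max()) if partial.size else 1.0)
    ess = m * n_post / tau
    names = get_family(ce.family).parameter_names
    return DiagnosticsReport(
        parameter_names=names, rho=rho, tau=tau, ess=ess,
        acceptance_fraction=ce.acceptance_fraction.copy(), t_max=t_max,
        n_walkers=m, n_retained_iterations=n_post,
    )
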
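"""Shared helpers for the test suite."""

import numpy as np

import cascadefit as cf
from cascadefit.inference import PosteriorSample, prune_walkers, run_ensemble
from cascadefit.model import GeneFitResult

# reduced MCMC settings used throughout the suite
REDUCED = dict(n_iterations=2000, burn_in=1000, n_subsets=500)


def trajectory_from_specs(specs, n_cells, phi, seed, umi_total=None,
                          include_background=True):
    cfg = cf.SimulationConfig(n_cells=n_cells, phi=phi, gene_specs=specs,
                              seed=seed, umi_total=umi_total)
    cm, pt, truth = cf.make_benchmark_dataset(
        cfg, include_background=include_background)
    return cf.build_trajectory(cm, pt), truth


def posterior_for_family(td, gene, family, phi, seed,
                         n_iterations=2000, burn_in=1000):
    """Fit one family only and return its pruned posterior."""
    ce = run_ensemble(family, td, gene, phi, n_iterations=n_iterations,
                      burn_in=burn_in, seed=seed)
    return prune_walkers(ce)


def fake_fit_result(gene, family, times, signs, dynamic_class=None):
    """GeneFitResult with prescribed inflection samples (for cascade tests)."""
    family = cf.FAMILIES[family] if isinstance(family, str) else family
    times = np.atleast_2d(np.asarray(times, dtype=float))
    if times.shape[0] == 1 and times.shape[1] > 4:
        times = times.T  # passed as a flat sample vector for one locus
    signs = np.broadcast_to(np.atleast_2d(np.asarray(signs, dtype=float)),
                            times.shape).copy()
    n = times.shape[0]
    ps = PosteriorSample(family, np.ones((n, family.parameter_count)),
                         np.zeros(n), retained_walkers=np.array([0]))
    infl = cf.InflectionSample(family, times, signs)
    dc = dynamic_class or cf.classify_dynamics(family, infl)
    return GeneFitResult(gene=gene, family=family, posterior=ps,
                         inflections=infl, dynamic_class=dc)


def point_cloud(center, n=400, spread=1.0, seed=0):
    return center + spread * np.random.default_rng(seed).standard_normal(n)
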
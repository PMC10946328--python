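"""Synthetic pseudotime trajectories generated from known response functions.

The generator inverts the fitting model: a true curve f(t) in log-normalized
fit space is mapped to a per-cell NB mean through the inverse normalization
mu_t = (e^{f(t)} - 1) * M_t / Mtilde and counts are drawn NB(mu_t, phi)
(gamma-Poisson mixture).  Per-cell UMI totals are either constant (clean
oracle tests) or lognormal around a median of 5,000 with sigma_log 0.3,
exercising the size-factor normalization the way droplet scRNA-seq data do.

The benchmark builder emits files in exactly the dialects ``dataio`` reads
(Matrix Market + sidecars, pseudotime TSV) plus a truth table with the
generating family, parameters and closed-form signed inflection loci.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataio import CountMatrix, PseudotimeOrdering
from .models import ParameterVector, evaluate_family

__all__ = [
    "SimulationConfig",
    "simulate_umi_totals",
    "simulate_gene",
    "make_benchmark_dataset",
    "true_inflections",
    "benchmark_gene_specs",
]

DEFAULT_UMI_MEDIAN = 5000
DEFAULT_UMI_SIGMA_LOG = 0.3


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic trajectory."""

    n_cells: int
    phi: float
    gene_specs: list  # (gene_id, ParameterVector true parameters in fit space)
    seed: int = 0
    umi_total: int = None            # constant per-cell total if set
    umi_median: float = DEFAULT_UMI_MEDIAN
    umi_sigma_log: float = DEFAULT_UMI_SIGMA_LOG

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.umi_total is not None and self.umi_total < 100:
            raise ValueError("UMI totals must be >= 100")
        for gene, pv in self.gene_specs:
            pv.validate(n_cells=self.n_cells)


def simulate_umi_totals(cfg: SimulationConfig, rng=None) -> np.ndarray:
    """Per-cell UMI totals M_t: constant, or lognormal with the configured
    median and log-scale sigma, floored at 100."""
    if cfg.umi_total is not None:
        return np.full(cfg.n_cells, int(cfg.umi_total), dtype=np.int64)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    draws = np.exp(np.log(cfg.umi_median)
                   + cfg.umi_sigma_log * rng.standard_normal(cfg.n_cells))
    return np.maximum(np.rint(draws).astype(np.int64), 100)


def _nb_draw(rng, mu, phi):
    """NB(mu, phi) via gamma-Poisson; mu = 0 deterministically yields 0."""
    mu = np.asarray(mu, dtype=float)
    lam = np.zeros_like(mu)
    pos = mu > 0
    lam[pos] = rng.gamma(shape=phi, scale=mu[pos] / phi)
    return rng.poisson(lam).astype(np.int64)


def simulate_gene(cfg: SimulationConfig, pv: ParameterVector, umi_totals,
                  rng) -> np.ndarray:
    """Counts for one gene along t = 1..N from its true fit-space curve."""
    t = np.arange(1, cfg.n_cells + 1, dtype=float)
    f = evaluate_family(pv.family, pv.values[None, :], t)[0]
    size_factor = float(np.median(umi_totals))
    mu = np.expm1(np.maximum(f, 0.0)) * umi_totals / size_factor
    return _nb_draw(rng, mu, cfg.phi)


def true_inflections(pv: ParameterVector):
    """Closed-form signed inflection loci of a true generating curve."""
    name = pv.family.name
    if name == "uniform":
        return []
    if name == "gaussian":
        t0, sigma = pv["t0"], pv["sigma"]
        return [(t0 - sigma, 1), (t0 + sigma, -1)]
    if name == "sigmoidal":
        return [(pv["t0"], 1 if pv["k"] >= 0 else -1)]
    return [
        (pv["t1"], 1 if pv["bmid"] >= pv["bmin"] else -1),
        (pv["t2"], 1 if pv["bmax"] >= pv["bmid"] else -1),
    ]


def make_benchmark_dataset(cfg: SimulationConfig, out_dir=None,
                           include_background=True):
    """Simulate a full trajectory; optionally write .mtx/sidecar/TSV fixtures.

    Returns (CountMatrix, PseudotimeOrdering, truth DataFrame).  Pseudotime
    is emitted as rank/N so rebuilding the trajectory reproduces the
    generating order.  A ``background_total`` filler gene absorbs the UMIs of
    the unmodeled transcriptome so that each cell's column total equals its
    drawn UMI total M_t (as in real data, where modeled genes are a small
    fraction of each cell's library); it carries no truth entry.
    """
    rng = np.random.default_rng(cfg.seed)
    umi_totals = simulate_umi_totals(cfg, rng)
    n = cfg.n_cells
    cell_ids = [f"cell{i:05d}" for i in range(1, n + 1)]
    gene_ids = [g for g, _ in cfg.gene_specs]
    counts = np.vstack([
        simulate_gene(cfg, pv, umi_totals, rng) for _, pv in cfg.gene_specs
    ]) if cfg.gene_specs else np.empty((0, n), dtype=np.int64)
    if include_background:
        background = np.maximum(umi_totals - counts.sum(axis=0), 0)
        counts = np.vstack([counts, background[None, :]])
        gene_ids = gene_ids + ["background_total"]
    cm = CountMatrix(gene_ids, cell_ids, counts)
    pt = PseudotimeOrdering(list(cell_ids), np.arange(1, n + 1) / n)

    rows = []
    for gene, pv in cfg.gene_specs:
        loci = true_inflections(pv)
        rows.append({
            "gene": gene,
            "family": pv.family.name,
            "parameters": ";".join(f"{k}={v:.10g}" for k, v in pv.as_dict().items()),
            "inflection_times": ";".join(f"{t:.10g}" for t, _ in loci),
            "inflection_signs": ";".join(f"{s:+d}" for _, s in loci),
        })
    truth = pd.DataFrame(rows, columns=["gene", "family", "parameters",
                                        "inflection_times", "inflection_signs"])

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        scipy.io.mmwrite(os.path.join(out_dir, "counts.mtx"),
                         scipy.sparse.coo_matrix(cm.counts))
        with open(os.path.join(out_dir, "genes.txt"), "w") as fh:
            fh.write("\n".join(gene_ids) + ("\n" if gene_ids else ""))
        with open(os.path.join(out_dir, "cells.txt"), "w") as fh:
            fh.write("\n".join(cell_ids) + "\n")
        pd.DataFrame({"cell_id": cell_ids, "pseudotime": pt.pseudotime}).to_csv(
            os.path.join(out_dir, "pseudotime.tsv"), sep="\t", index=False)
        truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    return cm, pt, truth


def benchmark_gene_specs(n_per_family, n_cells, seed=0, amplitude=1.5,
                         uniform_only=False):
    """Strong-amplitude generating parameters for family-recovery benchmarks.

    Curves have a peak-to-baseline fit-space difference of at least 1.0.
    Double-sigmoidal genes alternate between stepwise and asymmetric impulse
    shapes so the family is identifiable against the Gaussian.  Switch times
    and widths are fractions of N and slopes scale as 1/N, so the curve
    shapes are invariant to the trajectory length.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = n_cells
    ks = 300.0 / n  # slope scale: per-cell slopes defined at N = 300
    specs = []

    def unif():
        return ParameterVector.from_dict("uniform", b=rng.uniform(0.5, 1.5))

    def gauss():
        return ParameterVector.from_dict(
            "gaussian", a=rng.uniform(amplitude, amplitude + 0.5),
            b=rng.uniform(0.1, 0.4), t0=rng.uniform(0.35 * n, 0.65 * n),
            sigma=rng.uniform(0.06 * n, 0.12 * n))

    def sig():
        sign = 1 if rng.random() < 0.5 else -1
        return ParameterVector.from_dict(
            "sigmoidal", k=sign * rng.uniform(0.04, 0.10) * ks,
            L=rng.uniform(amplitude, amplitude + 0.5),
            t0=rng.uniform(0.3 * n, 0.7 * n), bmin=rng.uniform(0.1, 0.4))

    def dsig(i):
        t1 = rng.uniform(0.2 * n, 0.35 * n)
        t2 = rng.uniform(0.6 * n, 0.8 * n)
        k1 = rng.uniform(0.06, 0.15) * ks
        k2 = rng.uniform(0.06, 0.15) * ks
        lo = rng.uniform(0.1, 0.3)
        if i % 2 == 0:  # stepwise up/down
            mid = lo + amplitude * 0.7
            hi = lo + 2 * amplitude * 0.7
            if i % 4 == 2:
                lo, hi = hi, lo
        else:  # asymmetric impulse with unequal baselines
            mid = lo + amplitude
            hi = lo + 0.5
            if i % 4 == 3:
                lo, mid, hi = mid, lo, mid + 0.5
        return ParameterVector.from_dict(
            "double_sigmoidal", k1=k1, k2=k2, t1=t1, t2=t2,
            bmin=lo, bmid=mid, bmax=hi)

    if uniform_only:
        for i in range(n_per_family):
            specs.append((f"unif{i:03d}", unif()))
        return specs
    for i in range(n_per_family):
        specs.append((f"unif{i:03d}", unif()))
        specs.append((f"gauss{i:03d}", gauss()))
        specs.append((f"sig{i:03d}", sig()))
        specs.append((f"dsig{i:03d}", dsig(i)))
    return specs
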
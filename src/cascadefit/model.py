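"""Model/Results front end for per-gene dynamics fitting.

:class:`GeneDynamicsModel` binds one gene of a pseudotime-ordered trajectory
to the NB likelihood and the four response-function families;
``fit()`` runs the ensemble MCMC for every family, prunes walkers, applies
the subsample-BIC selection, extracts signed inflection points from the
winning posterior, and returns a :class:`GeneDynamicsResults` carrying the
estimates, their uncertainties, diagnostics and a ``summary()`` table.

``fit_trajectory`` is the batch driver used by the CLI: it estimates the
global dispersion once, fits every gene, and hands back serializable
:class:`GeneFitResult` records that the cascade operations consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .dataio import TrajectoryDataset, build_trajectory
from .inference import PosteriorSample, diagnostics, prune_walkers, run_ensemble
from .inflection import InflectionSample, classify_dynamics, extract_inflections
from .models import FAMILIES, PriorSpec, evaluate_family, get_family
from .normalization import estimate_global_dispersion, lognormalize
from .selection import ModelSelection, select_model, subsample_bics

logger = logging.getLogger(__name__)

__all__ = ["GeneDynamicsModel", "GeneDynamicsResults", "GeneFitResult",
           "fit_gene", "fit_trajectory"]

_FAMILY_ORDER = ("uniform", "gaussian", "sigmoidal", "double_sigmoidal")


class GeneDynamicsModel:
    """Bayesian response-curve model for one gene along a trajectory.

    Parameters
    ----------
    trajectory : TrajectoryDataset
        Pseudotime-ordered counts (see :func:`cascadefit.dataio.build_trajectory`).
    gene : str
        Gene id to fit.
    phi : float, optional
        Global NB dispersion.  Estimated from the full trajectory with
        :func:`cascadefit.normalization.estimate_global_dispersion` if omitted.
    prior_config : dict, optional
        Overrides for the prior hyperparameters (see ``PriorSpec.default``).
    """

    def __init__(self, trajectory: TrajectoryDataset, gene, phi=None,
                 prior_config=None):
        self.trajectory = trajectory
        self.gene = gene
        self.counts = trajectory.gene_counts(gene)
        self.profile = lognormalize(self.counts, trajectory.umi_totals,
                                    trajectory.size_factor)
        if phi is None:
            phi = estimate_global_dispersion(trajectory).phi
        self.phi = float(phi)
        self.prior_config = dict(prior_config or {})
        self.priors = {
            name: PriorSpec.default(name, trajectory.n_cells,
                                    float(np.max(self.profile)),
                                    config=self.prior_config)
            for name in _FAMILY_ORDER
        }

    @classmethod
    def from_dataframe(cls, counts, pseudotime, gene, phi=None, **kwargs):
        """Build from a genes x cells DataFrame and a per-cell pseudotime
        Series/dict keyed by cell id."""
        from .dataio import CountMatrix, PseudotimeOrdering

        cm = CountMatrix(list(counts.index.astype(str)),
                         list(counts.columns), counts.to_numpy())
        if isinstance(pseudotime, dict):
            pseudotime = pd.Series(pseudotime)
        pt = PseudotimeOrdering(list(pseudotime.index.astype(str)),
                                pseudotime.to_numpy(float))
        return cls(build_trajectory(cm, pt), gene, phi=phi, **kwargs)

    def fit(self, n_iterations=10_000, burn_in=5_000, n_subsets=10_000,
            drop_frac=0.02, seed=0, keep_chains=False) -> "GeneDynamicsResults":
        """Fit all four families and select the best; deterministic per seed."""
        rng = np.random.default_rng(seed)
        family_seeds = {name: int(rng.integers(2 ** 31))
                        for name in _FAMILY_ORDER}
        subsample_seed = int(rng.integers(2 ** 31))

        ensembles, posteriors, bic_sets = {}, {}, {}
        for name in _FAMILY_ORDER:
            ce = run_ensemble(name, self.trajectory, self.gene, self.phi,
                              priors=self.priors[name],
                              n_iterations=n_iterations, burn_in=burn_in,
                              seed=family_seeds[name])
            ps = prune_walkers(ce)
            bic_sets[name] = subsample_bics(
                ps, self.trajectory, self.gene, self.phi,
                n_subsets=n_subsets, drop_frac=drop_frac, seed=subsample_seed)
            posteriors[name] = ps
            ensembles[name] = ce
        selection = select_model(bic_sets, gene=str(self.gene))
        winner = selection.family.name
        if not keep_chains:
            ensembles = {winner: ensembles[winner]}
        return GeneDynamicsResults(
            model=self, selection=selection, posteriors=posteriors,
            ensembles=ensembles, seed=seed,
            settings={"n_iterations": n_iterations, "burn_in": burn_in,
                      "n_subsets": n_subsets, "drop_frac": drop_frac},
        )


@dataclass
class GeneDynamicsResults:
    """Fit output for one gene: selected family, posterior, inflections."""

    model: GeneDynamicsModel
    selection: ModelSelection
    posteriors: dict
    ensembles: dict
    seed: int
    settings: dict
    inflections: InflectionSample = field(init=False)
    dynamic_class: str = field(init=False)

    def __post_init__(self):
        self.inflections = extract_inflections(self.posterior)
        self.dynamic_class = classify_dynamics(self.family, self.inflections)

    @property
    def family(self):
        return self.selection.family

    @property
    def posterior(self) -> PosteriorSample:
        return self.posteriors[self.family.name]

    @property
    def mean_params(self) -> dict:
        return self.posterior.mean_parameter_vector().as_dict()

    def param_std(self) -> dict:
        return dict(zip(self.family.parameter_names,
                        self.posterior.draws.std(axis=0)))

    def inflection_summary(self):
        """Posterior median, central 95% interval and majority sign per locus."""
        out = []
        for j in range(self.inflections.n_loci):
            times = self.inflections.locus(j)
            lo, med, hi = np.percentile(times, [2.5, 50.0, 97.5])
            sign = 1 if self.inflections.signs[:, j].mean() >= 0 else -1
            out.append({"median": float(med), "lo": float(lo), "hi": float(hi),
                        "sign": sign})
        return out

    def diagnostics(self, t_max=1000):
        """Autocorrelation diagnostics of the winning family's full ensemble."""
        return diagnostics(self.ensembles[self.family.name], t_max=t_max)

    def to_fit_result(self) -> "GeneFitResult":
        return GeneFitResult(
            gene=str(self.model.gene), family=self.family,
            posterior=self.posterior, inflections=self.inflections,
            dynamic_class=self.dynamic_class, branch=self.selection.branch,
            bic_summaries=self.selection.summaries(),
            acceptance_fraction=self.ensembles.get(
                self.family.name).acceptance_fraction
            if self.family.name in self.ensembles else None,
            phi=self.model.phi,
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = []
        bar = "=" * 64
        lines.append(bar)
        lines.append("Gene expression dynamics fit".center(64))
        lines.append(bar)
        lines.append(f"Gene: {self.model.gene}    N cells: "
                     f"{self.model.trajectory.n_cells}    phi: {self.model.phi:.4g}")
        lines.append(f"Best family: {self.family.name}    "
                     f"(selection branch: {self.selection.branch})")
        lines.append(f"Dynamic class: {self.dynamic_class}")
        lines.append("-" * 64)
        lines.append("Subsample BIC  mean [min, max]  (n_sub = "
                     f"{self.selection.sets[self.family.name].n_sub})")
        for name in _FAMILY_ORDER:
            s = self.selection.sets[name]
            lines.append(f"  {name:<17s} {s.mean:12.2f} [{s.min:10.2f}, "
                         f"{s.max:10.2f}]")
        lines.append("-" * 64)
        lines.append("Posterior mean +/- sd")
        stds = self.param_std()
        for name, val in self.mean_params.items():
            lines.append(f"  {name:<6s} {val:12.4f} +/- {stds[name]:.4f}")
        infl = self.inflection_summary()
        if infl:
            lines.append("Inflection points (median [95% CI], sign)")
            for loc in infl:
                sgn = "+" if loc["sign"] > 0 else "-"
                lines.append(f"  t = {loc['median']:8.2f} "
                             f"[{loc['lo']:8.2f}, {loc['hi']:8.2f}]  ({sgn})")
        else:
            lines.append("Inflection points: none (uniform fit)")
        acc = self.ensembles[self.family.name].acceptance_fraction \
            if self.family.name in self.ensembles else None
        if acc is not None:
            lines.append(f"Acceptance fraction: mean {acc.mean():.3f}  "
                         f"min {acc.min():.3f}")
        lines.append(bar)
        return "\n".join(lines)

    def plot(self, ax=None, n_curves=100, seed=0):
        """Scatter the normalized profile and overlay posterior curve draws."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n = self.model.trajectory.n_cells
        t = np.arange(1, n + 1)
        ax.plot(t, self.model.profile, ".", ms=2, color="0.6", label="data")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, self.posterior.n_draws,
                           size=min(n_curves, self.posterior.n_draws))
        curves = evaluate_family(self.family, self.posterior.draws[idx],
                                 t.astype(float))
        ax.plot(t, curves.T, color="C0", alpha=0.05)
        ax.set_xlabel("pseudotime rank t")
        ax.set_ylabel("log-normalized expression")
        ax.set_title(f"{self.model.gene}: {self.family.name} "
                     f"({self.dynamic_class})")
        return ax


@dataclass
class GeneFitResult:
    """Serializable per-gene fit record consumed by the cascade operations."""

    gene: str
    family: object
    posterior: PosteriorSample
    inflections: InflectionSample
    dynamic_class: str
    branch: str = ""
    bic_summaries: dict = field(default_factory=dict)
    acceptance_fraction: np.ndarray = None
    phi: float = float("nan")

    def __post_init__(self):
        self.family = get_family(self.family)

    def inflection_summary(self):
        out = []
        for j in range(self.inflections.n_loci):
            times = self.inflections.locus(j)
            lo, med, hi = np.percentile(times, [2.5, 50.0, 97.5])
            sign = 1 if self.inflections.signs[:, j].mean() >= 0 else -1
            out.append({"median": float(med), "lo": float(lo), "hi": float(hi),
                        "sign": sign})
        return out

    def summary_row(self) -> dict:
        row = {"gene": self.gene, "best_fit": self.family.name,
               "decision_branch": self.branch,
               "dynamic_class": self.dynamic_class,
               "mean_params": ";".join(
                   f"{k}={v:.12g}"
                   for k, v in self.posterior.mean_parameter_vector()
                   .as_dict().items())}
        for fam in _FAMILY_ORDER:
            s = self.bic_summaries.get(fam, {})
            for stat in ("mean", "min", "max"):
                row[f"bic_{fam}_{stat}"] = s.get(stat, float("nan"))
        infl = self.inflection_summary()
        row["n_inflections"] = len(infl)
        row["inflection_medians"] = ";".join(f"{x['median']:.12g}" for x in infl)
        row["inflection_ci_lo"] = ";".join(f"{x['lo']:.12g}" for x in infl)
        row["inflection_ci_hi"] = ";".join(f"{x['hi']:.12g}" for x in infl)
        row["inflection_signs"] = ";".join(f"{x['sign']:+d}" for x in infl)
        if self.acceptance_fraction is not None:
            row["acceptance_mean"] = float(np.mean(self.acceptance_fraction))
            row["acceptance_min"] = float(np.min(self.acceptance_fraction))
        else:
            row["acceptance_mean"] = row["acceptance_min"] = float("nan")
        row["phi"] = self.phi
        return row

    def sample_table(self) -> pd.DataFrame:
        """One row per retained post-burn-in draw: parameters, log posterior,
        inflection times and signs."""
        data = {"draw": np.arange(self.posterior.n_draws)}
        for j, name in enumerate(self.family.parameter_names):
            data[name] = self.posterior.draws[:, j]
        data["log_posterior"] = self.posterior.log_probs
        for j in range(self.inflections.n_loci):
            data[f"inflection_time_{j + 1}"] = self.inflections.times[:, j]
            data[f"inflection_sign_{j + 1}"] = self.inflections.signs[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_tables(cls, row, samples: pd.DataFrame) -> "GeneFitResult":
        """Rebuild from a summary row and a per-gene sample table."""
        family = get_family(str(row["best_fit"]))
        draws = samples[list(family.parameter_names)].to_numpy(float)
        lps = samples["log_posterior"].to_numpy(float) \
            if "log_posterior" in samples else np.zeros(len(samples))
        posterior = PosteriorSample(family, draws, lps,
                                    retained_walkers=np.array([], dtype=int))
        n_loci = {"uniform": 0, "gaussian": 2, "sigmoidal": 1,
                  "double_sigmoidal": 2}[family.name]
        if n_loci:
            times = np.column_stack([
                samples[f"inflection_time_{j + 1}"].to_numpy(float)
                for j in range(n_loci)])
            signs = np.column_stack([
                samples[f"inflection_sign_{j + 1}"].to_numpy(float)
                for j in range(n_loci)])
        else:
            times = np.empty((len(samples), 0))
            signs = np.empty((len(samples), 0))
        inflections = InflectionSample(family, times, signs)
        bic_summaries = {}
        for fam in _FAMILY_ORDER:
            stats = {stat: float(row[f"bic_{fam}_{stat}"])
                     for stat in ("mean", "min", "max")
                     if f"bic_{fam}_{stat}" in row}
            if stats:
                bic_summaries[fam] = stats
        return cls(
            gene=str(row["gene"]), family=family, posterior=posterior,
            inflections=inflections, dynamic_class=str(row["dynamic_class"]),
            branch=str(row.get("decision_branch", "")),
            bic_summaries=bic_summaries,
            phi=float(row.get("phi", float("nan"))),
        )


def fit_gene(trajectory, gene, phi=None, **fit_kwargs) -> GeneDynamicsResults:
    """Convenience wrapper: build and fit a :class:`GeneDynamicsModel`."""
    return GeneDynamicsModel(trajectory, gene, phi=phi).fit(**fit_kwargs)


def fit_trajectory(trajectory, genes=None, phi=None, n_iterations=10_000,
                   burn_in=5_000, n_subsets=10_000, drop_frac=0.02, seed=0,
                   prior_config=None):
    """Fit every gene of a trajectory; returns (results, metadata).

    ``results`` is a list of :class:`GeneFitResult`; ``metadata`` records the
    dispersion estimate, settings and seed for the run-metadata JSON.
    """
    if genes is None:
        genes = list(trajectory.gene_ids)
    if phi is None:
        disp = estimate_global_dispersion(trajectory)
        phi = disp.phi
        bin_report = disp.bin_report
    else:
        bin_report = None
    rng = np.random.default_rng(seed)
    results = []
    for gene in genes:
        gene_seed = int(rng.integers(2 ** 31))
        model = GeneDynamicsModel(trajectory, gene, phi=phi,
                                  prior_config=prior_config)
        res = model.fit(n_iterations=n_iterations, burn_in=burn_in,
                        n_subsets=n_subsets, drop_frac=drop_frac,
                        seed=gene_seed)
        results.append(res.to_fit_result())
        logger.info("fit %s: %s (%s)", gene, res.family.name, res.dynamic_class)
    metadata = {
        "version": __version__, "seed": seed, "phi": float(phi),
        "size_factor": trajectory.size_factor, "n_cells": trajectory.n_cells,
        "n_genes_fit": len(genes), "n_iterations": n_iterations,
        "burn_in": burn_in, "n_subsets": n_subsets, "drop_frac": drop_frac,
    }
    if bin_report is not None:
        metadata["dispersion_bin_report"] = bin_report
    return results, metadata
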
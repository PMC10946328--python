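"""Model selection by BIC at the posterior-mean parameters on random subsets.

Each family is scored with BIC = k ln(n) - 2 ln P(y | <theta>), where <theta>
is the mean over all retained MCMC draws and the maximized likelihood of the
classical BIC is replaced by the likelihood at <theta>.  To reduce the
influence of outliers, the BIC is evaluated on many random subsets of the
cells (by default 10,000 subsets each dropping a random 2%), and a family is
chosen by the branch rules:

* double sigmoidal iff max(BIC_dsig) < min(BIC_unif) and <BIC_dsig> beats
  both the Gaussian and sigmoidal means;
* else sigmoidal iff max(BIC_sig) < min(BIC_unif) and <BIC_sig> < <BIC_gauss>;
* else Gaussian iff max(BIC_gauss) < min(BIC_unif) and <BIC_gauss> < <BIC_sig>;
* else uniform.

The same subset sequence is used for all four families (common random
numbers), so subset-to-subset noise cancels from every comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .inference import _posterior_for
from .models import FAMILIES, ParameterVector, get_family

logger = logging.getLogger(__name__)

__all__ = [
    "SubsampleBICSet",
    "ModelSelection",
    "repair_mean_params",
    "bic_at_mean_params",
    "subsample_bics",
    "select_model",
]


@dataclass
class SubsampleBICSet:
    """BIC values for one family across random cell subsets."""

    family: object
    bics: np.ndarray
    n_sub: int

    @property
    def mean(self) -> float:
        return float(self.bics.mean())

    @property
    def min(self) -> float:
        return float(self.bics.min())

    @property
    def max(self) -> float:
        return float(self.bics.max())

    def summary(self) -> dict:
        return {"mean": self.mean, "min": self.min, "max": self.max}


@dataclass
class ModelSelection:
    """Chosen family with the branch that fired and all four BIC summaries."""

    gene: str
    family: object
    branch: str
    sets: dict = field(default_factory=dict)

    def summaries(self) -> dict:
        return {name: s.summary() for name, s in self.sets.items()}


def repair_mean_params(ps, n_cells=None):
    """Posterior-mean parameters projected onto the family constraint set.

    Means of multimodal posteriors can violate hard constraints (e.g. the
    means of t1 and t2 crossing); such vectors are repaired — inverted switch
    times swapped, positives floored, times clipped — with a logged warning.
    """
    family = get_family(ps.family)
    values = ps.mean_params.copy()
    repaired = False
    kinds_pos = {
        "uniform": [0], "gaussian": [0, 1, 3], "sigmoidal": [1, 3],
        "double_sigmoidal": [0, 1, 4, 5, 6],
    }[family.name]
    for j in kinds_pos:
        if values[j] <= 0:
            values[j] = 1e-6
            repaired = True
    if family.name == "double_sigmoidal" and values[2] >= values[3]:
        values[2], values[3] = values[3], values[2]
        if values[2] >= values[3]:  # equal: nudge apart
            values[3] = values[2] + 1e-6
        repaired = True
    if n_cells is not None and family.name in ("gaussian", "sigmoidal"):
        clipped = np.clip(values[2], 1.0, float(n_cells))
        repaired |= clipped != values[2]
        values[2] = clipped
    if repaired:
        logger.warning("mean parameters of %s repaired onto constraint set", family)
    return ParameterVector(family, values)


def bic_at_mean_params(ps, td, gene, phi, subset=None) -> float:
    """BIC of one family at <theta>: k ln(|subset|) - 2 sum_{t in subset} ln p."""
    pv = repair_mean_params(ps, n_cells=td.n_cells)
    lpost = _posterior_for(td, gene, pv.family, phi)
    terms = lpost.log_likelihood_terms(pv.values[None, :])[0]
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        terms = terms[subset]
    n = terms.size
    k = pv.family.parameter_count
    return float(k * np.log(n) - 2.0 * terms.sum())


def _dropped_indices(n_cells, n_subsets, drop_frac, seed):
    """Indices dropped per subset, shape (n_subsets, n_drop); common across
    families when called with the same seed."""
    n_drop = int(round(drop_frac * n_cells))
    if n_drop == 0:
        return None, n_cells
    rng = np.random.default_rng(seed)
    u = rng.random((n_subsets, n_cells))
    drops = np.argpartition(u, n_drop - 1, axis=1)[:, :n_drop]
    return drops, n_cells - n_drop


def subsample_bics(ps, td, gene, phi, n_subsets=10_000, drop_frac=0.02,
                   seed=0) -> SubsampleBICSet:
    """BIC at <theta> on ``n_subsets`` random subsets each missing a random
    ``drop_frac`` of cells (drawn without replacement, independently per
    subset; deterministic given seed)."""
    pv = repair_mean_params(ps, n_cells=td.n_cells)
    lpost = _posterior_for(td, gene, pv.family, phi)
    terms = lpost.log_likelihood_terms(pv.values[None, :])[0]
    total = terms.sum()
    k = pv.family.parameter_count
    drops, n_sub = _dropped_indices(td.n_cells, n_subsets, drop_frac, seed)
    if drops is None:
        bic_full = k * np.log(n_sub) - 2.0 * total
        return SubsampleBICSet(ps.family, np.full(n_subsets, bic_full), n_sub)
    dropped_ll = terms[drops].sum(axis=1)
    bics = k * np.log(n_sub) - 2.0 * (total - dropped_ll)
    return SubsampleBICSet(ps.family, bics, n_sub)


def select_model(sets, gene="") -> ModelSelection:
    """Apply the selection branches to the four per-family BIC sets.

    ``sets`` maps family names to :class:`SubsampleBICSet` computed on the
    same subset sequence.  The branch order is authoritative: double
    sigmoidal, then sigmoidal, then Gaussian, else uniform.
    """
    missing = set(FAMILIES) - set(sets)
    if missing:
        raise ValueError(f"missing BIC sets for families: {sorted(missing)}")
    dsig = sets["double_sigmoidal"]
    sig = sets["sigmoidal"]
    gauss = sets["gaussian"]
    unif = sets["uniform"]
    if (dsig.max < unif.min and dsig.mean < gauss.mean and dsig.mean < sig.mean):
        chosen, branch = "double_sigmoidal", "double_sigmoidal"
    elif sig.max < unif.min and sig.mean < gauss.mean:
        chosen, branch = "sigmoidal", "sigmoidal"
    elif gauss.max < unif.min and gauss.mean < sig.mean:
        chosen, branch = "gaussian", "gaussian"
    else:
        chosen, branch = "uniform", "uniform_fallthrough"
    return ModelSelection(gene=gene, family=get_family(chosen), branch=branch,
                          sets=dict(sets))
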
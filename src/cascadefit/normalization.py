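"""Log-normalization mapping and global NB dispersion estimation.

Counts y in cell t with UMI total M_t map to fit space via
``ytilde = ln(y * Mtilde / M_t + 1)`` where Mtilde is the dataset median UMI
total; model curves are evaluated in fit space and mapped back through the
inverse before entering the count likelihood.

The global dispersion phi of the NB variance law sigma^2 = mu + mu^2 / phi is
estimated from genes whose mean-variance behaviour tracks the technical
(rather than biological) variability: log10 gene means are split into five
equal bins, a linear log10 mean/log10 variance fit is made per bin, genes in
the top 20th percentile of variance excess over that fit are dropped per bin,
and phi is then fit to the survivors by nonlinear least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "lognormalize",
    "inverse_lognormalize",
    "DispersionEstimate",
    "estimate_global_dispersion",
]


def lognormalize(y, m_t, m_tilde):
    """Map counts to fit space: ln(y * Mtilde / M_t + 1).

    Accepts scalars or arrays; strictly increasing in y and zero iff y = 0.
    """
    m_t = np.asarray(m_t, dtype=float)
    if np.any(m_t <= 0):
        raise ValueError("M_t must be positive")
    if m_tilde <= 0:
        raise ValueError("size factor must be positive")
    return np.log1p(np.asarray(y, dtype=float) * (m_tilde / m_t))


def inverse_lognormalize(ytilde, m_t, m_tilde):
    """Map fit-space values back to count space: (e^ytilde - 1) * M_t / Mtilde."""
    ytilde = np.asarray(ytilde, dtype=float)
    if np.any(ytilde < 0):
        raise ValueError("fit-space values must be nonnegative")
    m_t = np.asarray(m_t, dtype=float)
    if np.any(m_t <= 0):
        raise ValueError("M_t must be positive")
    return np.expm1(ytilde) * (m_t / m_tilde)


@dataclass
class DispersionEstimate:
    """Fitted global dispersion with the per-bin mean-variance fit report."""

    phi: float
    fitted_gene_ids: list
    bin_report: list = field(default_factory=list)  # dicts: bin edges, slope, intercept, n


def _variance_filter(log_mean, variance, n_bins):
    """Per-bin linear fit of log10 variance on log10 mean; drop the top 20th
    percentile of (observed - fit-predicted) variance per bin.  Returns a
    boolean keep mask and the bin report."""
    edges = np.linspace(log_mean.min(), log_mean.max(), n_bins + 1)
    # right-closed last bin
    bin_idx = np.clip(np.digitize(log_mean, edges[1:-1], right=False), 0, n_bins - 1)
    keep = np.zeros(log_mean.size, dtype=bool)
    report = []
    log_var = np.log10(np.maximum(variance, 1e-300))
    for b in range(n_bins):
        sel = np.where(bin_idx == b)[0]
        if sel.size == 0:
            continue
        if sel.size >= 2 and np.ptp(log_mean[sel]) > 0:
            slope, intercept = np.polyfit(log_mean[sel], log_var[sel], 1)
        else:
            slope, intercept = 0.0, float(np.mean(log_var[sel]))
        expected = 10.0 ** (slope * log_mean[sel] + intercept)
        excess = variance[sel] - expected
        cutoff = np.percentile(excess, 80.0)
        keep[sel[excess <= cutoff]] = True
        report.append({
            "bin": b, "lo": float(edges[b]), "hi": float(edges[b + 1]),
            "slope": float(slope), "intercept": float(intercept),
            "n_genes": int(sel.size),
        })
    return keep, report


def estimate_global_dispersion(td, n_bins=5) -> DispersionEstimate:
    """Estimate the global NB dispersion phi from a trajectory dataset.

    Parameters are fit on raw counts: per-gene mean and variance across cells,
    the binned variance-excess filter described in the module docstring, then
    an unconstrained least-squares fit of sigma^2 = mu + mu^2/phi over ln phi
    (initialized at phi = 10; optimizing ln phi keeps phi positive).
    """
    counts = td.counts
    mean = counts.mean(axis=1)
    variance = counts.var(axis=1, ddof=1)
    nonzero = mean > 0
    if nonzero.sum() < 50:
        raise ValueError(
            f"dispersion estimation needs >= 50 genes with nonzero mean "
            f"(got {int(nonzero.sum())})"
        )
    gene_ids = np.asarray(td.gene_ids, dtype=object)[nonzero]
    mean = mean[nonzero]
    variance = variance[nonzero]
    log_mean = np.log10(mean)

    keep, report = _variance_filter(log_mean, variance, n_bins)
    if sum(1 for r in report if r["n_genes"] > 0) < 5 and n_bins == 5:
        logger.warning("fewer than 5 nonempty bins; falling back to 3 bins")
        keep, report = _variance_filter(log_mean, variance, 3)

    mu = mean[keep]
    var = variance[keep]

    def resid(log_phi):
        return var - (mu + mu * mu / np.exp(log_phi))

    sol = least_squares(resid, x0=[np.log(10.0)],
                        bounds=([-10.0], [np.log(1e8)]), method="trf")
    if not sol.success:
        raise RuntimeError(f"dispersion least squares did not converge: {sol.message}")
    phi = float(np.exp(sol.x[0]))
    return DispersionEstimate(phi=phi, fitted_gene_ids=list(gene_ids[keep]),
                              bin_report=report)
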
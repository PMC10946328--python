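"""Inflection points: closed-form second derivatives, signed extraction per
posterior draw, the double-sigmoidal inflection-existence gate, and dynamic
classification.

Inflection loci are read directly off the parameters at every retained draw:
the Gaussian has two, at t0 - sigma (sign +) and t0 + sigma (sign -); the
sigmoid one at t0 with the sign of k; the double sigmoid two, anchored at t1
and t2 with the signs of (bmid - bmin) and (bmax - bmid).  Anchoring the
double sigmoid's loci at t1 and t2 is only sound when the curvature actually
changes sign near both, which is what the gate enforces during sampling:
a proposal is admitted only if f''(t1 - dt) and f''(t1 + dt) differ in sign,
and likewise around t2, for dt = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ParameterVector, get_family

__all__ = [
    "second_derivative",
    "dsig_inflection_gate",
    "InflectionSample",
    "extract_inflections",
    "classify_dynamics",
    "DYNAMIC_CLASSES",
]

DYNAMIC_CLASSES = (
    "state_switch_up", "state_switch_down",
    "transient_up", "transient_down",
    "stepwise_up", "stepwise_down",
    "none",
)


def _sig_curvature_core(x):
    """g(x) = e^-x (e^-x - 1) / (1 + e^-x)^3 written stably as
    s (1 - s)(1 - 2 s) with s = logistic(x)."""
    x = np.asarray(x, dtype=float)
    s = np.empty_like(x)
    pos = x >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    s[~pos] = ex / (1.0 + ex)
    return s * (1.0 - s) * (1.0 - 2.0 * s)


def _dsig_second_derivative_matrix(params, t):
    """f'' of the double sigmoid for params (W, 7) at times t (...,); (W, N)."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k1 = params[:, 0:1]; k2 = params[:, 1:2]
    t1 = params[:, 2:3]; t2 = params[:, 3:4]
    bmin = params[:, 4:5]; bmid = params[:, 5:6]; bmax = params[:, 6:7]
    return (k1 ** 2 * (bmid - bmin) * _sig_curvature_core(k1 * (t - t1))
            + k2 ** 2 * (bmax - bmid) * _sig_curvature_core(k2 * (t - t2)))


def second_derivative(pv: ParameterVector, t):
    """Closed-form f''(t) for the non-uniform families."""
    name = pv.family.name
    t_in = t
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if name == "uniform":
        raise ValueError("uniform family has no second derivative of interest")
    if name == "gaussian":
        a, b, t0, sigma = pv.values
        out = (a / sigma ** 4
               * np.exp(-((t - t0) ** 2) / (2.0 * sigma ** 2))
               * (t - (t0 - sigma)) * (t - (t0 + sigma)))
    elif name == "sigmoidal":
        k, L, t0, bmin = pv.values
        out = k ** 2 * L * _sig_curvature_core(k * (t - t0))
    else:
        out = _dsig_second_derivative_matrix(pv.values[None, :], t)[0]
    return float(out[0]) if np.ndim(t_in) == 0 else out


def _dsig_second_derivative_at(params, t):
    """f'' of the double sigmoid at one per-walker time each: (W,) -> (W,)."""
    k1, k2 = params[:, 0], params[:, 1]
    t1, t2 = params[:, 2], params[:, 3]
    bmin, bmid, bmax = params[:, 4], params[:, 5], params[:, 6]
    return (k1 ** 2 * (bmid - bmin) * _sig_curvature_core(k1 * (t - t1))
            + k2 ** 2 * (bmax - bmid) * _sig_curvature_core(k2 * (t - t2)))


def _dsig_gate_matrix(params, dt=1.0):
    """Vectorized inflection-existence gate over params (W, 7) -> bool (W,)."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    ok = np.ones(params.shape[0], dtype=bool)
    for tc in (params[:, 2], params[:, 3]):
        lo = _dsig_second_derivative_at(params, tc - dt)
        hi = _dsig_second_derivative_at(params, tc + dt)
        ok &= np.sign(lo) * np.sign(hi) < 0
    return ok


def dsig_inflection_gate(pv: ParameterVector, dt=1.0) -> bool:
    """True iff f'' changes sign across both (t1 +/- dt) and (t2 +/- dt)."""
    if pv.family.name != "double_sigmoidal":
        raise ValueError("gate applies to the double-sigmoidal family only")
    return bool(_dsig_gate_matrix(pv.values[None, :], dt=dt)[0])


@dataclass
class InflectionSample:
    """Signed inflection loci per retained posterior draw.

    ``times`` and ``signs`` have shape (n_draws, n_loci) with n_loci 1 for the
    sigmoid, 2 for Gaussian and double sigmoid, 0 for uniform.
    """

    family: object
    times: np.ndarray
    signs: np.ndarray
    gate_dt: float = 1.0

    @property
    def n_loci(self) -> int:
        return self.times.shape[1] if self.times.ndim == 2 else 0

    def locus(self, index) -> np.ndarray:
        """Inflection-time samples of one locus across draws."""
        return self.times[:, index]

    def first_times(self) -> np.ndarray:
        """Per-draw earliest inflection time (the cascade-ordering key)."""
        return self.times.min(axis=1)


def extract_inflections(ps) -> InflectionSample:
    """Family-specific signed inflection loci for every retained draw of a
    :class:`cascadefit.inference.PosteriorSample`."""
    family = get_family(ps.family)
    draws = ps.draws
    n = draws.shape[0]
    if family.name == "uniform":
        return InflectionSample(family, np.empty((n, 0)), np.empty((n, 0)))
    if family.name == "gaussian":
        t0, sigma = draws[:, 2], draws[:, 3]
        times = np.column_stack([t0 - sigma, t0 + sigma])
        signs = np.tile([1.0, -1.0], (n, 1))
    elif family.name == "sigmoidal":
        times = draws[:, 2:3].copy()
        signs = np.where(draws[:, 0:1] >= 0, 1.0, -1.0)
    else:
        times = draws[:, 2:4].copy()
        signs = np.column_stack([
            np.where(draws[:, 5] - draws[:, 4] >= 0, 1.0, -1.0),
            np.where(draws[:, 6] - draws[:, 5] >= 0, 1.0, -1.0),
        ])
    return InflectionSample(family, times, signs)


def classify_dynamics(family, inflections: InflectionSample = None) -> str:
    """Dynamic class from winning family and inflection signs.

    Accepts either (family, InflectionSample) or a single fit-result object
    exposing ``.family`` and ``.inflections``.
    """
    if inflections is None:
        inflections = family.inflections
        family = family.family
    name = get_family(family).name
    if name == "uniform":
        return "none"
    if name == "gaussian":
        return "transient_up"
    # majority sign per locus across draws
    mean_signs = inflections.signs.mean(axis=0)
    signs = tuple(1 if s >= 0 else -1 for s in mean_signs)
    if name == "sigmoidal":
        return "state_switch_up" if signs[0] > 0 else "state_switch_down"
    return {
        (1, -1): "transient_up",
        (-1, 1): "transient_down",
        (1, 1): "stepwise_up",
        (-1, -1): "stepwise_down",
    }[signs]
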
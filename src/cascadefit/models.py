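"""The four response-function families, their constraints, priors, and
walker initialization.

Expression along the trajectory (in log-normalized fit space) is modeled by
one of four families:

* ``uniform``           f(t) = b                                    (no dynamics)
* ``gaussian``          f(t) = a * exp(-(t - t0)^2 / (2 sigma^2)) + b   (impulse)
* ``sigmoidal``         f(t) = L / (1 + exp(-k (t - t0))) + bmin    (state switch)
* ``double_sigmoidal``  f(t) = bmin + (bmid - bmin) / (1 + exp(-k1 (t - t1)))
                               + (bmax - bmid) / (1 + exp(-k2 (t - t2)))

The double sigmoid models asymmetric impulses and stepwise up/down patterns.
Level parameters are positive; the double sigmoid additionally requires
k1, k2 > 0 and 1 <= t1 < t2 <= N.  The single sigmoid's slope k may take
either sign (down-regulating state switches are fit with k < 0).

Priors: level/amplitude parameters are uniform on (0.01, 2 * max ytilde) and
switch times uniform on (1, N) — uninformative but keeping parameters in
interpretable ranges; slopes carry a zero-mode folded-normal prior with
variance 0.1 (large slopes change the curve very little), and the Gaussian
width sigma a zero-mode folded normal with variance N/10 (discourages
degenerate flat fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ModelFamily",
    "FAMILIES",
    "get_family",
    "ParameterVector",
    "PriorSpec",
    "evaluate_model",
    "folded_normal_logpdf",
    "log_prior",
    "initial_guesses",
]


@dataclass(frozen=True)
class ModelFamily:
    name: str
    parameter_names: tuple

    @property
    def parameter_count(self) -> int:
        return len(self.parameter_names)

    @property
    def n_walkers(self) -> int:
        # ensemble size: four walkers per parameter
        return 4 * self.parameter_count

    def __str__(self):
        return self.name


UNIFORM = ModelFamily("uniform", ("b",))
GAUSSIAN = ModelFamily("gaussian", ("a", "b", "t0", "sigma"))
SIGMOIDAL = ModelFamily("sigmoidal", ("k", "L", "t0", "bmin"))
DOUBLE_SIGMOIDAL = ModelFamily(
    "double_sigmoidal", ("k1", "k2", "t1", "t2", "bmin", "bmid", "bmax"))

FAMILIES = {f.name: f for f in (UNIFORM, GAUSSIAN, SIGMOIDAL, DOUBLE_SIGMOIDAL)}


def get_family(family) -> ModelFamily:
    if isinstance(family, ModelFamily):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown model family {family!r}") from None


@dataclass
class ParameterVector:
    """Named parameters of one family, stored as an array in declaration order."""

    family: ModelFamily
    values: np.ndarray

    def __post_init__(self):
        self.family = get_family(self.family)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.family.parameter_count,):
            raise ValueError(
                f"{self.family} expects {self.family.parameter_count} parameters, "
                f"got shape {self.values.shape}"
            )

    @classmethod
    def from_dict(cls, family, **params):
        family = get_family(family)
        try:
            values = [params[name] for name in family.parameter_names]
        except KeyError as exc:
            raise ValueError(f"missing parameter {exc} for family {family}") from None
        return cls(family, np.array(values, dtype=float))

    def as_dict(self) -> dict:
        return dict(zip(self.family.parameter_names, self.values.tolist()))

    def __getitem__(self, name):
        return float(self.values[self.family.parameter_names.index(name)])

    def validate(self, n_cells=None):
        """Raise ValueError naming the offending parameter if a family
        constraint is violated."""
        p = self.as_dict()
        name = self.family.name
        if name == "uniform":
            if p["b"] <= 0:
                raise ValueError("uniform: b must be > 0")
        elif name == "gaussian":
            for key in ("a", "b", "sigma"):
                if p[key] <= 0:
                    raise ValueError(f"gaussian: {key} must be > 0")
            if n_cells is not None and not (1 <= p["t0"] <= n_cells):
                raise ValueError("gaussian: t0 must lie in [1, N]")
        elif name == "sigmoidal":
            for key in ("L", "bmin"):
                if p[key] <= 0:
                    raise ValueError(f"sigmoidal: {key} must be > 0")
            if p["k"] == 0:
                raise ValueError("sigmoidal: k must be nonzero")
            if n_cells is not None and not (1 <= p["t0"] <= n_cells):
                raise ValueError("sigmoidal: t0 must lie in [1, N]")
        else:
            for key in ("bmin", "bmid", "bmax", "k1", "k2"):
                if p[key] <= 0:
                    raise ValueError(f"double_sigmoidal: {key} must be > 0")
            if not p["t1"] < p["t2"]:
                raise ValueError("double_sigmoidal: requires t1 < t2")
            if n_cells is not None and not (1 <= p["t1"] and p["t2"] <= n_cells):
                raise ValueError("double_sigmoidal: t1, t2 must lie in [1, N]")


# ---------------------------------------------------------------------------
# Evaluation (vectorized kernels accept params with shape (..., ndim))
# ---------------------------------------------------------------------------

def _sigmoid(x):
    # numerically stable logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def evaluate_family(family, params, t):
    """Evaluate f(t) for a batch of parameter vectors.

    ``params`` has shape (..., ndim) and ``t`` shape (N,); returns (..., N).
    No constraint checking (MCMC hot path; priors gate the support).
    """
    family = get_family(family)
    params = np.asarray(params, dtype=float)
    t = np.asarray(t, dtype=float)
    p = params[..., :, None]  # broadcast each parameter over t
    if family.name == "uniform":
        return np.broadcast_to(p[..., 0, :], params.shape[:-1] + t.shape).copy()
    if family.name == "gaussian":
        a, b, t0, sigma = p[..., 0, :], p[..., 1, :], p[..., 2, :], p[..., 3, :]
        return a * np.exp(-((t - t0) ** 2) / (2.0 * sigma ** 2)) + b
    if family.name == "sigmoidal":
        k, L, t0, bmin = p[..., 0, :], p[..., 1, :], p[..., 2, :], p[..., 3, :]
        return L * _sigmoid(k * (t - t0)) + bmin
    k1, k2 = p[..., 0, :], p[..., 1, :]
    t1, t2 = p[..., 2, :], p[..., 3, :]
    bmin, bmid, bmax = p[..., 4, :], p[..., 5, :], p[..., 6, :]
    return (bmin + (bmid - bmin) * _sigmoid(k1 * (t - t1))
            + (bmax - bmid) * _sigmoid(k2 * (t - t2)))


def evaluate_model(pv: ParameterVector, t, n_cells=None):
    """Evaluate one validated parameter vector at time(s) t."""
    pv.validate(n_cells=n_cells)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = evaluate_family(pv.family, pv.values[None, :], t_arr)[0]
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def folded_normal_logpdf(x, mu, sigma2):
    """Log density of the folded normal |Z|, Z ~ N(mu, sigma2), support x >= 0."""
    x = np.asarray(x, dtype=float)
    base = -0.5 * np.log(2.0 * np.pi * sigma2)
    a = -((x - mu) ** 2) / (2.0 * sigma2)
    b = -((x + mu) ** 2) / (2.0 * sigma2)
    out = base + np.logaddexp(a, b)
    return np.where(x >= 0, out, -np.inf)


@dataclass
class PriorSpec:
    """Prior hyperparameters for one family, scaled to the data.

    ``amp_lo``/``amp_hi`` bound all level and amplitude parameters
    (b, bmin, bmid, bmax, a, L); switch times are uniform on (1, N); slopes
    carry a folded-normal(0, slope_variance) prior (applied to |k| for the
    sign-free sigmoid slope) and the Gaussian width a
    folded-normal(0, sigma_variance).
    """

    family: ModelFamily
    n_cells: int
    amp_lo: float = 0.01
    amp_hi: float = 1.0
    slope_variance: float = 0.1
    sigma_variance: float = field(default=None)

    def __post_init__(self):
        self.family = get_family(self.family)
        if self.sigma_variance is None:
            self.sigma_variance = self.n_cells / 10.0

    @classmethod
    def default(cls, family, n_cells, max_expr, config=None):
        cfg = dict(config or {})
        amp_lo = float(cfg.get("amp_lo", 0.01))
        amp_hi = float(cfg.get("amp_hi_factor", 2.0)) * float(max_expr)
        amp_hi = max(amp_hi, float(cfg.get("amp_hi_min", 1.0)))
        return cls(
            family=family, n_cells=n_cells, amp_lo=amp_lo, amp_hi=amp_hi,
            slope_variance=float(cfg.get("slope_variance", 0.1)),
            sigma_variance=cfg.get("sigma_variance",
                                   n_cells / float(cfg.get("sigma_variance_divisor", 10.0))),
        )

    def _kinds(self):
        """Per-parameter prior kind in declaration order."""
        n = self.family.name
        if n == "uniform":
            return ("amp",)
        if n == "gaussian":
            return ("amp", "amp", "time", "width")
        if n == "sigmoidal":
            return ("slope_signfree", "amp", "time", "amp")
        return ("slope", "slope", "time", "time", "amp", "amp", "amp")

    def log_prior_matrix(self, values):
        """Vectorized log prior over rows of ``values`` with shape (W, ndim)."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        logp = np.zeros(values.shape[0])
        for j, kind in enumerate(self._kinds()):
            x = values[:, j]
            if kind == "amp":
                ok = (x > self.amp_lo) & (x < self.amp_hi)
                logp += np.where(ok, -np.log(self.amp_hi - self.amp_lo), -np.inf)
            elif kind == "time":
                ok = (x >= 1.0) & (x <= self.n_cells)
                logp += np.where(ok, -np.log(max(self.n_cells - 1.0, 1e-12)), -np.inf)
            elif kind == "width":
                logp += folded_normal_logpdf(x, 0.0, self.sigma_variance)
            elif kind == "slope":
                logp += folded_normal_logpdf(x, 0.0, self.slope_variance)
            else:  # slope_signfree: folded-normal mass split over both signs
                logp += folded_normal_logpdf(np.abs(x), 0.0,
                                             self.slope_variance) - np.log(2.0)
        if self.family.name == "double_sigmoidal":
            logp = np.where(values[:, 2] < values[:, 3], logp, -np.inf)
        return logp

    def perturbation_scales(self, frac=0.01):
        """Per-parameter noise scale for least-squares-seeded walkers:
        ``frac`` of each parameter's prior range (4 sd for folded priors)."""
        scales = []
        for kind in self._kinds():
            if kind == "amp":
                scales.append(frac * (self.amp_hi - self.amp_lo))
            elif kind == "time":
                scales.append(frac * (self.n_cells - 1.0))
            elif kind == "width":
                scales.append(frac * 4.0 * np.sqrt(self.sigma_variance))
            else:
                scales.append(frac * 4.0 * np.sqrt(self.slope_variance))
        return np.asarray(scales)


def log_prior(pv: ParameterVector, ps: PriorSpec):
    """Log prior density of one parameter vector (-inf out of support)."""
    return float(ps.log_prior_matrix(pv.values[None, :])[0])


# ---------------------------------------------------------------------------
# Initial guesses
# ---------------------------------------------------------------------------

def _gauss_f(t, a, b, t0, sigma):
    return a * np.exp(-((t - t0) ** 2) / (2.0 * sigma ** 2)) + b


def _sig_f(t, k, L, t0, bmin):
    return L / (1.0 + np.exp(-np.clip(k * (t - t0), -500, 500))) + bmin


def _clip_into_support(family, values, ps):
    """Project walker start points into the prior support."""
    eps = 1e-6
    kinds = ps._kinds()
    for j, kind in enumerate(kinds):
        if kind == "amp":
            lo = ps.amp_lo * (1 + eps)
            hi = ps.amp_hi * (1 - eps)
            values[:, j] = np.clip(values[:, j], lo, hi)
        elif kind == "time":
            values[:, j] = np.clip(values[:, j], 1.0, float(ps.n_cells))
        elif kind == "width":
            values[:, j] = np.maximum(np.abs(values[:, j]), 1e-3)
        elif kind == "slope":
            values[:, j] = np.maximum(np.abs(values[:, j]), 1e-4)
        else:  # sign-free slope: keep sign, floor magnitude
            sign = np.where(values[:, j] >= 0, 1.0, -1.0)
            values[:, j] = sign * np.maximum(np.abs(values[:, j]), 1e-4)
    if get_family(family).name == "double_sigmoidal":
        t1 = np.minimum(values[:, 2], values[:, 3])
        t2 = np.maximum(values[:, 2], values[:, 3])
        too_close = t2 - t1 < 4.0
        t2[too_close] = np.minimum(t1[too_close] + 4.0, float(ps.n_cells))
        t1[too_close] = np.maximum(t2[too_close] - 4.0, 1.0)
        values[:, 2], values[:, 3] = t1, t2
    return values


def _gaussian_seed(t, profile):
    lo, hi = float(np.min(profile)), float(np.max(profile))
    t0 = float(t[int(np.argmax(profile))])
    return np.array([max(hi - lo, 0.05), max(lo, 0.02), t0, len(t) / 10.0])


def _sigmoid_seed(t, profile):
    lo, hi = float(np.min(profile)), float(np.max(profile))
    n = len(t)
    # rising or falling: compare means of the first and last thirds
    rising = profile[: n // 3].mean() <= profile[-(n // 3):].mean()
    k0 = (10.0 / n) if rising else (-10.0 / n)
    return np.array([k0, max(hi - lo, 0.05), n / 2.0, max(lo, 0.02)])


def initial_guesses(family, profile, n_walkers=None, seed=0, priors=None):
    """Starting positions for the ensemble walkers, shape (n_walkers, ndim).

    Gaussian and sigmoidal walkers start from a nonlinear least-squares point
    fit to the log-normalized profile, perturbed per walker with Gaussian
    noise at 1% of each parameter's prior range; uniform walkers are drawn
    uniformly over (0.01, max ytilde); double-sigmoidal walkers are drawn to
    cover step-up, step-down, impulse-up and impulse-down shapes with
    randomized t1 < t2.  All returned vectors lie in the prior support (and,
    for the double sigmoid, pass the inflection-existence gate).
    Deterministic given ``seed``.
    """
    from .inflection import _dsig_gate_matrix

    family = get_family(family)
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    t = np.arange(1, n + 1, dtype=float)
    if n_walkers is None:
        n_walkers = family.n_walkers
    if priors is None:
        priors = PriorSpec.default(family, n, float(np.max(profile)))
    rng = np.random.default_rng(seed)

    if family.name == "uniform":
        hi = max(float(np.max(profile)), priors.amp_lo + 0.01)
        values = rng.uniform(priors.amp_lo, hi, size=(n_walkers, 1))
        return _finalize(family, values, priors, rng)

    if family.name in ("gaussian", "sigmoidal"):
        f = _gauss_f if family.name == "gaussian" else _sig_f
        seed_fn = _gaussian_seed if family.name == "gaussian" else _sigmoid_seed
        p0 = seed_fn(t, profile)
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(f, t, profile, p0=p0, maxfev=2000)
            if not np.all(np.isfinite(popt)):
                raise RuntimeError("non-finite least-squares fit")
        except Exception:
            popt = p0  # moment-based heuristic fallback
        scales = priors.perturbation_scales()
        values = popt[None, :] + rng.standard_normal((n_walkers, popt.size)) * scales
        if family.name == "sigmoidal":
            # keep every walker on the fitted slope sign
            sign = 1.0 if popt[0] >= 0 else -1.0
            values[:, 0] = sign * np.abs(values[:, 0])
        return _finalize(family, values, priors, rng)

    # double sigmoidal: walkers cover qualitatively distinct shapes
    q10, q50, q90 = np.quantile(profile, [0.1, 0.5, 0.9])
    lo = max(float(q10), priors.amp_lo + 0.01)
    hi = max(float(q90), lo + 0.1)
    mid = max(float(q50), priors.amp_lo + 0.01)
    shapes = [
        (lo, mid, hi),   # step up
        (hi, mid, lo),   # step down
        (lo, hi, lo),    # impulse up
        (hi, lo, hi),    # impulse down
    ]
    values = np.empty((n_walkers, 7))
    for w in range(n_walkers):
        bmin, bmid, bmax = shapes[w % len(shapes)]
        for _ in range(200):
            t1 = rng.uniform(0.10 * n, 0.45 * n)
            t2 = rng.uniform(0.55 * n, 0.90 * n)
            k1 = rng.uniform(0.02, 0.3)
            k2 = rng.uniform(0.02, 0.3)
            noise = rng.standard_normal(3) * 0.02 * (priors.amp_hi - priors.amp_lo)
            cand = np.array([k1, k2, t1, t2,
                             bmin + noise[0], bmid + noise[1], bmax + noise[2]])
            cand = _clip_into_support(family, cand[None, :], priors)
            if (np.isfinite(priors.log_prior_matrix(cand)[0])
                    and bool(_dsig_gate_matrix(cand)[0])):
                values[w] = cand[0]
                break
        else:
            # wide separation always passes the gate for moderate slopes
            values[w] = [0.1, 0.1, 0.2 * n, 0.8 * n, lo, mid, hi]
    return values


def _finalize(family, values, priors, rng):
    values = _clip_into_support(family, values, priors)
    # resample any walker that still fell outside the prior support
    bad = ~np.isfinite(priors.log_prior_matrix(values))
    for w in np.where(bad)[0]:
        for _ in range(100):
            jitter = values[w] * (1 + 0.01 * rng.standard_normal(values.shape[1]))
            cand = _clip_into_support(family, jitter[None, :], priors)
            if np.isfinite(priors.log_prior_matrix(cand)[0]):
                values[w] = cand[0]
                break
    return values
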
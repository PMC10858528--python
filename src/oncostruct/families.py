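"""Parametric survival families for extrapolation under right censoring.

Six families are supported: exponential, Weibull, Gompertz, lognormal,
log-logistic and generalized gamma.  Each family exposes the log survival
function and log density in a *natural* parameterization, plus an internal
unconstrained parameterization used by the optimizer (positive parameters are
log-transformed; real-valued parameters pass through).

Conventions
-----------
* Time is measured in days; all scale parameters are in days, all rate
  parameters per day.
* The generalized gamma uses the location–scale–shape (mu, sigma, Q) form:
  with ``w = (log t - mu) / sigma`` and ``gamma = Q**-2``,

      S(t) = 1 - P(gamma, gamma * exp(Q w))   for Q > 0
      S(t) =     P(gamma, gamma * exp(Q w))   for Q < 0

  where P is the regularized lower incomplete gamma function.  The Q -> 0
  limit is the lognormal; an explicit branch at ``|Q| < 1e-6`` handles it.
  Q = 1 recovers the Weibull (shape 1/sigma, scale exp(mu)); sigma = Q
  recovers the gamma.
* The Gompertz shape may be negative, in which case the survival function
  plateaus at ``exp(rate/shape) > 0`` — a defective (cure-fraction-like)
  distribution, reported as such rather than rejected.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import special

_LOG_EPS = -745.0  # log of smallest positive double, for clamping

# ---------------------------------------------------------------------------
# family implementations: natural-parameter log S and log f
# ---------------------------------------------------------------------------


def _exp_logsf(t, p):
    (rate,) = p
    return -rate * t


def _exp_logpdf(t, p):
    (rate,) = p
    return np.log(rate) - rate * t


def _weibull_logsf(t, p):
    shape, scale = p
    return -np.power(t / scale, shape)


def _weibull_logpdf(t, p):
    shape, scale = p
    lt = np.log(t / scale)
    return np.log(shape / scale) + (shape - 1.0) * lt - np.exp(shape * lt)


def _gompertz_cumhaz(t, shape, rate):
    if abs(shape) < 1e-12:
        return rate * t
    return rate * np.expm1(shape * t) / shape


def _gompertz_logsf(t, p):
    shape, rate = p
    return -_gompertz_cumhaz(t, shape, rate)


def _gompertz_logpdf(t, p):
    shape, rate = p
    return np.log(rate) + shape * t - _gompertz_cumhaz(t, shape, rate)


def _lognormal_logsf(t, p):
    mu, sigma = p
    z = (np.log(t) - mu) / sigma
    return special.log_ndtr(-z)


def _lognormal_logpdf(t, p):
    mu, sigma = p
    z = (np.log(t) - mu) / sigma
    return -0.5 * z * z - 0.5 * np.log(2.0 * np.pi) - np.log(sigma) - np.log(t)


def _loglogistic_logsf(t, p):
    scale, shape = p
    return -np.log1p(np.power(t / scale, shape))


def _loglogistic_logpdf(t, p):
    scale, shape = p
    lt = np.log(t / scale)
    return np.log(shape / scale) + (shape - 1.0) * lt - 2.0 * np.log1p(np.exp(shape * lt))


def _gengamma_logsf(t, p):
    mu, sigma, q = p
    if abs(q) < 1e-6:
        return _lognormal_logsf(t, (mu, sigma))
    gamma = q**-2
    w = (np.log(t) - mu) / sigma
    u = gamma * np.exp(np.clip(q * w, _LOG_EPS, 700.0))
    with np.errstate(divide="ignore"):
        if q > 0:
            return np.log(np.clip(special.gammaincc(gamma, u), 0.0, 1.0))
        return np.log(np.clip(special.gammainc(gamma, u), 0.0, 1.0))


def _gengamma_logpdf(t, p):
    mu, sigma, q = p
    if abs(q) < 1e-6:
        return _lognormal_logpdf(t, (mu, sigma))
    gamma = q**-2
    w = (np.log(t) - mu) / sigma
    qw = np.clip(q * w, _LOG_EPS, 700.0)
    return (
        np.log(abs(q))
        + gamma * np.log(gamma)
        - special.gammaln(gamma)
        - np.log(sigma)
        - np.log(t)
        + gamma * (qw - np.exp(qw))
    )


# ---------------------------------------------------------------------------
# family registry
# ---------------------------------------------------------------------------


class ParametricFamily:
    """One parametric survival family: closed-form log S, log f and the
    transforms between natural and unconstrained optimizer parameters."""

    def __init__(
        self,
        name: str,
        param_names: tuple[str, ...],
        logsf: Callable,
        logpdf: Callable,
        to_internal: Callable,
        to_natural: Callable,
        starts: Callable,
        bounds: tuple[tuple[float, float], ...] = (),
    ):
        self.name = name
        self.param_names = param_names
        self._logsf = logsf
        self._logpdf = logpdf
        self.to_internal = to_internal
        self.to_natural = to_natural
        self.starts = starts
        # plausibility box on the *internal* (unconstrained) parameters; keeps
        # the optimizer away from degenerate likelihood spikes (e.g. the
        # sigma -> 0 collapse of location-scale families)
        self.bounds = bounds or tuple((-np.inf, np.inf) for _ in param_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def logsf(self, t, params):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(t > 0, self._logsf(np.maximum(t, 1e-300), params), 0.0)
        return out

    def logpdf(self, t, params):
        t = np.asarray(t, dtype=float)
        return self._logpdf(np.maximum(t, 1e-300), params)

    def sf(self, t, params):
        return np.exp(np.clip(self.logsf(t, params), _LOG_EPS, 0.0))

    def hazard(self, t, params):
        logs = self.logsf(t, params)
        return np.exp(self.logpdf(t, params) - logs)

    def __repr__(self):  # pragma: no cover
        return f"ParametricFamily({self.name!r})"


def _log_moments(time, event):
    """Mean/sd of log event times (all times if everything censored)."""
    t = np.asarray(time, dtype=float)
    obs = t[np.asarray(event, dtype=bool)]
    if obs.size == 0:
        obs = t
    lt = np.log(np.maximum(obs, 1e-12))
    m = float(np.mean(lt))
    s = float(np.std(lt))
    return m, max(s, 0.05)


def _exp_rate_guess(time, event):
    d = max(int(np.sum(event)), 1)
    return d / max(float(np.sum(time)), 1e-12)


FAMILIES: dict[str, ParametricFamily] = {}


def _register(fam: ParametricFamily):
    FAMILIES[fam.name] = fam
    return fam


_register(
    ParametricFamily(
        "exponential",
        ("rate",),
        _exp_logsf,
        _exp_logpdf,
        lambda p: np.log(p),
        lambda x: np.exp(x),
        lambda t, e: [np.log([_exp_rate_guess(t, e)])],
        bounds=((-30.0, 5.0),),
    )
)

_register(
    ParametricFamily(
        "weibull",
        ("shape", "scale"),
        _weibull_logsf,
        _weibull_logpdf,
        lambda p: np.log(p),
        lambda x: np.exp(x),
        lambda t, e: [
            np.log([shape, 1.0 / _exp_rate_guess(t, e)]) for shape in (0.8, 1.0, 1.5)
        ],
        bounds=((-3.0, 3.0), (-5.0, 15.0)),
    )
)


def _gompertz_starts(t, e):
    rate0 = _exp_rate_guess(t, e)
    tbar = max(float(np.mean(t)), 1e-6)
    return [
        np.array([c / tbar, np.log(rate0)])
        for c in (-1.0, -0.3, 1e-4, 0.3, 1.0)
    ]


_register(
    ParametricFamily(
        "gompertz",
        ("shape", "rate"),
        _gompertz_logsf,
        _gompertz_logpdf,
        lambda p: np.array([p[0], np.log(p[1])]),
        lambda x: np.array([x[0], np.exp(x[1])]),
        _gompertz_starts,
        bounds=((-1.0, 1.0), (-30.0, 5.0)),
    )
)

_register(
    ParametricFamily(
        "lognormal",
        ("mu", "sigma"),
        _lognormal_logsf,
        _lognormal_logpdf,
        lambda p: np.array([p[0], np.log(p[1])]),
        lambda x: np.array([x[0], np.exp(x[1])]),
        lambda t, e: [np.array([m, np.log(s)]) for m, s in [_log_moments(t, e)]],
        bounds=((-10.0, 20.0), (-3.9, 3.0)),
    )
)

_register(
    ParametricFamily(
        "loglogistic",
        ("scale", "shape"),
        _loglogistic_logsf,
        _loglogistic_logpdf,
        lambda p: np.log(p),
        lambda x: np.exp(x),
        lambda t, e: [
            np.array([m, np.log(np.pi / (s * np.sqrt(3.0)))])
            for m, s in [_log_moments(t, e)]
        ],
        bounds=((-5.0, 15.0), (-3.0, 3.0)),
    )
)


def _gengamma_starts(t, e):
    m, s = _log_moments(t, e)
    return [np.array([m, np.log(s), q]) for q in (1.0, 0.3, -0.5, 1.5)]


_register(
    ParametricFamily(
        "generalized_gamma",
        ("mu", "sigma", "Q"),
        _gengamma_logsf,
        _gengamma_logpdf,
        lambda p: np.array([p[0], np.log(p[1]), p[2]]),
        lambda x: np.array([x[0], np.exp(x[1]), x[2]]),
        _gengamma_starts,
        bounds=((-10.0, 20.0), (-3.9, 3.0), (-5.0, 5.0)),
    )
)

FAMILY_ORDER = (
    "exponential",
    "weibull",
    "gompertz",
    "lognormal",
    "loglogistic",
    "generalized_gamma",
)


def get_family(name: str) -> ParametricFamily:
    try:
        return FAMILIES[name]
    except KeyError:
        raise KeyError(
            f"unknown parametric family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
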
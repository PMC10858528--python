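"""Survival-curve estimation: Kaplan–Meier, censored maximum likelihood for the
six parametric families, information-criterion model selection and
proportional-hazards diagnostics.

All endpoints are fitted independently per arm (no shared-coefficient models);
the proportional-hazards test is reported for diagnostics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import optimize

from .families import FAMILIES, FAMILY_ORDER, ParametricFamily, get_family


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class EndpointDataset:
    """Right-censored time-to-event data for one endpoint.

    ``time`` is in days from the clock origin (index date for cohort-level
    endpoints, state-entry date for state-conditional ones); ``event`` is True
    for an observed event, False for censoring at that time.
    """

    name: str
    time: np.ndarray
    event: np.ndarray
    arm: str | None = None
    clock_origin: str = "index"
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have the same length")
        if self.time.size and np.any(self.time <= 0):
            raise ValueError(f"endpoint {self.name!r}: times must be strictly positive")

    def __len__(self):
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event.astype(int)})
        if self.ids is not None:
            df.insert(0, "id", self.ids)
        if self.arm is not None:
            df["arm"] = self.arm
        return df


@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray
    median: float | None

    def sf(self, t) -> np.ndarray:
        """Right-continuous step-function evaluation of the KM curve."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out


@dataclass
class FittedSurvivalModel:
    """A parametric family with fitted (or imposed) parameters.

    Exposes S(t) and h(t) for the cohort engines plus the maximized
    log-likelihood and the information criteria used for selection.
    """

    family: str
    params: np.ndarray
    loglik: float = np.nan
    n: int = 0
    n_events: int = 0
    converged: bool = True

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        fam = get_family(self.family)
        if self.params.shape != (fam.n_params,):
            raise ValueError(
                f"{self.family} expects {fam.n_params} parameters, got {self.params.shape}"
            )

    @property
    def _fam(self) -> ParametricFamily:
        return get_family(self.family)

    @property
    def k(self) -> int:
        return self._fam.n_params

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def aicc(self) -> float:
        denom = self.n - self.k - 1
        if denom <= 0:
            return np.inf
        return self.aic + 2 * self.k * (self.k + 1) / denom

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2 * self.loglik

    def sf(self, t) -> np.ndarray:
        return self._fam.sf(t, self.params)

    def hazard(self, t) -> np.ndarray:
        return self._fam.hazard(t, self.params)

    def param_dict(self) -> dict[str, float]:
        return dict(zip(self._fam.param_names, map(float, self.params)))

    def to_json_dict(self) -> dict:
        return {
            "family": self.family,
            "params": [float(p) for p in self.params],
            "param_names": list(self._fam.param_names),
            "loglik": float(self.loglik),
            "n": int(self.n),
            "n_events": int(self.n_events),
            "aic": float(self.aic),
            "aicc": float(self.aicc),
            "bic": float(self.bic),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "FittedSurvivalModel":
        return cls(
            family=d["family"],
            params=np.asarray(d["params"], dtype=float),
            loglik=d.get("loglik", np.nan),
            n=d.get("n", 0),
            n_events=d.get("n_events", 0),
            converged=d.get("converged", True),
        )


def survival_at(model: FittedSurvivalModel, t) -> np.ndarray:
    """S(t) with domain validation; vectorized over t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival_at requires t >= 0")
    return model.sf(t)


def hazard_at(model: FittedSurvivalModel, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("hazard_at requires t >= 0")
    return model.hazard(t)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


def km_estimate(dataset: EndpointDataset) -> KMEstimate:
    """Product-limit estimator with Greenwood variance.

    Deaths are processed before censorings at tied times (the product-limit
    convention).  The median is the smallest time with S(t) <= 0.5 and is None
    when the curve never reaches 0.5.
    """
    if len(dataset) == 0:
        raise ValueError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(dataset.time, event_observed=dataset.event)
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0)
    greenwood = surv**2 * np.cumsum(incr)
    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    return KMEstimate(times, surv, at_risk, greenwood, median)


# ---------------------------------------------------------------------------
# parametric maximum likelihood
# ---------------------------------------------------------------------------


class FitError(ValueError):
    pass


def _negloglik(x, fam: ParametricFamily, time, event):
    for xi, (lo, hi) in zip(x, fam.bounds):
        if not lo <= xi <= hi:
            return 1e12 + 1e6 * (abs(xi - lo) + abs(xi - hi))
    params = fam.to_natural(x)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        logsf = fam.logsf(time, params)
        logpdf = fam.logpdf(time, params)
        ll = np.sum(np.where(event, logpdf, logsf))
    if not np.isfinite(ll):
        return 1e12
    return -ll


def fit_parametric(dataset: EndpointDataset, family: str | ParametricFamily) -> FittedSurvivalModel:
    """Censored MLE of one family on one endpoint.

    The likelihood is sum(log f) over events plus sum(log S) over censored
    subjects.  Multiple starting points are used (several for the Gompertz and
    generalized gamma, whose likelihoods can be multimodal); the best local
    optimum is kept.  Non-convergence is flagged, not raised.
    """
    fam = family if isinstance(family, ParametricFamily) else get_family(family)
    if len(dataset) == 0:
        raise FitError("empty dataset")
    if dataset.n_events == 0:
        raise FitError(f"endpoint {dataset.name!r}: all observations censored")
    time, event = dataset.time, dataset.event

    best = None
    any_converged = False
    for x0 in fam.starts(time, event):
        res = optimize.minimize(
            _negloglik,
            x0,
            args=(fam, time, event),
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)
    # polish the best solution
    polish = optimize.minimize(
        _negloglik,
        best.x,
        args=(fam, time, event),
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
    )
    if polish.fun <= best.fun:
        best = polish
        any_converged = any_converged or bool(polish.success)
    params = fam.to_natural(best.x)
    return FittedSurvivalModel(
        family=fam.name,
        params=np.asarray(params, dtype=float),
        loglik=-float(best.fun),
        n=len(dataset),
        n_events=dataset.n_events,
        converged=any_converged and best.fun < 1e11,
    )


def fit_all_families(
    dataset: EndpointDataset, families: tuple[str, ...] = FAMILY_ORDER
) -> list[FittedSurvivalModel]:
    out = []
    for name in families:
        try:
            out.append(fit_parametric(dataset, name))
        except FitError:
            raise
    return out


def select_best(
    models: list[FittedSurvivalModel],
    criterion: str = "aic",
    override_family: str | None = None,
) -> tuple[FittedSurvivalModel, pd.DataFrame]:
    """Pick the winning family (default: lowest AIC) and return the ranking.

    Ties are broken by fewer parameters, then by the fixed family order.
    ``override_family`` forces a family, standing in for visual inspection.
    Non-converged fits are excluded from selection but still listed.
    """
    if criterion not in ("aic", "aicc", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rows = []
    for m in models:
        rows.append(
            {
                "family": m.family,
                "k": m.k,
                "loglik": m.loglik,
                "aic": m.aic,
                "aicc": m.aicc,
                "bic": m.bic,
                "converged": m.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values(criterion, kind="mergesort").reset_index(drop=True)
    candidates = [m for m in models if m.converged]
    if not candidates:
        raise FitError("no converged models to select from")
    if override_family is not None:
        forced = [m for m in candidates if m.family == override_family]
        if not forced:
            raise FitError(f"override family {override_family!r} not among converged fits")
        return forced[0], table
    order = {name: i for i, name in enumerate(FAMILY_ORDER)}
    winner = min(
        candidates,
        key=lambda m: (round(getattr(m, criterion), 12), m.k, order.get(m.family, 99)),
    )
    return winner, table


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics
# ---------------------------------------------------------------------------


@dataclass
class PHDiagnostics:
    hazard_ratio: float
    per_covariate: pd.DataFrame  # test_statistic, p per covariate
    global_statistic: float
    global_p: float
    log_cumhaz_curves: dict = field(default_factory=dict)  # arm -> (times, log(-log S))
    holds: bool = True


def test_proportional_hazards(
    dataset_a: EndpointDataset, dataset_b: EndpointDataset, alpha: float = 0.05
) -> PHDiagnostics:
    """Two-arm PH check: Cox fit on an arm indicator, scaled Schoenfeld
    residual trend test per covariate plus a global chi-square, and
    log-cumulative-hazard curves for plotting."""
    if dataset_a.n_events == 0 or dataset_b.n_events == 0:
        raise ValueError("both arms need at least one event")
    df = pd.concat(
        [
            pd.DataFrame({"time": dataset_a.time, "event": dataset_a.event.astype(int), "arm": 1}),
            pd.DataFrame({"time": dataset_b.time, "event": dataset_b.event.astype(int), "arm": 0}),
        ],
        ignore_index=True,
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
        res = proportional_hazard_test(cph, df, time_transform="km")
    per_cov = res.summary[["test_statistic", "p"]].copy()
    global_stat = float(per_cov["test_statistic"].sum())
    from scipy import stats as _stats

    global_p = float(_stats.chi2.sf(global_stat, df=len(per_cov)))
    curves = {}
    for label, ds in (("A", dataset_a), ("B", dataset_b)):
        km = km_estimate(ds)
        with np.errstate(divide="ignore", invalid="ignore"):
            loglog = np.log(-np.log(np.clip(km.survival, 1e-300, 1.0 - 1e-12)))
        mask = np.isfinite(loglog)
        curves[label] = (km.times[mask], loglog[mask])
    return PHDiagnostics(
        hazard_ratio=float(np.exp(cph.params_.iloc[0])),
        per_covariate=per_cov,
        global_statistic=global_stat,
        global_p=global_p,
        log_cumhaz_curves=curves,
        holds=global_p >= alpha,
    )
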
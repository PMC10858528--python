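"""Cohort engines for the three model structures.

* PSM — partitioned survival: state occupancy read directly off the OS and
  TTNT curves (dead = 1 − S_OS, progression-free = min(S_TTNT, S_OS),
  post-progression = the difference).
* STM3 — three-state semi-Markov cohort model (PF, PP, Death) with
  time-dependent transition probabilities and a tunnel-state expansion of PP
  so the PP death probability depends on time since progression.
* STM5 — five-state extension with brain-metastasis states BMIT (continuing
  initial therapy) and BMST (subsequent therapy), all of PP/BMIT/BMST
  tunnelled on time-in-state clocks.

Transitions out of the entry state PF use the model-time clock (both clocks
coincide there); tunnel-state transitions use the time-since-entry clock.
State membership is recorded at cycle boundaries t = 0, c, 2c, ...

Competing exits from one state are combined either by the cause-specific
hazard-split rule (default: convert each conditional exit probability to a
cycle hazard, exponentiate the total, allocate proportionally — guarantees the
probabilities sum to at most 1) or by plain subtraction (config-selectable,
rescaled with a warning if the sum exceeds 1).  Where one driving curve nests
another (the TTNT curve's exit includes death), the nested pair is first
reduced to an effective total exit and a death share, so that switching off
the BM causes collapses STM5 to STM3 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import FittedSurvivalModel, survival_at

YEAR_DAYS = 365.25
DEFAULT_CYCLE_DAYS = 21.0
DEFAULT_HORIZON_DAYS = 7 * YEAR_DAYS

STM3_STATES = ("PF", "PP", "Death")
STM5_STATES = ("PF", "PP", "BMIT", "BMST", "Death")
TUNNEL_STATES = ("PP", "BMIT", "BMST")

STM3_CURVES = ("ttnt", "death_from_pf", "death_from_pp")
STM5_CURVES = (
    "ttnt_from_pf",
    "death_from_pf",
    "bm_from_pf",
    "death_from_pp",
    "bm_from_pp",
    "ttnt_in_bmit",
    "death_in_bmit",
    "death_in_bmst",
)
PSM_CURVES = ("os", "ttnt")


@dataclass
class ModelStructure:
    """Declarative description of one model structure: its name, the fitted
    curves that drive it (keyed by endpoint name) and, for STM5, the fraction
    of the cohort starting in BMIT (baseline brain-metastasis history)."""

    name: str  # "PSM" | "STM3" | "STM5"
    models: dict[str, FittedSurvivalModel]
    initial_bm_fraction: float = 0.0

    def __post_init__(self):
        required = {"PSM": PSM_CURVES, "STM3": STM3_CURVES, "STM5": STM5_CURVES}
        if self.name not in required:
            raise ValueError(f"unknown structure {self.name!r}")
        missing = [c for c in required[self.name] if c not in self.models]
        if missing:
            raise ValueError(f"{self.name}: missing driving curves {missing}")
        if not 0.0 <= self.initial_bm_fraction <= 1.0:
            raise ValueError("initial_bm_fraction must be in [0, 1]")


@dataclass
class CohortTrace:
    states: tuple[str, ...]
    cycle_days: float
    times: np.ndarray  # cycle-boundary times in days, length T+1
    occupancy: np.ndarray  # (T+1, n_states), rows sum to 1
    tunnels: dict[str, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.times) - 1

    def state(self, name: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "time_days", self.times)
        df.insert(0, "cycle", np.arange(len(self.times)))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cycle_days: float) -> "CohortTrace":
        states = tuple(c for c in df.columns if c not in ("cycle", "time_days"))
        return cls(
            states=states,
            cycle_days=cycle_days,
            times=df["time_days"].to_numpy(dtype=float),
            occupancy=df[list(states)].to_numpy(dtype=float),
        )


def n_cycles(horizon_days: float, cycle_days: float) -> int:
    return int(math.ceil(horizon_days / cycle_days - 1e-12))


def conditional_exit_probability(model: FittedSurvivalModel, t, cycle_days: float):
    """P(exit in (t, t+c] | in state at clock time t) = 1 − S(t+c)/S(t).

    Where S(t) = 0 the whole remaining cohort exits (probability 1).
    Vectorized over t; clipped to [0, 1].
    """
    t = np.asarray(t, dtype=float)
    if cycle_days <= 0:
        raise ValueError("cycle length must be positive")
    s0 = survival_at(model, t)
    s1 = survival_at(model, t + cycle_days)
    # below ~1e-300 the curve is numerically exhausted (S may be held at a
    # denormal by the log-clamp); the whole remaining cohort exits
    alive = s0 > 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(alive, 1.0 - s1 / np.where(alive, s0, 1.0), 1.0)
    return np.clip(q, 0.0, 1.0)


def combine_competing(qs: np.ndarray, rule: str = "hazard_split"):
    """Allocate a state's total exit probability among competing causes.

    ``qs`` holds each cause's own conditional exit probability for the cycle.
    hazard_split: total exit 1 − prod(1 − q_i), allocated proportionally to the
    cause-specific cycle hazards −log(1 − q_i); exact when only one cause is
    active.  subtraction: the q_i are used as-is, rescaled if they sum past 1.
    Returns (allocated probabilities, flag that a cap/rescale fired).
    """
    qs = np.clip(np.asarray(qs, dtype=float), 0.0, 1.0)
    if rule == "subtraction":
        tot = qs.sum()
        if tot > 1.0:
            return qs / tot, True
        return qs, False
    if rule != "hazard_split":
        raise ValueError(f"unknown competing rule {rule!r}")
    sat = qs >= 1.0
    if sat.any():
        out = np.zeros_like(qs)
        out[sat] = 1.0 / sat.sum()
        return out, False
    active = qs > 0.0
    if active.sum() <= 1:
        return qs, False
    lam = -np.log1p(-qs)
    total = -np.expm1(-lam.sum())
    return total * lam / lam.sum(), False


# ---------------------------------------------------------------------------
# per-cycle probability schedules
# ---------------------------------------------------------------------------


def _nested_exit(q_total, q_death):
    """Reduce a (total-exit curve, death curve) pair to (effective total exit,
    death share, transition share).  The transition probability is the total
    exit minus death, floored at 0."""
    trans = np.maximum(q_total - q_death, 0.0)
    return q_death + trans, q_death, trans


def _stm3_schedule(models, T, c, competing):
    t_model = np.arange(T) * c
    t_layer = np.arange(T + 1) * c
    q_tot = conditional_exit_probability(models["ttnt"], t_model, c)
    q_d = conditional_exit_probability(models["death_from_pf"], t_model, c)
    _, tp2, tp1 = _nested_exit(q_tot, q_d)
    floors = int(np.sum(q_d > q_tot + 1e-15))
    q3 = conditional_exit_probability(models["death_from_pp"], t_layer, c)
    pf_exit = np.stack([tp1, tp2], axis=1)  # -> PP, Death
    pp_exit = q3[:, None]  # -> Death
    return {"PF": pf_exit, "PP": pp_exit}, floors


def _stm5_schedule(models, T, c, competing):
    t_model = np.arange(T) * c
    t_layer = np.arange(T + 1) * c
    q_nt = conditional_exit_probability(models["ttnt_from_pf"], t_model, c)
    q_d = conditional_exit_probability(models["death_from_pf"], t_model, c)
    q_bm = conditional_exit_probability(models["bm_from_pf"], t_model, c)
    q_nt_eff, tp2_raw, tp1_raw = _nested_exit(q_nt, q_d)
    floors = int(np.sum(q_d > q_nt + 1e-15))
    capped = 0
    pf_exit = np.zeros((T, 3))  # -> PP, BMIT, Death
    for k in range(T):
        alloc, cap = combine_competing(np.array([q_nt_eff[k], q_bm[k]]), competing)
        capped += cap
        qn, qb = alloc
        if q_nt_eff[k] > 0:
            pf_exit[k, 0] = qn * tp1_raw[k] / q_nt_eff[k]
            pf_exit[k, 2] = qn * tp2_raw[k] / q_nt_eff[k]
        pf_exit[k, 1] = qb

    q3 = conditional_exit_probability(models["death_from_pp"], t_layer, c)
    q5 = conditional_exit_probability(models["bm_from_pp"], t_layer, c)
    pp_exit = np.zeros((T + 1, 2))  # -> BMST, Death
    for u in range(T + 1):
        alloc, cap = combine_competing(np.array([q5[u], q3[u]]), competing)
        capped += cap
        pp_exit[u] = alloc

    q_nt_b = conditional_exit_probability(models["ttnt_in_bmit"], t_layer, c)
    q7 = conditional_exit_probability(models["death_in_bmit"], t_layer, c)
    _, tp7, tp6 = _nested_exit(q_nt_b, q7)
    floors += int(np.sum(q7 > q_nt_b + 1e-15))
    bmit_exit = np.stack([tp6, tp7], axis=1)  # -> BMST, Death

    q8 = conditional_exit_probability(models["death_in_bmst"], t_layer, c)
    bmst_exit = q8[:, None]  # -> Death
    return (
        {"PF": pf_exit, "PP": pp_exit, "BMIT": bmit_exit, "BMST": bmst_exit},
        floors,
        capped,
    )


# ---------------------------------------------------------------------------
# trace builders
# ---------------------------------------------------------------------------


def build_psm_trace(
    os_model: FittedSurvivalModel,
    ttnt_model: FittedSurvivalModel,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    cycle_days: float = DEFAULT_CYCLE_DAYS,
) -> CohortTrace:
    """Partitioned-survival occupancy: Death = 1 − S_OS, PF = min(S_TTNT, S_OS)
    (the min caps PF at OS where the curves cross), PP = S_OS − PF."""
    T = n_cycles(horizon_days, cycle_days)
    times = np.arange(T + 1) * cycle_days
    s_os = survival_at(os_model, times)
    s_ttnt = survival_at(ttnt_model, times)
    pf = np.minimum(s_ttnt, s_os)
    caps = int(np.sum(s_ttnt > s_os + 1e-15))
    occ = np.column_stack([pf, s_os - pf, 1.0 - s_os])
    warns = []
    if caps:
        warns.append(f"PSM: PF capped at OS in {caps}/{T + 1} cycles (curve crossing)")
    return CohortTrace(STM3_STATES, cycle_days, times, occ, warnings=warns)


def _run_tunnel_engine(states, schedule, initial, T, cycle_days, warns):
    """Advance the cohort through the cycle loop.

    ``schedule[state]`` is an array of per-cycle (entry state, indexed by model
    time) or per-layer (tunnel states, indexed by time-in-state) exit
    probabilities, one column per exit target in the order given by
    ``_TARGETS[structure][state]``.
    """
    tunnel = {s: np.zeros(T + 1) for s in states if s in TUNNEL_STATES}
    pf = initial.get("PF", 0.0)
    if "BMIT" in tunnel:
        tunnel["BMIT"][0] = initial.get("BMIT", 0.0)
    dead = 0.0

    occ = np.zeros((T + 1, len(states)))
    tun_hist = {s: np.zeros((T + 1, T + 1)) for s in tunnel}

    def record(k):
        row = []
        for s in states:
            if s == "PF":
                row.append(pf)
            elif s == "Death":
                row.append(dead)
            else:
                row.append(tunnel[s].sum())
        occ[k] = row
        for s in tunnel:
            tun_hist[s][k] = tunnel[s]

    record(0)
    five_state = "BMIT" in tunnel
    for k in range(T):
        if five_state:
            to_pp, to_bmit, pf_dead = (pf * p for p in schedule["PF"][k])
        else:
            to_pp, pf_dead = (pf * p for p in schedule["PF"][k])
            to_bmit = 0.0
        pf = pf - to_pp - to_bmit - pf_dead
        dead += pf_dead

        pp = tunnel["PP"]
        if five_state:
            pp_bm = pp * schedule["PP"][:, 0]
            pp_dead = pp * schedule["PP"][:, 1]
        else:
            pp_bm = np.zeros_like(pp)
            pp_dead = pp * schedule["PP"][:, 0]
        stay = pp - pp_bm - pp_dead
        new_pp = np.zeros_like(pp)
        new_pp[1:] = stay[:-1]
        new_pp[0] = to_pp
        dead += pp_dead.sum()

        if five_state:
            bmit = tunnel["BMIT"]
            bmit_switch = bmit * schedule["BMIT"][:, 0]
            bmit_dead = bmit * schedule["BMIT"][:, 1]
            stay_b = bmit - bmit_switch - bmit_dead
            new_bmit = np.zeros_like(bmit)
            new_bmit[1:] = stay_b[:-1]
            new_bmit[0] = to_bmit
            dead += bmit_dead.sum()

            bmst = tunnel["BMST"]
            bmst_dead = bmst * schedule["BMST"][:, 0]
            stay_s = bmst - bmst_dead
            new_bmst = np.zeros_like(bmst)
            new_bmst[1:] = stay_s[:-1]
            new_bmst[0] = pp_bm.sum() + bmit_switch.sum()
            dead += bmst_dead.sum()
            tunnel["BMIT"] = new_bmit
            tunnel["BMST"] = new_bmst

        tunnel["PP"] = new_pp
        record(k + 1)

    times = np.arange(T + 1) * cycle_days
    return CohortTrace(tuple(states), cycle_days, times, occ, tunnels=tun_hist, warnings=warns)


def build_stm3_trace(
    models: dict[str, FittedSurvivalModel],
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    cycle_days: float = DEFAULT_CYCLE_DAYS,
    competing: str = "hazard_split",
) -> CohortTrace:
    """Three-state semi-Markov trace.

    PF exits by death (TP2, from the PF-death curve on model time) and by
    progression (TP1 = total PF exit from the TTNT curve minus TP2, floored at
    0); the PP cohort is tracked by time-since-entry layers, each dying with
    TP3 from the PP-death curve on the time-in-state clock.
    """
    T = n_cycles(horizon_days, cycle_days)
    schedule, floors = _stm3_schedule(models, T, cycle_days, competing)
    warns = []
    if floors:
        msg = f"STM3: TP1 floored at 0 in {floors}/{T} cycles (TTNT/death curve inconsistency)"
        warns.append(msg)
        if floors > 0.1 * T:
            import warnings as _w

            _w.warn(msg)
    return _run_tunnel_engine(STM3_STATES, schedule, {"PF": 1.0}, T, cycle_days, warns)


def build_stm5_trace(
    models: dict[str, FittedSurvivalModel],
    initial_bm_fraction: float = 0.0,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    cycle_days: float = DEFAULT_CYCLE_DAYS,
    competing: str = "hazard_split",
) -> CohortTrace:
    """Five-state semi-Markov trace with brain-metastasis tunnel states.

    The cohort starts (1 − f) in PF and f in BMIT (baseline BM history).  PF
    has competing exits to PP, BMIT and Death on the model-time clock; PP,
    BMIT and BMST are tunnelled on time-in-state clocks; BMIT→BMST entrants
    restart the BMST clock at zero.
    """
    if not 0.0 <= initial_bm_fraction <= 1.0:
        raise ValueError("initial_bm_fraction must be in [0, 1]")
    T = n_cycles(horizon_days, cycle_days)
    schedule, floors, capped = _stm5_schedule(models, T, cycle_days, competing)
    warns = []
    if floors:
        warns.append(f"STM5: nested-exit floor fired in {floors} cycle evaluations")
    if capped:
        warns.append(f"STM5: competing-exit rescale fired in {capped} cycle evaluations")
    initial = {"PF": 1.0 - initial_bm_fraction, "BMIT": initial_bm_fraction}
    return _run_tunnel_engine(STM5_STATES, schedule, initial, T, cycle_days, warns)


def build_trace(
    structure: ModelStructure,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    cycle_days: float = DEFAULT_CYCLE_DAYS,
    competing: str = "hazard_split",
) -> CohortTrace:
    if structure.name == "PSM":
        return build_psm_trace(structure.models["os"], structure.models["ttnt"], horizon_days, cycle_days)
    if structure.name == "STM3":
        return build_stm3_trace(structure.models, horizon_days, cycle_days, competing)
    return build_stm5_trace(
        structure.models, structure.initial_bm_fraction, horizon_days, cycle_days, competing
    )


# ---------------------------------------------------------------------------
# microsimulation oracle
# ---------------------------------------------------------------------------


def microsimulate(
    structure: ModelStructure,
    n: int,
    seed: int,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    cycle_days: float = DEFAULT_CYCLE_DAYS,
    competing: str = "hazard_split",
) -> CohortTrace:
    """Individual-level counterpart of the cohort engines.

    Simulates n individuals cycle-by-cycle using exactly the per-cycle
    transition probabilities and clocks of the cohort trace (counts are
    updated with multinomial draws per state/tunnel-layer cell, which is
    distributionally identical to simulating individuals one at a time).
    Returns the empirical occupancy trace.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if structure.name == "PSM":
        raise ValueError("microsimulation applies to the state-transition structures")
    rng = np.random.default_rng(seed)
    T = n_cycles(horizon_days, cycle_days)
    five = structure.name == "STM5"
    if five:
        schedule, _, _ = _stm5_schedule(structure.models, T, cycle_days, competing)
        states = STM5_STATES
        n_bmit = rng.binomial(n, structure.initial_bm_fraction)
    else:
        schedule, _ = _stm3_schedule(structure.models, T, cycle_days, competing)
        states = STM3_STATES
        n_bmit = 0

    pf = n - n_bmit
    pp = np.zeros(T + 1, dtype=np.int64)
    bmit = np.zeros(T + 1, dtype=np.int64)
    bmst = np.zeros(T + 1, dtype=np.int64)
    bmit[0] = n_bmit
    dead = 0

    occ = np.zeros((T + 1, len(states)))

    def record(k):
        if five:
            occ[k] = [pf, pp.sum(), bmit.sum(), bmst.sum(), dead]
        else:
            occ[k] = [pf, pp.sum(), dead]

    def split(count, probs):
        """Multinomial split of `count` into exits (per probs) + stay."""
        p = np.append(probs, max(1.0 - probs.sum(), 0.0))
        p = p / p.sum()
        return rng.multinomial(count, p)

    record(0)
    for k in range(T):
        if pf > 0:
            parts = split(pf, schedule["PF"][k])
            if five:
                to_pp, to_bmit, pf_dead, pf_stay = parts
            else:
                to_pp, pf_dead, pf_stay = parts
                to_bmit = 0
        else:
            to_pp = to_bmit = pf_dead = pf_stay = 0
        pf = int(pf_stay)
        dead += int(pf_dead)

        new_pp = np.zeros_like(pp)
        bm_out = 0
        for u in np.nonzero(pp)[0]:
            parts = split(pp[u], schedule["PP"][u])
            if five:
                pp_bm, pp_dead, pp_stay = parts
            else:
                pp_dead, pp_stay = parts
                pp_bm = 0
            bm_out += int(pp_bm)
            dead += int(pp_dead)
            if u + 1 <= T:
                new_pp[u + 1] = pp_stay
        new_pp[0] = to_pp
        pp = new_pp

        if five:
            new_bmit = np.zeros_like(bmit)
            switch_out = 0
            for u in np.nonzero(bmit)[0]:
                sw, bd, st = split(bmit[u], schedule["BMIT"][u])
                switch_out += int(sw)
                dead += int(bd)
                if u + 1 <= T:
                    new_bmit[u + 1] = st
            new_bmit[0] = to_bmit
            bmit = new_bmit

            new_bmst = np.zeros_like(bmst)
            for u in np.nonzero(bmst)[0]:
                bd, st = split(bmst[u], schedule["BMST"][u])
                dead += int(bd)
                if u + 1 <= T:
                    new_bmst[u + 1] = st
            new_bmst[0] = bm_out + switch_out
            bmst = new_bmst
        record(k + 1)

    times = np.arange(T + 1) * cycle_days
    return CohortTrace(tuple(states), cycle_days, times, occ / n)
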
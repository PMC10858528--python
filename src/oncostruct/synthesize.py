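"""Synthetic claims-like patient data with a five-state disease structure.

The generator emulates a second-line EGFR-mutated NSCLC claims extraction: two
treatment cohorts (an osimertinib-like arm "A" and a pemetrexed–platinum-like
arm "B"), latent times to next treatment, brain metastasis (BM) and death with
arm-specific cause-specific hazards on each edge of the state graph

    PF -> {PP, BMIT, Death},  PP -> {BMST, Death},
    BMIT -> {BMST, Death},    BMST -> Death,

administrative censoring at a study cut-off, a claims-based BM diagnosis rule
(>=1 inpatient or >=2 outpatient C793 claims), and baseline covariates for
propensity matching.  Clocks restart on state entry (semi-Markov); the
transition taken out of a state is the minimum of its competing latent times,
with BM winning exact ties (deterministic tie-break).

All times are in days.  Patients with a BM history at the index date start in
BMIT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .fitting import EndpointDataset

STATES = ("PF", "PP", "BMIT", "BMST", "Death")

# out-edges per state; BM-target edges listed first so that argmin over this
# order resolves same-day ties in favor of the BM transition
OUT_EDGES: dict[str, tuple[tuple[str, str], ...]] = {
    "PF": (("BMIT", "pf_bm"), ("PP", "pf_next_treatment"), ("Death", "pf_death")),
    "PP": (("BMST", "pp_bm"), ("Death", "pp_death")),
    "BMIT": (("BMST", "bmit_next_treatment"), ("Death", "bmit_death")),
    "BMST": (("Death", "bmst_death"),),
}

EDGE_NAMES = (
    "pf_next_treatment",
    "pf_death",
    "pf_bm",
    "pp_death",
    "pp_bm",
    "bmit_next_treatment",
    "bmit_death",
    "bmst_death",
)

ENDPOINT_NAMES = (
    "os",
    "ttnt",
    "death_from_pf",
    "death_from_pp",
    "ttnt_from_pf",
    "bm_from_pf",
    "bm_from_pp",
    "ttnt_in_bmit",
    "death_in_bmit",
    "death_in_bmst",
)

C793 = "C793"


class ConfigError(ValueError):
    pass


@dataclass
class HazardSpec:
    """Cause-specific latent-time distribution for one edge.

    ``exponential`` takes a rate per day (rate 0 means the transition never
    fires); ``weibull`` takes shape and scale (days).
    """

    family: str
    rate: float | None = None
    shape: float | None = None
    scale: float | None = None

    def validate(self, edge: str):
        if self.family == "exponential":
            if self.rate is None or self.rate < 0:
                raise ConfigError(f"edge {edge!r}: exponential rate must be >= 0")
        elif self.family == "weibull":
            if self.shape is None or self.shape <= 0 or self.scale is None or self.scale <= 0:
                raise ConfigError(f"edge {edge!r}: weibull needs shape > 0 and scale > 0")
        else:
            raise ConfigError(f"edge {edge!r}: unknown hazard family {self.family!r}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "exponential":
            if self.rate == 0:
                return np.inf
            return rng.exponential(1.0 / self.rate)
        return self.scale * rng.weibull(self.shape)


def _default_hazards() -> dict[str, dict[str, HazardSpec]]:
    def e(rate):
        return HazardSpec("exponential", rate=rate)

    return {
        "A": {
            "pf_next_treatment": e(0.0012),
            "pf_death": e(0.0003),
            "pf_bm": e(0.0007),
            "pp_death": e(0.0019),
            "pp_bm": e(0.0004),
            "bmit_next_treatment": e(0.0010),
            "bmit_death": e(0.0008),
            "bmst_death": e(0.0030),
        },
        "B": {
            "pf_next_treatment": e(0.0033),
            "pf_death": e(0.0006),
            "pf_bm": e(0.0007),
            "pp_death": e(0.0028),
            "pp_bm": e(0.0005),
            "bmit_next_treatment": e(0.0045),
            "bmit_death": e(0.0025),
            "bmst_death": e(0.0060),
        },
    }


@dataclass
class SimulationConfig:
    n_per_arm: int = 735
    seed: int = 20240209
    study_cutoff: float = 2200.0  # days from the earliest possible index date
    index_dispersion: float = 1100.0  # index dates uniform on [0, dispersion]
    female_fraction: float = 0.615
    age_mean: float = 64.9
    age_sd: float = 9.5
    baseline_bm_fraction: float = 0.2
    hazards: dict[str, dict[str, HazardSpec]] = field(default_factory=_default_hazards)
    # claims emission
    inpatient_fraction: float = 0.5  # qualifying BM patterns that use one inpatient claim
    outpatient_gap: float = 7.0  # days between the two outpatient claims
    diagnosis_lag: float = 0.0  # days from latent BM entry to the first claim
    noise_fraction: float = 0.05  # never-BM patients given a single outpatient claim

    def validate(self):
        if self.n_per_arm < 1:
            raise ConfigError("n_per_arm must be >= 1")
        for p, name in (
            (self.female_fraction, "female_fraction"),
            (self.baseline_bm_fraction, "baseline_bm_fraction"),
            (self.noise_fraction, "noise_fraction"),
            (self.inpatient_fraction, "inpatient_fraction"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.study_cutoff <= self.index_dispersion:
            raise ConfigError("study_cutoff must exceed index_dispersion (positive follow-up)")
        for arm in ("A", "B"):
            if arm not in self.hazards:
                raise ConfigError(f"missing hazard spec for arm {arm!r}")
            for edge in EDGE_NAMES:
                if edge not in self.hazards[arm]:
                    raise ConfigError(f"arm {arm!r}: missing hazard spec for edge {edge!r}")
                self.hazards[arm][edge].validate(edge)

    def to_yaml(self, path):
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        hz = {
            arm: {edge: HazardSpec(**spec) for edge, spec in edges.items()}
            for arm, edges in d.pop("hazards").items()
        }
        return cls(hazards=hz, **d)


@dataclass
class PatientRecord:
    id: int
    arm: str
    index_date: float
    female: bool
    age: float
    baseline_bm: bool
    latent: dict[str, float]  # edge name -> latent time drawn at state entry
    path: list[tuple[str, float]]  # (state, entry time in days from index)

    @property
    def death_time(self) -> float:
        return self.path[-1][1]

    def state_entry(self, state: str) -> float | None:
        for s, t in self.path:
            if s == state:
                return t
        return None


@dataclass
class ClaimRecord:
    patient_id: int
    service_date: float  # days from index
    setting: str  # "inpatient" | "outpatient"
    code: str


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    caliper: float | None


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _simulate_path(rng, hazards, start_state) -> tuple[list, dict]:
    path = [(start_state, 0.0)]
    latent: dict[str, float] = {}
    state, now = start_state, 0.0
    while state != "Death":
        draws = []
        for target, edge in OUT_EDGES[state]:
            t = hazards[edge].sample(rng)
            latent[edge] = t
            draws.append((t, target))
        times = np.array([d[0] for d in draws])
        if not np.isfinite(times).any():
            break  # no finite exit: patient remains in this state forever
        j = int(np.argmin(times))  # ties resolve to the BM edge (listed first)
        state = draws[j][1]
        now += draws[j][0]
        path.append((state, now))
    return path, latent


def generate_cohorts(config: SimulationConfig) -> list[PatientRecord]:
    """Simulate 2 x n_per_arm patients through the five-state graph.

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    records = []
    pid = 0
    for arm in ("A", "B"):
        hz = config.hazards[arm]
        for _ in range(config.n_per_arm):
            index_date = rng.uniform(0.0, config.index_dispersion)
            female = rng.random() < config.female_fraction
            age = rng.normal(config.age_mean, config.age_sd)
            baseline_bm = rng.random() < config.baseline_bm_fraction
            start = "BMIT" if baseline_bm else "PF"
            path, latent = _simulate_path(rng, hz, start)
            records.append(
                PatientRecord(
                    id=pid,
                    arm=arm,
                    index_date=index_date,
                    female=female,
                    age=age,
                    baseline_bm=baseline_bm,
                    latent=latent,
                    path=path,
                )
            )
            pid += 1
    return records


def observation_end(record: PatientRecord, config: SimulationConfig) -> float:
    """Days of potential follow-up (cut-off minus index date)."""
    return config.study_cutoff - record.index_date


# ---------------------------------------------------------------------------
# claims
# ---------------------------------------------------------------------------


def _bm_entry(record: PatientRecord) -> float | None:
    """Time of the BM event: entering BMIT, or entering BMST directly from PP.
    A BMIT->BMST move is a therapy switch, not a new BM diagnosis."""
    prev = None
    for state, t in record.path:
        if state == "BMIT":
            return t
        if state == "BMST" and prev == "PP":
            return t
        prev = state
    return None


def emit_claims(records: list[PatientRecord], config: SimulationConfig) -> list[ClaimRecord]:
    """Emit C793 claim patterns.

    BM patients receive a qualifying pattern (one inpatient claim, or two
    outpatient claims ``outpatient_gap`` days apart) starting ``diagnosis_lag``
    days after the latent BM entry; a ``noise_fraction`` of never-BM patients
    receive exactly one outpatient claim (non-qualifying).  Claims falling
    after the patient's censoring date are not observed and are dropped.
    """
    rng = np.random.default_rng([config.seed, 1])
    claims: list[ClaimRecord] = []
    for rec in records:
        death = rec.death_time if rec.path[-1][0] == "Death" else np.inf
        obs_end = min(observation_end(rec, config), death)
        entry = _bm_entry(rec)
        if entry is not None:
            first = entry + config.diagnosis_lag
            if rng.random() < config.inpatient_fraction:
                pattern = [(first, "inpatient")]
            else:
                pattern = [(first, "outpatient"), (first + config.outpatient_gap, "outpatient")]
            for date, setting in pattern:
                if 0.0 <= date <= obs_end:
                    claims.append(ClaimRecord(rec.id, date, setting, C793))
        elif config.noise_fraction > 0 and rng.random() < config.noise_fraction:
            if obs_end > 0:
                claims.append(ClaimRecord(rec.id, rng.uniform(0.0, obs_end), "outpatient", C793))
    return claims


def diagnose_brain_metastasis(
    patient_claims: list[ClaimRecord],
) -> tuple[bool, float | None]:
    """Apply the claims rule: >=1 inpatient OR >=2 outpatient C793 claims.

    The diagnosis date is the earliest date at which the rule is satisfied
    (first inpatient claim, or second outpatient claim, whichever is earlier).
    """
    inpatient = sorted(
        c.service_date for c in patient_claims if c.code == C793 and c.setting == "inpatient"
    )
    outpatient = sorted(
        c.service_date for c in patient_claims if c.code == C793 and c.setting == "outpatient"
    )
    candidates = []
    if inpatient:
        candidates.append(inpatient[0])
    if len(outpatient) >= 2:
        candidates.append(outpatient[1])
    if not candidates:
        return False, None
    return True, min(candidates)


# ---------------------------------------------------------------------------
# endpoint derivation
# ---------------------------------------------------------------------------


def derive_endpoint_datasets(
    records: list[PatientRecord],
    claims: list[ClaimRecord],
    cutoff: float | None = None,
    config: SimulationConfig | None = None,
) -> dict[str, dict[str, EndpointDataset]]:
    """Derive the ten right-censored endpoints, per arm.

    All endpoints are defined in terms of the three events a claims extraction
    can observe — the first next-treatment (therapy switch) date, the
    claims-rule BM diagnosis date, and death — never the latent state path:

    * ``os``/``ttnt`` run from the index date over the whole cohort.
    * ``death_from_pf`` is death before any next treatment (the whole cohort is
      at risk from index; next treatment censors); ``death_from_pp`` is death
      after the next-treatment date (clock = switch date).  These two partition
      the observed deaths, which is what the three-state structure needs: its
      "PF" is simply pre-switch (BM status unobserved by that model).
    * The five-state refinements condition on the BM diagnosis: ``ttnt_from_pf``
      and ``bm_from_pf`` censor each other among patients with no BM history;
      ``bm_from_pp`` runs from the switch date; the BMIT endpoints run from the
      BM diagnosis date for patients diagnosed before any switch; and
      ``death_in_bmst`` runs from the later of diagnosis and switch.

    Censoring is applied at the study cut-off for every endpoint.  Returns
    ``{endpoint: {arm: EndpointDataset}}``; an empty at-risk set yields an
    empty dataset with a warning.
    """
    if cutoff is None:
        if config is None:
            raise ValueError("provide either cutoff or config")
        cutoff = config.study_cutoff
    if any(cutoff < r.index_date for r in records):
        raise ValueError("cutoff precedes some index dates")

    by_patient: dict[int, list[ClaimRecord]] = {}
    for c in claims:
        by_patient.setdefault(c.patient_id, []).append(c)

    rows: dict[str, list[tuple[int, str, float, bool]]] = {n: [] for n in ENDPOINT_NAMES}

    def add(name, rec, time, event):
        if time > 0:
            rows[name].append((rec.id, rec.arm, float(time), bool(event)))

    for rec in records:
        obs_end = cutoff - rec.index_date
        if obs_end <= 0:
            continue
        death = rec.death_time if rec.path[-1][0] == "Death" else np.inf
        nt_times = [t for s, t in rec.path if s in ("PP", "BMST")]
        t_nt = min(nt_times) if nt_times else np.inf
        diagnosed, bm_diag = diagnose_brain_metastasis(by_patient.get(rec.id, []))
        t_bm = bm_diag if diagnosed else np.inf

        # --- overall survival
        add("os", rec, min(death, obs_end), death <= obs_end)

        # --- time to next treatment (next systemic therapy or death)
        t_evt = min(t_nt, death)
        add("ttnt", rec, min(t_evt, obs_end), t_evt <= obs_end)

        # --- death before / after the switch (the 3-state model's clocks)
        stop = min(t_nt, death, obs_end)
        add("death_from_pf", rec, stop, death <= min(t_nt, obs_end))
        if t_nt < min(death, obs_end):
            add("death_from_pp", rec, min(death, obs_end) - t_nt, death <= obs_end)

        # --- five-state PF endpoints: no BM history, BM diagnosis censors
        if not rec.baseline_bm:
            pf_stop = min(t_bm, t_nt, death, obs_end)
            add("ttnt_from_pf", rec, pf_stop, min(t_nt, death) <= min(t_bm, obs_end))
            add("bm_from_pf", rec, pf_stop, t_bm <= min(t_nt, death, obs_end))

        # --- BM after the switch (PP -> BMST)
        if t_nt < min(t_bm, death, obs_end):
            pp_stop = min(t_bm, death, obs_end)
            add("bm_from_pp", rec, pp_stop - t_nt, t_bm <= min(death, obs_end))

        # --- BMIT endpoints: diagnosed before any switch (incl. baseline BM)
        if t_bm < min(t_nt, death) and t_bm < obs_end:
            bmit_stop = min(t_nt, death, obs_end)
            add("ttnt_in_bmit", rec, bmit_stop - t_bm, min(t_nt, death) <= obs_end)
            add("death_in_bmit", rec, bmit_stop - t_bm, death <= min(t_nt, obs_end))

        # --- death in BMST: both diagnosis and switch observed
        bmst_entry = max(t_bm, t_nt)
        if bmst_entry < min(death, obs_end):
            add("death_in_bmst", rec, min(death, obs_end) - bmst_entry, death <= obs_end)

    out: dict[str, dict[str, EndpointDataset]] = {}
    origins = {n: "state-entry" for n in ENDPOINT_NAMES}
    origins.update({"os": "index", "ttnt": "index", "death_from_pf": "index",
                    "ttnt_from_pf": "index", "bm_from_pf": "index"})
    for name in ENDPOINT_NAMES:
        out[name] = {}
        for arm in ("A", "B"):
            sel = [(i, t, e) for i, a, t, e in rows[name] if a == arm]
            if not sel:
                warnings.warn(f"endpoint {name!r}, arm {arm!r}: empty at-risk set")
                out[name][arm] = EndpointDataset(
                    name, np.empty(0), np.empty(0, dtype=bool), arm, origins[name],
                    ids=np.empty(0, dtype=int),
                )
                continue
            ids, times, events = zip(*sel)
            out[name][arm] = EndpointDataset(
                name,
                np.asarray(times, dtype=float),
                np.asarray(events, dtype=bool),
                arm,
                origins[name],
                ids=np.asarray(ids, dtype=int),
            )
    return out


# ---------------------------------------------------------------------------
# propensity matching
# ---------------------------------------------------------------------------


def standardized_mean_difference(xa: np.ndarray, xb: np.ndarray) -> float:
    """SMD with the pooled-variance denominator; 0 (with warning) when both
    arms are degenerate."""
    va, vb = np.var(xa, ddof=1) if xa.size > 1 else 0.0, np.var(xb, ddof=1) if xb.size > 1 else 0.0
    pooled = np.sqrt((va + vb) / 2.0)
    if pooled == 0:
        if np.mean(xa) != np.mean(xb):
            warnings.warn("zero-variance covariate with unequal means; SMD undefined, reporting 0")
        else:
            warnings.warn("zero-variance covariate; SMD reported as 0")
        return 0.0
    return float((np.mean(xa) - np.mean(xb)) / pooled)


def propensity_match(
    records: list[PatientRecord],
    covariates: tuple[str, ...] = ("age", "female"),
    caliper: float | None = None,
    scores: dict[int, float] | None = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on the logit of the propensity
    score, without replacement.

    The propensity model is a logistic regression of arm membership on the
    covariates.  Arm-A patients are processed in descending score order; each
    takes the closest unmatched arm-B patient on the logit scale, subject to
    the optional caliper (in logit units).  ``scores`` lets callers inject
    precomputed logit scores, bypassing the model.
    """
    a = [r for r in records if r.arm == "A"]
    b = [r for r in records if r.arm == "B"]
    if not a or not b:
        raise ValueError("matching needs at least one patient per arm")

    if scores is None:
        X = np.array([[float(getattr(r, c)) for c in covariates] for r in records])
        y = np.array([1.0 if r.arm == "A" else 0.0 for r in records])
        model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0)
        logit = fit.fittedvalues  # linear predictor = logit of the score
        scores = {r.id: float(s) for r, s in zip(records, logit)}

    a_sorted = sorted(a, key=lambda r: -scores[r.id])
    b_ids = np.array([r.id for r in b])
    b_scores = np.array([scores[r.id] for r in b])
    available = np.ones(len(b), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for ra in a_sorted:
        if not available.any():
            break
        d = np.abs(b_scores - scores[ra.id])
        d[~available] = np.inf
        j = int(np.argmin(d))
        if caliper is not None and d[j] > caliper:
            continue
        pairs.append((ra.id, int(b_ids[j])))
        available[j] = False
    if not pairs:
        raise ValueError("no matches possible under the caliper")

    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    smd_before, smd_after = {}, {}
    for c in covariates:
        xa = np.array([float(getattr(r, c)) for r in a])
        xb = np.array([float(getattr(r, c)) for r in b])
        smd_before[c] = standardized_mean_difference(xa, xb)
        xa_m = np.array([float(getattr(r, c)) for r in a if r.id in matched_a])
        xb_m = np.array([float(getattr(r, c)) for r in b if r.id in matched_b])
        smd_after[c] = standardized_mean_difference(xa_m, xb_m)
    return MatchResult(pairs, smd_before, smd_after, caliper)


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "arm": r.arm,
            "index_date": r.index_date,
            "female": int(r.female),
            "age": r.age,
            "baseline_bm": int(r.baseline_bm),
            "path": ";".join(f"{s}@{t:.10g}" for s, t in r.path),
        }
        for edge in EDGE_NAMES:
            row[f"latent_{edge}"] = r.latent.get(edge, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in df.iterrows():
        path = []
        for tok in row["path"].split(";"):
            s, t = tok.split("@")
            path.append((s, float(t)))
        latent = {
            e: float(row[f"latent_{e}"])
            for e in EDGE_NAMES
            if f"latent_{e}" in row and np.isfinite(row[f"latent_{e}"])
        }
        records.append(
            PatientRecord(
                id=int(row["id"]),
                arm=str(row["arm"]),
                index_date=float(row["index_date"]),
                female=bool(row["female"]),
                age=float(row["age"]),
                baseline_bm=bool(row["baseline_bm"]),
                latent=latent,
                path=path,
            )
        )
    return records


def claims_to_frame(claims: list[ClaimRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient_id": c.patient_id, "service_date": c.service_date,
             "setting": c.setting, "code": c.code}
            for c in claims
        ],
        columns=["patient_id", "service_date", "setting", "code"],
    )


def frame_to_claims(df: pd.DataFrame) -> list[ClaimRecord]:
    return [
        ClaimRecord(int(r.patient_id), float(r.service_date), str(r.setting), str(r.code))
        for r in df.itertuples()
    ]
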
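"""End-to-end study pipeline: synthesize → match → derive endpoints → fit →
select → trace (PSM / STM3 / STM5, both arms) → outcomes → comparison report.

Each stage reads and writes plain files under the output directory, so any
stage can be re-run from disk artifacts; ``run_study`` chains them and writes
a manifest with content digests for reproducibility checks.  One global seed
fans out to per-stage substreams (data generation is unaffected by changes in
later stages).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engines, outcomes, synthesize
from .engines import (
    DEFAULT_CYCLE_DAYS,
    DEFAULT_HORIZON_DAYS,
    YEAR_DAYS,
    CohortTrace,
    ModelStructure,
    build_trace,
)
from .fitting import (
    FAMILY_ORDER,
    EndpointDataset,
    FittedSurvivalModel,
    fit_all_families,
    km_estimate,
    select_best,
    test_proportional_hazards,
)
from .outcomes import DiscountSpec, UtilitySet, default_utilities, summarize
from .synthesize import SimulationConfig

log = logging.getLogger("oncostruct")

STRUCTURE_CURVES = {
    "PSM": engines.PSM_CURVES,
    "STM3": engines.STM3_CURVES,
    "STM5": engines.STM5_CURVES,
}


@dataclass
class StudyConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    families: tuple[str, ...] = FAMILY_ORDER
    selection_criterion: str = "aic"
    # endpoint -> family, stands in for visual-inspection overrides
    family_overrides: dict[str, str] = field(default_factory=dict)
    horizon_years: float = 7.0
    cycle_days: float = DEFAULT_CYCLE_DAYS
    competing_rule: str = "hazard_split"
    utilities: UtilitySet = field(default_factory=default_utilities)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    sensitivity_horizons: tuple[float, ...] = (5.0, 10.0)
    sensitivity_rates: tuple[float, ...] = (0.03, 0.075)
    sensitivity_utilities: tuple[UtilitySet, ...] = ()
    match_covariates: tuple[str, ...] = ("age", "female")
    match_caliper: float | None = None

    @property
    def horizon_days(self) -> float:
        return self.horizon_years * YEAR_DAYS

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        if "simulation" in d:
            sim = d["simulation"]
            if "hazards" in sim:
                sim["hazards"] = {
                    arm: {e: synthesize.HazardSpec(**s) for e, s in edges.items()}
                    for arm, edges in sim["hazards"].items()
                }
            kwargs["simulation"] = SimulationConfig(**sim)
        if "utilities" in d:
            u = d["utilities"]
            kwargs["utilities"] = UtilitySet(**u)
        if "discount_rate" in d:
            kwargs["discount"] = DiscountSpec(d["discount_rate"])
        for key in (
            "selection_criterion",
            "horizon_years",
            "cycle_days",
            "competing_rule",
            "family_overrides",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "families" in d:
            kwargs["families"] = tuple(d["families"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def simulate_stage(config: StudyConfig, outdir: Path) -> dict:
    """Generate cohorts and claims, propensity-match, derive the ten
    endpoints for the matched population, and write everything as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    records = synthesize.generate_cohorts(sim)
    claims = synthesize.emit_claims(records, sim)
    match = synthesize.propensity_match(
        records, covariates=config.match_covariates, caliper=config.match_caliper
    )
    matched_ids = {i for pair in match.pairs for i in pair}
    matched = [r for r in records if r.id in matched_ids]
    endpoints = synthesize.derive_endpoint_datasets(matched, claims, config=sim)

    synthesize.records_to_frame(records).to_csv(outdir / "patients.csv", index=False)
    synthesize.claims_to_frame(claims).to_csv(outdir / "claims.csv", index=False)
    with open(outdir / "match.json", "w") as fh:
        json.dump(
            {
                "n_pairs": len(match.pairs),
                "pairs": match.pairs,
                "smd_before": match.smd_before,
                "smd_after": match.smd_after,
                "caliper": match.caliper,
            },
            fh,
            indent=1,
        )
    epdir = outdir / "endpoints"
    epdir.mkdir(exist_ok=True)
    for name, arms in endpoints.items():
        frames = [ds.to_frame() for ds in arms.values() if len(ds)]
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["id", "time", "event", "arm"]
        )
        df.to_csv(epdir / f"{name}.csv", index=False)

    # observed baseline BM fraction among matched patients, per arm (STM5
    # initial distribution)
    bm_frac = {
        arm: float(np.mean([r.baseline_bm for r in matched if r.arm == arm]))
        for arm in ("A", "B")
    }
    with open(outdir / "baseline_bm.json", "w") as fh:
        json.dump(bm_frac, fh)
    log.info("simulate: %d records, %d claims, %d matched pairs", len(records), len(claims), len(match.pairs))
    return {"records": records, "claims": claims, "match": match, "endpoints": endpoints, "baseline_bm": bm_frac}


def load_endpoints(outdir: Path) -> dict[str, dict[str, EndpointDataset]]:
    out = {}
    for name in synthesize.ENDPOINT_NAMES:
        df = pd.read_csv(Path(outdir) / "endpoints" / f"{name}.csv")
        out[name] = {}
        for arm in ("A", "B"):
            sub = df[df["arm"] == arm] if len(df) else df
            out[name][arm] = EndpointDataset(
                name,
                sub["time"].to_numpy(dtype=float) if len(sub) else np.empty(0),
                sub["event"].to_numpy(dtype=bool) if len(sub) else np.empty(0, dtype=bool),
                arm,
            )
    return out


def fit_stage(config: StudyConfig, outdir: Path, endpoints=None) -> dict:
    """Fit the six families to every endpoint and arm, select per criterion,
    and write fits.json plus a ranking table."""
    outdir = Path(outdir)
    if endpoints is None:
        endpoints = load_endpoints(outdir)
    fits: dict[str, dict[str, FittedSurvivalModel]] = {}
    ranking_rows = []
    for name, arms in endpoints.items():
        fits[name] = {}
        for arm, ds in arms.items():
            if len(ds) == 0 or ds.n_events == 0:
                # no events observed: the curve is flat at 1 (the transition
                # never fires), represented by a zero-rate exponential
                log.warning("fit: %s/%s has no events; using a null curve", name, arm)
                fits[name][arm] = FittedSurvivalModel(
                    "exponential", [0.0], loglik=float("nan"),
                    n=len(ds), n_events=0, converged=True,
                )
                continue
            models = fit_all_families(ds, config.families)
            best, table = select_best(
                models,
                criterion=config.selection_criterion,
                override_family=config.family_overrides.get(name),
            )
            fits[name][arm] = best
            table.insert(0, "arm", arm)
            table.insert(0, "endpoint", name)
            table["selected"] = table["family"] == best.family
            ranking_rows.append(table)
    with open(outdir / "fits.json", "w") as fh:
        json.dump(
            {n: {a: m.to_json_dict() for a, m in arms.items()} for n, arms in fits.items()},
            fh,
            indent=1,
        )
    ranking = pd.concat(ranking_rows, ignore_index=True)
    ranking.to_csv(outdir / "fit_ranking.csv", index=False)
    log.info("fit: %d endpoint/arm curves fitted", sum(len(a) for a in fits.values()))
    return {"fits": fits, "ranking": ranking}


def load_fits(outdir: Path) -> dict[str, dict[str, FittedSurvivalModel]]:
    with open(Path(outdir) / "fits.json") as fh:
        raw = json.load(fh)
    return {
        n: {a: FittedSurvivalModel.from_json_dict(d) for a, d in arms.items()}
        for n, arms in raw.items()
    }


def build_structures(
    fits: dict[str, dict[str, FittedSurvivalModel]],
    baseline_bm: dict[str, float],
) -> dict[str, dict[str, ModelStructure]]:
    """Assemble the three ModelStructures per arm from fitted curves."""
    out: dict[str, dict[str, ModelStructure]] = {}
    for sname, curves in STRUCTURE_CURVES.items():
        out[sname] = {}
        for arm in ("A", "B"):
            models = {}
            for c in curves:
                if arm not in fits.get(c, {}):
                    raise ValueError(f"structure {sname}: no fitted curve {c!r} for arm {arm}")
                models[c] = fits[c][arm]
            f = baseline_bm.get(arm, 0.0) if sname == "STM5" else 0.0
            out[sname][arm] = ModelStructure(sname, models, initial_bm_fraction=f)
    return out


def trace_stage(config: StudyConfig, outdir: Path, fits=None, baseline_bm=None) -> dict:
    outdir = Path(outdir)
    if fits is None:
        fits = load_fits(outdir)
    if baseline_bm is None:
        with open(outdir / "baseline_bm.json") as fh:
            baseline_bm = json.load(fh)
    structures = build_structures(fits, baseline_bm)
    traces: dict[str, dict[str, CohortTrace]] = {}
    for sname, arms in structures.items():
        traces[sname] = {}
        for arm, structure in arms.items():
            tr = build_trace(
                structure, config.horizon_days, config.cycle_days, config.competing_rule
            )
            traces[sname][arm] = tr
            tr.to_frame().to_csv(outdir / f"trace_{sname.lower()}_{arm}.csv", index=False)
            for w in tr.warnings:
                log.warning("trace %s/%s: %s", sname, arm, w)
    return {"structures": structures, "traces": traces}


def outcomes_stage(config: StudyConfig, outdir: Path, structures=None) -> dict:
    outdir = Path(outdir)
    if structures is None:
        structures = build_structures(load_fits(outdir), json.load(open(outdir / "baseline_bm.json")))
    summaries: dict[str, outcomes.OutcomeSummary] = {}
    frames = []
    builders = {}
    for sname, arms in structures.items():

        def builder(h, c, _arms=arms):
            return (
                build_trace(_arms["A"], h, c, config.competing_rule),
                build_trace(_arms["B"], h, c, config.competing_rule),
            )

        builders[sname] = builder
        ta, tb = builder(config.horizon_days, config.cycle_days)
        s = summarize(ta, tb, config.utilities, config.discount)
        summaries[sname] = s
        f = s.to_frame()
        f.insert(0, "structure", sname)
        frames.append(f)
    outcome_table = pd.concat(frames, ignore_index=True)
    outcome_table.to_csv(outdir / "outcomes.csv", index=False)

    comparison = compare_structures(summaries)
    comparison.to_csv(outdir / "comparison.csv", index=False)

    sens = outcomes.sensitivity_grid(
        builders,
        config.utilities,
        config.discount,
        config.horizon_days,
        config.cycle_days,
        horizons_years=config.sensitivity_horizons,
        rates=config.sensitivity_rates,
        utility_sets=config.sensitivity_utilities,
    )
    sens.to_csv(outdir / "sensitivity.csv", index=False)
    return {"summaries": summaries, "outcomes": outcome_table, "comparison": comparison, "sensitivity": sens}


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


def round_half_away(x: float) -> float:
    return math.copysign(math.floor(abs(x) + 0.5), x)


def relative_difference_pct(value: float, reference: float) -> float | None:
    """100 × (value − reference)/reference, rounded half away from zero to an
    integer percent; None when the reference is zero."""
    if reference == 0:
        return None
    return round_half_away(100.0 * (value - reference) / reference)


def compare_structures(summaries: dict[str, "outcomes.OutcomeSummary"]) -> pd.DataFrame:
    """Pairwise relative differences of incremental LY and QALY between
    structures, as rounded integer percentages."""
    if len(summaries) < 2:
        raise ValueError("need at least two structures to compare")
    rows = []
    names = list(summaries)
    for name in names:
        s = summaries[name]
        row = {
            "structure": name,
            "incremental_ly": s.incremental("ly"),
            "incremental_qaly": s.incremental("qaly"),
        }
        for ref in names:
            if ref == name:
                continue
            r = summaries[ref]
            row[f"ly_vs_{ref}_pct"] = relative_difference_pct(
                s.incremental("ly"), r.incremental("ly")
            )
            row[f"qaly_vs_{ref}_pct"] = relative_difference_pct(
                s.incremental("qaly"), r.incremental("qaly")
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plots and manifest
# ---------------------------------------------------------------------------


def _plot_km_fits(endpoints, fits, outdir):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name in ("os", "ttnt"):
        fig, ax = plt.subplots(figsize=(6, 4))
        tmax = 0.0
        for arm, color in (("A", "C0"), ("B", "C1")):
            ds = endpoints[name][arm]
            if len(ds) == 0:
                continue
            km = km_estimate(ds)
            ax.step(km.times, km.survival, where="post", color=color, label=f"arm {arm} KM")
            tmax = max(tmax, km.times.max())
            if arm in fits.get(name, {}):
                grid = np.linspace(0, DEFAULT_HORIZON_DAYS, 300)
                ax.plot(grid, fits[name][arm].sf(grid), color=color, ls="--",
                        label=f"arm {arm} {fits[name][arm].family}")
        ax.set_xlabel("days from index")
        ax.set_ylabel("S(t)")
        ax.set_title(name.upper())
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(Path(outdir) / f"km_fit_{name}.png", dpi=120)
        plt.close(fig)


def _plot_occupancy(traces, outdir):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, arm in zip(axes, ("A", "B")):
        for sname, style in (("PSM", ":"), ("STM3", "--"), ("STM5", "-")):
            tr = traces[sname][arm]
            years = tr.times / YEAR_DAYS
            if sname == "STM5":
                # PF+BMIT combined and PP+BMST combined, to align with the
                # three-state structures
                pf = tr.state("PF") + tr.state("BMIT")
                pp = tr.state("PP") + tr.state("BMST")
            else:
                pf, pp = tr.state("PF"), tr.state("PP")
            ax.plot(years, pf, "C0" + style, label=f"{sname} PF(+BMIT)")
            ax.plot(years, pp, "C1" + style, label=f"{sname} PP(+BMST)")
            ax.plot(years, tr.state("Death"), "C2" + style, label=f"{sname} Death")
        ax.set_title(f"arm {arm}")
        ax.set_xlabel("years")
    axes[0].set_ylabel("occupancy")
    axes[0].legend(fontsize=6, ncol=3)
    fig.tight_layout()
    fig.savefig(Path(outdir) / "occupancy.png", dpi=120)
    plt.close(fig)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig, outdir, make_plots: bool = True) -> dict:
    """Execute the full study and return the manifest (also written to
    manifest.json).  Rerunning with the same config and seed reproduces
    identical file digests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_seen: list[str] = []

    sim_out = simulate_stage(config, outdir)
    fit_out = fit_stage(config, outdir, endpoints=sim_out["endpoints"])
    trace_out = trace_stage(config, outdir, fits=fit_out["fits"], baseline_bm=sim_out["baseline_bm"])
    for sname, arms in trace_out["traces"].items():
        for arm, tr in arms.items():
            warnings_seen += [f"{sname}/{arm}: {w}" for w in tr.warnings]
    nonconv = fit_out["ranking"].query("~converged")
    warnings_seen += [
        f"non-converged fit: {r.endpoint}/{r.arm}/{r.family}" for r in nonconv.itertuples()
    ]
    out_out = outcomes_stage(config, outdir, structures=trace_out["structures"])

    # Table-1-style input listing
    inputs = {
        "n_per_arm": config.simulation.n_per_arm,
        "female_fraction": config.simulation.female_fraction,
        "age_mean": config.simulation.age_mean,
        "horizon_years": config.horizon_years,
        "cycle_days": config.cycle_days,
        "discount_rate": config.discount.annual_rate,
        "utilities": config.utilities.to_dict(),
        "selected_families": {
            n: {a: m.family for a, m in arms.items()} for n, arms in fit_out["fits"].items()
        },
        "baseline_bm_fraction_observed": sim_out["baseline_bm"],
    }
    with open(outdir / "inputs.json", "w") as fh:
        json.dump(inputs, fh, indent=1)

    if make_plots:
        _plot_km_fits(sim_out["endpoints"], fit_out["fits"], outdir)
        _plot_occupancy(trace_out["traces"], outdir)

    cfg_hash = hashlib.sha256(
        json.dumps(inputs, sort_keys=True, default=str).encode()
    ).hexdigest()
    digests = {
        p.name: _digest(p)
        for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json"))
        if p.name != "manifest.json"
    }
    import oncostruct

    manifest = {
        "config_hash": cfg_hash,
        "seed": config.simulation.seed,
        "digests": digests,
        "warnings": warnings_seen,
        "versions": {"oncostruct": oncostruct.__version__, "numpy": np.__version__},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {
        "manifest": manifest,
        "summaries": out_out["summaries"],
        "comparison": out_out["comparison"],
        "sensitivity": out_out["sensitivity"],
        "fits": fit_out["fits"],
        "traces": trace_out["traces"],
        "match": sim_out["match"],
    }
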
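"""Synthetic cohort generation, claims rule, endpoint derivation, matching."""

import numpy as np
import pytest

from oncostruct.fitting import km_estimate, EndpointDataset
from oncostruct.synthesize import (
    ClaimRecord,
    ConfigError,
    HazardSpec,
    PatientRecord,
    SimulationConfig,
    derive_endpoint_datasets,
    diagnose_brain_metastasis,
    emit_claims,
    generate_cohorts,
    propensity_match,
    records_to_frame,
    frame_to_records,
)


def zero_death_config(**kw):
    cfg = SimulationConfig(n_per_arm=kw.pop("n_per_arm", 50), **kw)
    for arm in ("A", "B"):
        for edge in ("pf_death", "pp_death", "bmit_death", "bmst_death"):
            cfg.hazards[arm][edge] = HazardSpec("exponential", rate=0.0)
    return cfg


class TestGenerateCohorts:
    def test_counts_and_arms(self):
        cfg = SimulationConfig(n_per_arm=735, seed=42)
        recs = generate_cohorts(cfg)
        assert len(recs) == 1470
        assert sum(r.arm == "A" for r in recs) == 735
        assert sum(r.arm == "B" for r in recs) == 735

    def test_determinism(self):
        cfg = SimulationConfig(n_per_arm=60, seed=9)
        a = records_to_frame(generate_cohorts(cfg))
        b = records_to_frame(generate_cohorts(SimulationConfig(n_per_arm=60, seed=9)))
        assert a.equals(b)

    def test_zero_death_hazard_no_deaths(self):
        recs = generate_cohorts(zero_death_config(seed=3))
        assert all(r.path[-1][0] != "Death" for r in recs)

    def test_exponential_death_mean(self):
        """Pure exponential death at 0.001/day with everything else off: the
        sample mean OS is within 3 SE of the closed-form mean 1000 days."""
        cfg = SimulationConfig(n_per_arm=5000, seed=8, baseline_bm_fraction=0.0)
        for arm in ("A", "B"):
            for edge in cfg.hazards[arm]:
                cfg.hazards[arm][edge] = HazardSpec("exponential", rate=0.0)
            cfg.hazards[arm]["pf_death"] = HazardSpec("exponential", rate=0.001)
        recs = generate_cohorts(cfg)
        times = np.array([r.death_time for r in recs])
        se = 1000.0 / np.sqrt(times.size)
        assert abs(times.mean() - 1000.0) < 3 * se

    def test_path_consistent_with_latent_minimum(self):
        """The transition out of PF equals the smallest competing latent time
        (first-visit check; deeper clocks are overwritten on re-entry draws)."""
        from oncostruct.synthesize import OUT_EDGES

        recs = generate_cohorts(SimulationConfig(n_per_arm=150, seed=13))
        for r in recs:
            state, entry = r.path[0]
            if state == "Death" or len(r.path) < 2:
                continue
            draws = {tgt: r.latent[e] for tgt, e in OUT_EDGES[state] if e in r.latent}
            nxt_state, nxt_t = r.path[1]
            assert nxt_state == min(draws, key=draws.get)
            assert nxt_t - entry == pytest.approx(min(draws.values()))

    def test_baseline_bm_starts_in_bmit(self):
        recs = generate_cohorts(SimulationConfig(n_per_arm=200, seed=2))
        for r in recs:
            assert r.path[0][0] == ("BMIT" if r.baseline_bm else "PF")

    def test_invalid_hazard_names_edge(self):
        cfg = SimulationConfig(n_per_arm=5)
        cfg.hazards["A"]["pp_death"] = HazardSpec("weibull", shape=-1.0, scale=100.0)
        with pytest.raises(ConfigError, match="pp_death"):
            generate_cohorts(cfg)


class TestClaimsRule:
    def test_single_outpatient_not_diagnosed(self):
        flag, date = diagnose_brain_metastasis([ClaimRecord(1, 10.0, "outpatient", "C793")])
        assert (flag, date) == (False, None)

    def test_single_inpatient_diagnosed(self):
        flag, date = diagnose_brain_metastasis([ClaimRecord(1, 30.0, "inpatient", "C793")])
        assert (flag, date) == (True, 30.0)

    def test_earliest_qualifying_date_wins(self):
        claims = [
            ClaimRecord(1, 10.0, "outpatient", "C793"),
            ClaimRecord(1, 40.0, "outpatient", "C793"),
            ClaimRecord(1, 50.0, "inpatient", "C793"),
        ]
        assert diagnose_brain_metastasis(claims) == (True, 40.0)

    def test_bm_patients_get_qualifying_pattern(self):
        cfg = SimulationConfig(n_per_arm=150, seed=4)
        recs = generate_cohorts(cfg)
        claims = emit_claims(recs, cfg)
        by_pat = {}
        for c in claims:
            by_pat.setdefault(c.patient_id, []).append(c)
        for r in recs:
            if r.baseline_bm:  # BM entry at day 0, claims cannot be clamped out
                pats = by_pat.get(r.id, [])
                inp = sum(c.setting == "inpatient" for c in pats)
                outp = sum(c.setting == "outpatient" for c in pats)
                death = r.death_time if r.path[-1][0] == "Death" else np.inf
                window = min(cfg.study_cutoff - r.index_date, death)
                if window > cfg.outpatient_gap:
                    assert inp >= 1 or outp >= 2

    def test_noise_fraction_zero_means_no_never_bm_claims(self):
        cfg = zero_death_config(seed=5, noise_fraction=0.0)
        recs = generate_cohorts(cfg)
        claims = emit_claims(recs, cfg)
        bm_ids = {r.id for r in recs if any(s in ("BMIT", "BMST") for s, _ in r.path)}
        assert all(c.patient_id in bm_ids for c in claims)

    def test_noise_count_binomial(self):
        """~10% of 5000 never-BM patients carry a single outpatient claim."""
        cfg = SimulationConfig(n_per_arm=2500, seed=6, noise_fraction=0.1,
                               baseline_bm_fraction=0.0)
        for arm in ("A", "B"):
            cfg.hazards[arm]["pf_bm"] = HazardSpec("exponential", rate=0.0)
            cfg.hazards[arm]["pp_bm"] = HazardSpec("exponential", rate=0.0)
        recs = generate_cohorts(cfg)
        claims = emit_claims(recs, cfg)
        carriers = {c.patient_id for c in claims}
        n, p = 5000, 0.1
        se = np.sqrt(n * p * (1 - p))
        assert abs(len(carriers) - n * p) < 3 * se
        counts = {pid: sum(c.patient_id == pid for c in claims) for pid in carriers}
        assert set(counts.values()) == {1}


class TestEndpointDerivation:
    @staticmethod
    def _patient(pid, arm, path, index=0.0, baseline_bm=False):
        return PatientRecord(pid, arm, index, False, 65.0, baseline_bm, {}, path)

    def test_hand_computed_three_patient_fixture(self):
        """Three hand-written paths with hand-derived ten-endpoint rows.

        Cut-off day 1000, all indices at 0, claims emitted by hand:
          P0 (A): PF -> PP(100) -> Death(400); no BM claims.
          P1 (A): PF -> BMIT(200) -> BMST(500) -> Death(800); inpatient claim
                  at 200.
          P2 (B): PF, alive and untreated past cut-off; one outpatient claim
                  (noise) at 300.
        """
        p0 = self._patient(0, "A", [("PF", 0.0), ("PP", 100.0), ("Death", 400.0)])
        p1 = self._patient(
            1, "A", [("PF", 0.0), ("BMIT", 200.0), ("BMST", 500.0), ("Death", 800.0)]
        )
        p2 = self._patient(2, "B", [("PF", 0.0)])
        claims = [
            ClaimRecord(1, 200.0, "inpatient", "C793"),
            ClaimRecord(2, 300.0, "outpatient", "C793"),
        ]
        eps = derive_endpoint_datasets([p0, p1, p2], claims, cutoff=1000.0)

        def rows(name, arm):
            ds = eps[name][arm]
            return sorted(zip(ds.ids, ds.time, ds.event))

        # OS: deaths at 400 and 800; P2 censored at 1000
        assert rows("os", "A") == [(0, 400.0, True), (1, 800.0, True)]
        assert rows("os", "B") == [(2, 1000.0, False)]
        # TTNT: P0 switches at 100; P1 switches at 500 (BMST); P2 censored
        assert rows("ttnt", "A") == [(0, 100.0, True), (1, 500.0, True)]
        assert rows("ttnt", "B") == [(2, 1000.0, False)]
        # death before any switch: censored at switch for P0/P1
        assert rows("death_from_pf", "A") == [(0, 100.0, False), (1, 500.0, False)]
        assert rows("death_from_pf", "B") == [(2, 1000.0, False)]
        # death from switch date: P0 400-100, P1 800-500
        assert rows("death_from_pp", "A") == [(0, 300.0, True), (1, 300.0, True)]
        assert rows("death_from_pp", "B") == []
        # five-state PF endpoints: P1 censored by BM diagnosis at 200
        assert rows("ttnt_from_pf", "A") == [(0, 100.0, True), (1, 200.0, False)]
        assert rows("bm_from_pf", "A") == [(0, 100.0, False), (1, 200.0, True)]
        assert rows("bm_from_pf", "B") == [(2, 1000.0, False)]
        # BM after switch: only P0 enters PP without BM; no event
        assert rows("bm_from_pp", "A") == [(0, 300.0, False)]
        # BMIT endpoints: P1 from diagnosis 200 to switch 500
        assert rows("ttnt_in_bmit", "A") == [(1, 300.0, True)]
        assert rows("death_in_bmit", "A") == [(1, 300.0, False)]
        # BMST: P1 from 500 to death 800
        assert rows("death_in_bmst", "A") == [(1, 300.0, True)]

    def test_death_without_next_treatment_is_ttnt_event(self):
        p = self._patient(0, "A", [("PF", 0.0), ("Death", 100.0)])
        eps = derive_endpoint_datasets([p], [], cutoff=1000.0)
        assert list(eps["ttnt"]["A"].time) == [100.0]
        assert list(eps["ttnt"]["A"].event) == [True]

    def test_alive_untreated_censored_at_cutoff(self):
        p = self._patient(0, "A", [("PF", 0.0)], index=200.0)
        eps = derive_endpoint_datasets([p], [], cutoff=1000.0)
        assert list(eps["ttnt"]["A"].time) == [800.0]
        assert list(eps["ttnt"]["A"].event) == [False]

    def test_censoring_monotonicity(self):
        """Raising the cut-off never decreases any endpoint's event count."""
        cfg = SimulationConfig(n_per_arm=250, seed=10)
        recs = generate_cohorts(cfg)
        claims = emit_claims(recs, cfg)
        lo = derive_endpoint_datasets(recs, claims, cutoff=1400.0)
        hi = derive_endpoint_datasets(recs, claims, cutoff=2200.0)
        for name in lo:
            for arm in ("A", "B"):
                assert hi[name][arm].n_events >= lo[name][arm].n_events

    def test_deaths_partition_between_pre_and_post_switch(self):
        """Every observed death is attributed to exactly one clock: OS events
        = death-before-switch + death-after-switch; BM-state deaths nest
        inside those."""
        cfg = SimulationConfig(n_per_arm=300, seed=11)
        recs = generate_cohorts(cfg)
        claims = emit_claims(recs, cfg)
        eps = derive_endpoint_datasets(recs, claims, config=cfg)
        for arm in ("A", "B"):
            os_ev = eps["os"][arm].n_events
            assert os_ev == eps["death_from_pf"][arm].n_events + eps["death_from_pp"][arm].n_events
            assert eps["death_in_bmit"][arm].n_events <= eps["death_from_pf"][arm].n_events
            assert eps["death_in_bmst"][arm].n_events <= eps["death_from_pp"][arm].n_events

    def test_empty_at_risk_set_warns_not_crashes(self):
        p = self._patient(0, "A", [("PF", 0.0)])
        with pytest.warns(UserWarning, match="empty at-risk"):
            eps = derive_endpoint_datasets([p], [], cutoff=100.0)
        assert len(eps["death_in_bmst"]["B"]) == 0

    def test_km_converges_to_true_all_cause_survival(self):
        """At n=20000 the OS Kaplan–Meier tracks the all-cause survival
        implied by the exponential hazard spec (five-state phase-type curve
        computed by fine-step matrix powers) within a Greenwood-style band."""
        from oracles import stm5_matrix_power

        cfg = SimulationConfig(n_per_arm=10000, seed=14, noise_fraction=0.0)
        recs = generate_cohorts(cfg)
        for arm in ("A", "B"):
            sub = [r for r in recs if r.arm == arm]
            times = np.array([r.death_time for r in sub])
            ds = EndpointDataset("os", times, np.ones(times.size, dtype=bool))
            km = km_estimate(ds)
            rates = {k: cfg.hazards[arm][k].rate for k in cfg.hazards[arm]}
            # the TTNT curves count "next treatment OR death", so their
            # cause-specific rates are sums of the underlying edge rates
            curve_rates = {
                "ttnt_from_pf": rates["pf_next_treatment"] + rates["pf_death"],
                "death_from_pf": rates["pf_death"],
                "bm_from_pf": rates["pf_bm"],
                "death_from_pp": rates["pp_death"],
                "bm_from_pp": rates["pp_bm"],
                "ttnt_in_bmit": rates["bmit_next_treatment"] + rates["bmit_death"],
                "death_in_bmit": rates["bmit_death"],
                "death_in_bmst": rates["bmst_death"],
            }
            dt = 0.25
            T = int(3000 / dt)
            truth = stm5_matrix_power(curve_rates, cfg.baseline_bm_fraction, T, dt)
            grid = np.arange(T + 1) * dt
            alive = 1.0 - truth[:, 4]
            check = np.linspace(100, 2900, 15)
            for t in check:
                s_true = np.interp(t, grid, alive)
                se = np.sqrt(s_true * (1 - s_true) / len(sub))
                assert abs(km.sf(t) - s_true) < 4 * se + 0.004


class TestPropensityMatching:
    def test_hand_set_scores_greedy_order(self):
        """Scores {A: .9, .2}, {B: .85, .25}: descending-order greedy pairs
        (A.9, B.85) then (A.2, B.25)."""
        recs = [
            PatientRecord(0, "A", 0, False, 65, False, {}, [("PF", 0.0)]),
            PatientRecord(1, "A", 0, False, 65, False, {}, [("PF", 0.0)]),
            PatientRecord(2, "B", 0, False, 65, False, {}, [("PF", 0.0)]),
            PatientRecord(3, "B", 0, False, 65, False, {}, [("PF", 0.0)]),
        ]
        scores = {0: 0.9, 1: 0.2, 2: 0.85, 3: 0.25}
        res = propensity_match(recs, covariates=("age",), scores=scores)
        assert sorted(res.pairs) == [(0, 2), (1, 3)]

    def test_balanced_cohort_smd_below_threshold(self):
        """Covariates drawn from identical distributions at n=735/arm: all
        post-match SMDs < 0.1."""
        recs = generate_cohorts(SimulationConfig(n_per_arm=735, seed=15))
        res = propensity_match(recs)
        assert all(abs(v) < 0.1 for v in res.smd_after.values())
        assert len(res.pairs) == 735

    def test_each_id_used_at_most_once(self):
        recs = generate_cohorts(SimulationConfig(n_per_arm=100, seed=16))
        res = propensity_match(recs)
        ids = [i for p in res.pairs for i in p]
        assert len(ids) == len(set(ids))

    def test_degenerate_covariate_warns_smd_zero(self):
        recs = [
            PatientRecord(0, "A", 0, True, 65, False, {}, [("PF", 0.0)]),
            PatientRecord(1, "B", 0, True, 65, False, {}, [("PF", 0.0)]),
        ]
        with pytest.warns(UserWarning):
            res = propensity_match(recs, covariates=("age",), scores={0: 0.5, 1: 0.5})
        assert res.smd_before["age"] == 0.0

    def test_caliper_blocks_distant_pairs(self):
        recs = [
            PatientRecord(0, "A", 0, False, 60, False, {}, [("PF", 0.0)]),
            PatientRecord(1, "B", 0, False, 60, False, {}, [("PF", 0.0)]),
            PatientRecord(2, "A", 0, False, 60, False, {}, [("PF", 0.0)]),
            PatientRecord(3, "B", 0, False, 60, False, {}, [("PF", 0.0)]),
        ]
        scores = {0: 2.0, 1: 1.95, 2: -1.0, 3: 0.5}
        res = propensity_match(recs, covariates=("age",), caliper=0.2, scores=scores)
        assert res.pairs == [(0, 1)]


def test_csv_round_trip():
    cfg = SimulationConfig(n_per_arm=40, seed=17)
    recs = generate_cohorts(cfg)
    df = records_to_frame(recs)
    back = frame_to_records(df)
    assert len(back) == len(recs)
    r0, b0 = recs[0], back[0]
    assert [s for s, _ in r0.path] == [s for s, _ in b0.path]
    np.testing.assert_allclose([t for _, t in r0.path], [t for _, t in b0.path])
    assert r0.latent.keys() == b0.latent.keys()
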
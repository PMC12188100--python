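import numpy as np
import pytest

import t2dsim as t
from t2dsim.engine import EVENT_ORDER, _EIDX
from t2dsim.errors import StateError

from conftest import constant_prob_table


def _run(cohort, table, horizon, seed, **kw):
    return t.simulate_cohort(cohort, table, horizon, seed, **kw)


class TestEventOrderRandomisation:
    def test_single_event_identity(self):
        rng = np.random.default_rng(1)
        assert t.randomize_event_order(["MI"], rng) == ["MI"]

    def test_empty(self):
        rng = np.random.default_rng(1)
        assert t.randomize_event_order([], rng) == []

    def test_uniform_over_orderings(self):
        rng = np.random.default_rng(2)
        counts = {}
        n = 60_000
        for _ in range(n):
            perm = tuple(t.randomize_event_order(["a", "b", "c"], rng))
            counts[perm] = counts.get(perm, 0) + 1
        assert len(counts) == 6
        bound = 3 * np.sqrt((1 / 6) * (5 / 6) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 6) < bound

    def test_engine_permutations_uniform(self, toy_cohort, table):
        # the engine's keyed permutation of candidate events is uniform too
        from t2dsim import streams
        keys = streams.patient_keys(3, "perm-test", 60_000)
        u = np.stack([streams.uniforms(keys, 1, 0, j) for j in range(3)],
                     axis=1)
        perms = np.argsort(u, axis=1)
        codes = perms[:, 0] * 9 + perms[:, 1] * 3 + perms[:, 2]
        _, counts = np.unique(codes, return_counts=True)
        assert len(counts) == 6
        bound = 3 * np.sqrt((1 / 6) * (5 / 6) / 60_000)
        assert np.all(np.abs(counts / 60_000 - 1 / 6) < bound)


class TestNullAndForcedDynamics:
    def test_null_dynamics(self, toy_cohort, table):
        tt = constant_prob_table(table, p_event=0.0, p_mort=0.0, p_jump=0.0)
        res = _run(toy_cohort, tt, 5, 1)
        assert not res.events.any()
        assert not res.died.any()
        assert res.alive_start.all()

    def test_immediate_death(self, toy_cohort, table):
        tt = constant_prob_table(table, p_event=0.0, p_mort=1.0)
        trajs = _run(toy_cohort, tt, 5, 1).to_trajectories()
        for traj in trajs:
            assert len(traj.records) == 1
            assert traj.records[0].died
            assert traj.death_year == 0

    def test_zero_mortality_full_horizon(self, toy_cohort, table):
        tt = constant_prob_table(table, p_event=0.0, p_mort=0.0, p_jump=0.0)
        trajs = _run(toy_cohort, tt, 7, 1).to_trajectories()
        assert all(len(traj.records) == 7 for traj in trajs)

    def test_acute_event_cap_enforced(self, cfg, table):
        # MI forced certain: occurs in years 0 and 1 (first/second equation),
        # never again
        tt = constant_prob_table(table, p_event=0.0, p_mort=0.0, p_jump=0.0,
                                 t2dm_mi1=1.0, t2dm_mi2=1.0)
        cohort, _ = t.make_fixture_cohort("uk_t2dm_like", 20, 1, cfg)
        res = _run(cohort, tt, 6, 1)
        mi = res.events[:, :, _EIDX["MI"]]
        assert mi[0].all() and mi[1].all()
        assert not mi[2:].any()

    def test_chronic_event_occurs_once(self, cfg, table):
        tt = constant_prob_table(table, p_event=0.0, p_mort=0.0, p_jump=0.0,
                                 t2dm_chf=1.0)
        cohort, _ = t.make_fixture_cohort("uk_t2dm_like", 20, 1, cfg)
        res = _run(cohort, tt, 6, 1)
        chf = res.events[:, :, _EIDX["CHF"]]
        assert chf[0].all() and not chf[1:].any()

    def test_ngt_acute_once_only(self, cfg, table):
        tt = constant_prob_table(table, p_event=0.0, p_mort=0.0, p_jump=0.0,
                                 ngt_mi=1.0)
        cohort, _ = t.make_fixture_cohort("dppos_like", 30, 1, cfg)
        res = _run(cohort, tt, 5, 1)
        mi = res.events[:, :, _EIDX["MI"]]
        started_ngt = ~res.t2dm_start[0]
        assert mi[0, started_ngt].all()
        # patients who stay NGT never repeat the event
        stay_ngt = ~res.t2dm_start.any(axis=0)
        assert not mi[1:, stay_ngt].any()


class TestStateTransitions:
    def test_jump_transitions_to_t2dm_next_cycle(self, toy_patient, table):
        tt = constant_prob_table(table, p_event=0.0, p_mort=0.0, p_jump=1.0)
        patient = toy_patient(hba1c=6.2)
        traj = t.simulate_patient(patient, tt, 3, 9)
        assert traj.records[0].state_at_start == t.NGT_PRE
        assert traj.records[0].risk_factors_end.hba1c == pytest.approx(6.74)
        assert traj.records[1].state_at_start == t.T2DM

    def test_t2dm_absorbing(self, cfg, table):
        # even if the progression equation pulls HbA1c below threshold,
        # classification never reverts
        d = table.to_dict()
        d["risk_factor_equations"]["hba1c@T2DM"] = {
            "form": "linear_update", "applicable_state": "T2DM",
            "coefficients": {"intercept": 5.0},    # drives HbA1c to 5.0
        }
        tt = constant_prob_table(type(table).from_dict(d),
                                 p_event=0.0, p_mort=0.0, p_jump=0.0)
        cohort, _ = t.make_fixture_cohort("uk_t2dm_like", 10, 1, cfg)
        res = _run(cohort, tt, 4, 1)
        assert res.t2dm_start.all()

    def test_duration_increments_only_in_t2dm(self, toy_patient, table):
        tt = constant_prob_table(table, p_event=0.0, p_mort=0.0, p_jump=1.0)
        patient = toy_patient(hba1c=6.2)
        t.simulate_year(patient, tt, seed=3, year_index=0)
        assert patient.years_since_t2dm == 0          # still pre-diabetic
        t.simulate_year(patient, tt, seed=3, year_index=1)
        assert patient.state == t.T2DM
        assert patient.years_since_t2dm == 1


class TestDeterminismAndIndependence:
    def test_same_seed_bit_identical(self, cfg, table):
        cohort, _ = t.make_fixture_cohort("toy", 8, 3, cfg)
        a = _run(cohort, table, 10, 17)
        b = _run(cohort, table, 10, 17)
        assert np.array_equal(a.events, b.events)
        assert np.array_equal(a.died, b.died)
        for f in a.rf_end:
            assert np.array_equal(a.rf_end[f], b.rf_end[f])

    def test_patient_order_invariance(self, cfg, table):
        cohort, _ = t.make_fixture_cohort("toy", 8, 3, cfg)
        res = _run(cohort, table, 8, 5)
        perm = np.array([5, 2, 7, 0, 1, 6, 3, 4])
        res_p = _run(cohort.subset(perm), table, 8, 5)
        assert np.array_equal(res.events[:, perm, :], res_p.events)
        assert np.array_equal(res.death_year[perm], res_p.death_year)

    def test_cohort_of_one_matches_batch(self, cfg, table):
        cohort, _ = t.make_fixture_cohort("toy", 5, 3, cfg)
        batch = _run(cohort, table, 6, 11).to_trajectories()
        for i in range(5):
            solo = t.simulate_patient(cohort[i], table, 6, 11)
            assert len(solo.records) == len(batch[i].records)
            for ra, rb in zip(solo.records, batch[i].records):
                assert ra.events == rb.events
                assert ra.died == rb.died
                assert ra.risk_factors_end == rb.risk_factors_end

    def test_simulate_year_reproduces_simulate_patient(self, cfg, table):
        cohort, _ = t.make_fixture_cohort("toy", 3, 4, cfg)
        for i in range(3):
            ref = t.simulate_patient(cohort[i], table, 5, 13)
            patient = cohort[i]
            for year, ref_rec in enumerate(ref.records):
                rec = t.simulate_year(patient, table, seed=13,
                                      year_index=year)
                assert rec.events == ref_rec.events
                assert rec.died == ref_rec.died
                assert rec.risk_factors_end == ref_rec.risk_factors_end
                if rec.died:
                    break

    def test_dead_patient_rejected(self, toy_patient, table):
        patient = toy_patient()
        patient.alive = False
        with pytest.raises(StateError):
            t.simulate_year(patient, table, seed=1)

    def test_empty_cohort(self, table):
        from t2dsim.cohort import ALL_FIELDS, Cohort
        empty = Cohort({f: np.array([]) for f in ALL_FIELDS})
        assert _run(empty, table, 5, 1).n == 0


class TestInvariants:
    def test_no_activity_after_death(self, cfg, table):
        cohort, _ = t.make_fixture_cohort("uk_t2dm_like", 300, 5, cfg)
        res = _run(cohort, table, 15, 5)
        for i in np.nonzero(res.death_year >= 0)[0][:50]:
            dy = res.death_year[i]
            assert not res.alive_start[dy + 1:, i].any()
            assert not res.events[dy + 1:, i, :].any()

    def test_chronic_monotonic_and_caps_fuzzed(self, cfg, table):
        # ~10^5 patient-years across both layers and mixed states
        cohort, _ = t.make_fixture_cohort("toy", 5000, 23, cfg)
        res = _run(cohort, table, 20, 23)
        assert res.alive_start.sum() >= 50_000
        for ev in ("CHF", "IHD", "BLINDNESS", "RENAL_FAILURE", "ULCER"):
            per_patient = res.events[:, :, _EIDX[ev]].sum(axis=0)
            assert per_patient.max() <= 1
        for ev in ("MI", "STROKE", "AMPUTATION"):
            e = _EIDX[ev]
            t2dm_counts = (res.events[:, :, e]
                           & res.t2dm_start).sum(axis=0)
            ngt_counts = (res.events[:, :, e]
                          & ~res.t2dm_start).sum(axis=0)
            assert t2dm_counts.max() <= 2
            if ev != "AMPUTATION":
                assert ngt_counts.max() <= 1
            else:
                assert ngt_counts.max() == 0
        # no event after death, no state reversal
        assert not (res.events.any(axis=2) & ~res.alive_start).any()
        started = res.t2dm_start.astype(int)
        assert np.all(np.diff(started, axis=0)[res.alive_start[1:]] >= 0)

    def test_marginal_event_frequency_matches_enumeration(self, cfg, table):
        # two candidate events with state-independent probabilities: the
        # randomised ordering must not change marginal frequencies, which a
        # brute-force enumeration gives as exactly p per event
        p1, p2 = 0.3, 0.6
        tt = constant_prob_table(table, p_event=0.0, p_mort=0.0, p_jump=0.0,
                                 t2dm_chf=p1, t2dm_ihd=p2)
        cohort, _ = t.make_fixture_cohort("uk_t2dm_like", 20_000, 31, cfg)
        res = _run(cohort, tt, 1, 31)
        f1 = res.events[0, :, _EIDX["CHF"]].mean()
        f2 = res.events[0, :, _EIDX["IHD"]].mean()
        n = 20_000
        assert abs(f1 - p1) < 3 * np.sqrt(p1 * (1 - p1) / n)
        assert abs(f2 - p2) < 3 * np.sqrt(p2 * (1 - p2) / n)
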
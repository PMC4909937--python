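"""Cage controller: state machine, reward economics, scheduling, colony."""

import math

import numpy as np
import pytest

from mesocage import controller as ctl


@pytest.fixture
def config():
    return ctl.CageConfig()


def make_state(**kw):
    return ctl.CageState(**kw)


# ---------------------------------------------------------------------------
# rig analytics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("lift,angle,expected", [
    (1.2, 30.0, 5.9),      # deployed solenoids at the bar contact angle
    (2.0, 30.0, 9.8),
])
def test_holding_force_values(lift, angle, expected):
    assert ctl.holding_force(lift, angle) == pytest.approx(expected, abs=0.05)


def test_holding_force_full_transfer_at_90_degrees():
    assert ctl.holding_force(3.3, 90.0) == pytest.approx(3.3 * 9.81)


@pytest.mark.parametrize("lift,angle", [(-1, 30), (1.2, 0), (1.2, 120)])
def test_holding_force_domain_errors(lift, angle):
    with pytest.raises(ValueError):
        ctl.holding_force(lift, angle)


# ---------------------------------------------------------------------------
# state machine
# ---------------------------------------------------------------------------


def run_visit(config, rng, t0=0.0, tag="M1"):
    state = make_state()
    events = []
    state, ev = ctl.step_state_machine(state, ctl.Event(t0, tag, "entry"),
                                       config, rng)
    events += ev
    state, ev = ctl.step_state_machine(state, ctl.Event(t0 + 2, tag, "contact"),
                                       config, rng)
    events += ev
    return state, events


def test_contact_always_fixes_at_probability_one(rng):
    config = ctl.CageConfig(fix_probability=1.0)
    for _ in range(20):
        _, events = run_visit(config, rng)
        assert any(e.kind == "fix_start" for e in events)


def test_contact_never_fixes_at_probability_zero(rng):
    config = ctl.CageConfig(fix_probability=0.0)
    for _ in range(20):
        _, events = run_visit(config, rng)
        assert not any(e.kind == "fix_start" for e in events)
        # non-fixed trial still dispenses the maximum-value reward
        contact_rewards = [e for e in events if e.kind == "reward"
                           and e.payload["reward_kind"] == "contact"]
        assert len(contact_rewards) == 1
        assert contact_rewards[0].payload["volume_ul"] == \
            pytest.approx(config.fix_trial_total_ul)


def test_trial_rewards_at_ten_second_intervals_with_400ms_valve():
    """A 30 s trial gets rewards at 0, 10, 20 s, each a 400 ms valve event."""
    config = ctl.CageConfig(trial_duration_s=30.0)
    rewards = ctl.schedule_trial_rewards(100.0, config)
    assert [r.t - 100.0 for r in rewards] == [0.0, 10.0, 20.0]
    assert all(r.payload["valve_open_ms"] == 400.0 for r in rewards)
    total = sum(r.payload["volume_ul"] for r in rewards)
    assert total == pytest.approx(config.fix_trial_total_ul)


def test_fix_end_exactly_trial_duration_after_fix_start(rng):
    config = ctl.CageConfig(fix_probability=1.0, trial_duration_s=30.0)
    state, events = run_visit(config, rng)
    fix_start = next(e for e in events if e.kind == "fix_start")
    # drain the schedule by stepping past the trial end
    state, late = ctl.step_state_machine(
        state, ctl.Event(fix_start.t + 60, "M1", "exit"), config, rng)
    fix_end = next(e for e in late if e.kind == "fix_end")
    assert fix_end.t - fix_start.t == pytest.approx(30.0)


def test_power_loss_releases_immediately_and_cancels_schedule(rng):
    config = ctl.CageConfig(fix_probability=1.0, trial_duration_s=30.0)
    state, events = run_visit(config, rng)
    t_loss = 10.0
    state, ev = ctl.step_state_machine(
        state, ctl.Event(t_loss, "", "fix_end", {"power_loss": True}),
        config, rng)
    ends = [e for e in ev if e.kind == "fix_end"]
    assert len(ends) == 1 and ends[0].t == t_loss
    assert state.phase != "fixed"
    assert not state.pending  # nothing scheduled survives the power loss


def test_contact_without_entry_is_a_consistency_error(rng, config):
    with pytest.raises(ctl.LogConsistencyError):
        ctl.step_state_machine(make_state(), ctl.Event(0.0, "M1", "contact"),
                               config, rng)


def test_entrance_rewards_capped_per_light_cycle_day(rng):
    config = ctl.CageConfig(entrance_reward_cap=3, fix_probability=0.0)
    state = make_state()
    volumes = []
    for i in range(6):
        t = i * 100.0
        state, ev = ctl.step_state_machine(state, ctl.Event(t, "M1", "entry"),
                                           config, rng)
        volumes += [e.payload["volume_ul"] for e in ev if e.kind == "reward"]
        state, _ = ctl.step_state_machine(state, ctl.Event(t + 50, "M1", "exit"),
                                          config, rng)
    assert len(volumes) == 3
    # next light-cycle day resets the cap
    state, ev = ctl.step_state_machine(
        state, ctl.Event(25 * 3600.0, "M1", "entry"), config, rng)
    assert any(e.kind == "reward" for e in ev)


# ---------------------------------------------------------------------------
# stimulus scheduling
# ---------------------------------------------------------------------------


def test_four_flashes_five_seconds_apart_in_35s_trial(rng):
    config = ctl.CageConfig(stim_trial_fraction=1.0, flashes_per_trial=4,
                            trial_duration_s=35.0)
    trial = ctl.TrialRecord("M1", 0.0, 35.0)
    times = ctl.schedule_stimuli(trial, config, rng)
    assert len(times) == 4
    assert np.allclose(np.diff(times), 5.0)


def test_twenty_flashes_fit_in_97s_trial(rng):
    config = ctl.CageConfig(stim_trial_fraction=1.0, flashes_per_trial=20,
                            trial_duration_s=97.0)
    trial = ctl.TrialRecord("M1", 0.0, 97.0)
    times = ctl.schedule_stimuli(trial, config, rng)
    assert len(times) == 20
    assert np.allclose(np.diff(times), 5.0)


def test_stim_fraction_zero_never_emits(rng):
    config = ctl.CageConfig(stim_trial_fraction=0.0, trial_duration_s=35.0)
    trial = ctl.TrialRecord("M1", 0.0, 35.0)
    for _ in range(50):
        assert ctl.schedule_stimuli(trial, config, rng) == []


def test_flashes_not_fitting_raise_configuration_error(rng):
    config = ctl.CageConfig(stim_trial_fraction=1.0, flashes_per_trial=20,
                            trial_duration_s=30.0)
    with pytest.raises(ctl.ConfigurationError):
        ctl.schedule_stimuli(ctl.TrialRecord("M1", 0.0, 30.0), config, rng)


# ---------------------------------------------------------------------------
# session association
# ---------------------------------------------------------------------------


def simple_log(events):
    log = ctl.EventLog()
    log.extend(events)
    return log


def test_movie_within_entry_exit_assigned():
    log = simple_log([ctl.Event(0, "M1", "entry"), ctl.Event(100, "M1", "exit")])
    records, unassigned = ctl.associate_sessions(log, [("mov0", 10, 40)])
    assert unassigned == []


def test_movie_spanning_exit_flagged_unassigned():
    log = simple_log([ctl.Event(0, "M1", "entry"), ctl.Event(100, "M1", "exit"),
                      ctl.Event(120, "M2", "entry"), ctl.Event(300, "M2", "exit")])
    _, unassigned = ctl.associate_sessions(log, [("mov0", 90, 130)])
    assert unassigned == ["mov0"]


def test_simulated_day_links_every_fix_to_a_movie():
    config = ctl.CageConfig()
    agents = [ctl.VirtualMouse(f"M{i}", entries_per_day=60.0,
                               contact_prob=0.3) for i in range(5)]
    log = ctl.run_virtual_colony(agents, config, days=1.0, seed=11)
    fixes = log.of_kind("fix_start")
    movies = [(f"mov{i}", e.t, e.t + config.trial_duration_s)
              for i, e in enumerate(fixes)]
    records, unassigned = ctl.associate_sessions(log, movies)
    assert unassigned == []
    assert len(records) == len(fixes)
    assert all(r.movie_id is not None for r in records)


def test_overlapping_fixations_are_impossible_state():
    log = simple_log([
        ctl.Event(0, "M1", "entry"), ctl.Event(1, "M2", "entry"),
        ctl.Event(2, "M1", "fix_start"), ctl.Event(3, "M2", "fix_start"),
    ])
    with pytest.raises(ctl.ImpossibleStateError):
        ctl.associate_sessions(log, [])


# ---------------------------------------------------------------------------
# virtual colony
# ---------------------------------------------------------------------------


def test_zero_entry_rate_gives_empty_log():
    log = ctl.run_virtual_colony(
        [ctl.VirtualMouse("M0", entries_per_day=0.0)],
        ctl.CageConfig(), days=2.0, seed=3)
    assert len(log) == 0


def test_same_seed_gives_identical_log():
    agents = [ctl.VirtualMouse(f"M{i}") for i in range(3)]
    a = ctl.run_virtual_colony(agents, ctl.CageConfig(), days=1.0, seed=5)
    b = ctl.run_virtual_colony(agents, ctl.CageConfig(), days=1.0, seed=5)
    assert [(e.t, e.tag, e.kind) for e in a] == [(e.t, e.tag, e.kind) for e in b]


def test_colony_log_satisfies_invariants_and_conserves_water():
    config = ctl.CageConfig()
    agents = [ctl.VirtualMouse(f"M{i}", entries_per_day=70.0,
                               contact_prob=0.2) for i in range(3)]
    log = ctl.run_virtual_colony(agents, config, days=2.0, seed=21)
    log.validate()
    n_entrance = sum(1 for e in log if e.kind == "reward"
                     and e.payload["reward_kind"] == "entrance")
    n_contact = sum(1 for e in log if e.kind == "reward"
                    and e.payload["reward_kind"] == "contact")
    n_fix = sum(1 for e in log if e.kind == "fix_start")
    expected = (n_entrance * config.entrance_reward_ul
                + (n_contact + n_fix) * config.fix_trial_total_ul)
    assert ctl.total_dispensed_ul(log) == pytest.approx(expected)


def test_colony_entry_rates_track_configured_rates():
    config = ctl.CageConfig(entrance_reward_cap=500)
    rates = [47.0, 70.0, 125.0]
    agents = [ctl.VirtualMouse(f"M{i}", entries_per_day=r, contact_prob=0.1)
              for i, r in enumerate(rates)]
    log = ctl.run_virtual_colony(agents, config, days=8.0, seed=9)
    for agent, r in zip(agents, rates):
        n = sum(1 for e in log.for_tag(agent.tag) if e.kind == "entry")
        assert n / 8.0 == pytest.approx(r, rel=0.15)


def test_nocturnal_bias_shows_in_night_entry_counts():
    agents = [ctl.VirtualMouse("M0", entries_per_day=100.0,
                               nocturnal_bias=3.0)]
    log = ctl.run_virtual_colony(agents, ctl.CageConfig(entrance_reward_cap=500),
                                 days=4.0, seed=2)
    night = day = 0
    for e in log.of_kind("entry"):
        hour = (e.t / 3600.0 + log.t0_hour) % 24.0
        if 7.0 <= hour < 19.0:
            day += 1
        else:
            night += 1
    assert night > day


def test_event_log_rejects_nonmonotone_and_unpaired_events():
    log = ctl.EventLog()
    log.append(ctl.Event(5.0, "M1", "entry"))
    with pytest.raises(ctl.LogConsistencyError):
        log.append(ctl.Event(1.0, "M1", "exit"))
    bad = simple_log([ctl.Event(0, "M1", "entry"), ctl.Event(1, "M1", "fix_start")])
    with pytest.raises(ctl.LogConsistencyError):
        bad.validate()


def test_water_accounting_helper_counts_all_reward_kinds():
    config = ctl.CageConfig(fix_probability=1.0)
    rng = np.random.default_rng(0)
    state = make_state()
    log = ctl.EventLog()
    state, ev = ctl.step_state_machine(state, ctl.Event(0, "M1", "entry"),
                                       config, rng)
    log.extend(ev)
    state, ev = ctl.step_state_machine(state, ctl.Event(2, "M1", "contact"),
                                       config, rng)
    log.extend(ev)
    state, ev = ctl.step_state_machine(state, ctl.Event(100, "M1", "exit"),
                                       config, rng)
    log.extend(ev)
    expected = config.entrance_reward_ul + config.fix_trial_total_ul
    assert ctl.total_dispensed_ul(log) == pytest.approx(expected)
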
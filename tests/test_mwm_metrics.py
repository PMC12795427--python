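"""Trial metrics: geometric closed forms, partition identities, invariances."""

import math

import numpy as np
import pytest

from retquant import mwm_metrics as mwm
from retquant import synthetic_data as syn


GEOM = mwm.PoolGeometry()  # 0.5 m pool, 4 cm platform in NW
RATE = 14.0


def _traj(xs, ys, rate=RATE, **labels):
    t = np.arange(len(xs)) / rate
    return mwm.Trajectory(t_s=t, x_m=np.asarray(xs), y_m=np.asarray(ys),
                          rate_hz=rate, **labels)


def _line(start, direction, speed, duration, rate=RATE):
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    dx, dy = direction
    norm = math.hypot(dx, dy)
    return _traj(start[0] + speed * t * dx / norm, start[1] + speed * t * dy / norm)


# ---------------------------------------------------------------------------
# latency


def test_straight_approach_latency_closed_form():
    px, py = GEOM.platform_center
    start = (px + 0.40, py)  # 0.40 m from platform center, radius 0.04
    traj = _line(start, (-1.0, 0.0), speed=0.1, duration=10)
    lat = mwm.latency(traj, GEOM)
    assert abs(lat - 3.6) <= 1.0 / RATE


def test_never_reaching_platform_returns_cap():
    traj = _line((0.3, -0.3), (1.0, 0.0), speed=0.001, duration=60)
    assert mwm.latency(traj, GEOM) == 60.0


def test_starting_on_platform_gives_zero_latency():
    traj = _line(GEOM.platform_center, (1.0, 0.0), speed=0.01, duration=5)
    assert mwm.latency(traj, GEOM) == 0.0


def test_empty_trajectory_rejected():
    traj = mwm.Trajectory(t_s=[], x_m=[], y_m=[])
    with pytest.raises(ValueError, match="empty"):
        mwm.latency(traj, GEOM)


# ---------------------------------------------------------------------------
# path length


def test_stationary_trajectory_has_zero_length():
    traj = _traj(np.zeros(50), np.zeros(50))
    assert mwm.path_length(traj) == 0.0


def test_unit_speed_line_length_closed_form():
    traj = _line((-0.3, -0.3), (1.0, 1.0), speed=0.1, duration=3.6)
    expected = 0.1 * (len(traj) - 1) / RATE
    assert mwm.path_length(traj) == pytest.approx(expected, abs=1e-9)
    assert abs(mwm.path_length(traj) - 0.36) <= 0.1 / RATE


def test_circle_length_matches_regular_polygon_formula():
    r, revs, rate, speed = 0.3, 2, 50.0, 0.15
    period = 2 * math.pi * r / speed
    n = int(revs * period * rate)
    theta = 2 * math.pi * revs * np.arange(n + 1) / n
    traj = mwm.Trajectory(
        t_s=np.arange(n + 1) / rate,
        x_m=r * np.cos(theta),
        y_m=r * np.sin(theta),
        rate_hz=rate,
    )
    # polygonal approximation of a circle: chord sum = 2 pi r k sinc(pi/m)
    step = 2 * math.pi * revs / n
    expected = n * 2 * r * math.sin(step / 2)
    assert mwm.path_length(traj) == pytest.approx(expected, rel=1e-9)
    assert mwm.path_length(traj) <= 2 * math.pi * r * revs


def test_path_length_truncates_at_latency():
    px, py = GEOM.platform_center
    traj = _line((px + 0.40, py), (-1.0, 0.0), speed=0.1, duration=10)
    lat = mwm.latency(traj, GEOM)
    full = mwm.path_length(traj)
    trunc = mwm.path_length(traj, until_s=lat)
    assert trunc < full
    assert trunc == pytest.approx(0.1 * lat, abs=1e-9)


# ---------------------------------------------------------------------------
# floating


def test_fully_stationary_is_100_percent_floating():
    traj = _traj(np.zeros(100), np.zeros(100))
    assert mwm.floating_fraction(traj) == pytest.approx(100.0)


def test_constant_speed_swim_has_zero_floating():
    traj = _line((-0.3, 0.0), (1.0, 0.0), speed=0.1, duration=5)
    assert mwm.floating_fraction(traj) == 0.0


def test_injected_six_second_pause_gives_ten_percent():
    rate = 14.0
    n = int(60 * rate)
    t = np.arange(n + 1) / rate
    # swim at 0.1 m/s, pause for 6 s in the middle (floating has no pool
    # geometry, so an unbounded straight path is a valid fixture)
    x = np.where(t < 27, 0.1 * t, np.where(t < 33, 2.7, 2.7 + 0.1 * (t - 33)))
    traj = mwm.Trajectory(t_s=t, x_m=x, y_m=np.zeros_like(x), rate_hz=rate)
    assert mwm.floating_fraction(traj) == pytest.approx(10.0, abs=1.0)


# ---------------------------------------------------------------------------
# thigmotaxis


def test_wall_hugging_is_100_percent():
    theta = np.linspace(0, 2 * math.pi, 200)
    traj = _traj(0.48 * np.cos(theta), 0.48 * np.sin(theta))
    assert mwm.thigmotaxis_fraction(traj, GEOM) == pytest.approx(100.0)


def test_center_swim_is_0_percent():
    traj = _line((-0.05, 0.0), (1.0, 0.0), speed=0.02, duration=5)
    assert mwm.thigmotaxis_fraction(traj, GEOM) == 0.0


def test_half_wall_half_center_is_50_percent():
    rate = 14.0
    n = 280  # 20 s
    theta = np.linspace(0, math.pi, n)
    wall_x, wall_y = 0.47 * np.cos(theta), 0.47 * np.sin(theta)
    center_x = np.linspace(0.0, 0.1, n)
    center_y = np.zeros(n)
    x = np.concatenate([wall_x, center_x])
    y = np.concatenate([wall_y, center_y])
    traj = _traj(x, y, rate=rate)
    assert mwm.thigmotaxis_fraction(traj, GEOM) == pytest.approx(50.0, abs=2.0)


# ---------------------------------------------------------------------------
# abidance and crossings


def test_uniform_circle_gives_25_percent_per_quadrant():
    n = 4000
    theta = 2 * math.pi * np.arange(n) / n  # one full revolution
    traj = _traj(0.3 * np.cos(theta), 0.3 * np.sin(theta), rate=n / 60)
    ab = mwm.quadrant_abidance(traj, GEOM)
    for q in mwm.QUADRANTS:
        assert ab[q] == pytest.approx(25.0, abs=0.1)


def test_confined_trajectory_is_100_percent_in_its_quadrant():
    traj = _line((0.1, 0.1), (1.0, 1.0), speed=0.01, duration=10)
    ab = mwm.quadrant_abidance(traj, GEOM)
    assert ab["NE"] == pytest.approx(100.0)
    assert ab["SW"] == 0.0


def test_abidance_partitions_to_exactly_100():
    rng = np.random.default_rng(0)
    steps = rng.normal(0, 0.02, size=(500, 2)).cumsum(axis=0)
    r = np.hypot(steps[:, 0], steps[:, 1])
    steps[r > 0.45] *= (0.45 / r[r > 0.45])[:, None]
    traj = _traj(steps[:, 0], steps[:, 1])
    ab = mwm.quadrant_abidance(traj, GEOM)
    assert sum(ab.values()) == pytest.approx(100.0, abs=1e-9)


def test_chord_through_target_twice_counts_two_crossings():
    px, py = GEOM.platform_center
    xs = np.concatenate([
        np.linspace(px - 0.2, px + 0.2, 60),  # in and out once
        np.linspace(px + 0.2, px - 0.2, 60),  # and back again
    ])
    ys = np.full_like(xs, py)
    traj = _traj(xs, ys)
    assert mwm.target_zone_crossings(traj, GEOM) == 2


def test_no_visit_counts_zero_and_start_inside_counts_one():
    far = _line((0.3, -0.3), (1.0, 0.0), speed=0.001, duration=10)
    assert mwm.target_zone_crossings(far, GEOM) == 0
    inside = _line(GEOM.platform_center, (1.0, 0.0), speed=0.001, duration=10)
    assert mwm.target_zone_crossings(inside, GEOM) == 1


def test_trained_swims_cross_target_more_than_naive_swims():
    cfg = syn.BehaviorConfig()
    cfg0 = syn.BehaviorConfig(memory_gain=0.0)
    geom = cfg.geometry()
    hi = [
        mwm.target_zone_crossings(
            syn.generate_trajectory(2.0, 5, 1, cfg, seed=i), geom
        )
        for i in range(150)
    ]
    lo = [
        mwm.target_zone_crossings(
            syn.generate_trajectory(0.0, 5, 1, cfg0, seed=i), geom
        )
        for i in range(150)
    ]
    assert np.mean(hi) > np.mean(lo)


# ---------------------------------------------------------------------------
# trial table


def test_trial_table_row_count_and_schema():
    cfg = syn.BehaviorConfig()
    geom = cfg.geometry()
    trajs = []
    for a in range(4):
        for day, quads in syn.TABLE4_SCHEDULE.items():
            for trial in range(1, len(quads) + 1):
                traj = syn.generate_trajectory(
                    0.5, day, trial, cfg, seed=a * 100 + day * 10 + trial
                )
                traj.animal = f"m{a}"
                trajs.append(traj)
    table = mwm.trial_table(trajs, geom, schedule=syn.TABLE4_SCHEDULE)
    assert len(table) == 68  # 4 animals x (4 days x 4 trials + 1 probe)
    probe = table[table.day == 5]
    assert probe["latency_s"].isna().all()
    assert probe["crossings"].notna().all()
    training = table[table.day < 5]
    assert training["latency_s"].notna().all()
    assert training["crossings"].isna().all()
    # rows reproduce the single-trial operations
    row = table[(table.animal == "m0") & (table.day == 1) & (table.trial == 1)]
    t0 = next(t for t in trajs if t.animal == "m0" and t.day == 1 and t.trial == 1)
    assert row["latency_s"].iloc[0] == mwm.latency(t0, geom)


def test_trial_table_rejects_unknown_day():
    cfg = syn.BehaviorConfig()
    traj = syn.generate_trajectory(0.0, 1, 1, cfg, seed=0)
    traj.animal, traj.day = "m0", 6
    with pytest.raises(ValueError, match="schedule"):
        mwm.trial_table([traj], cfg.geometry(), schedule=syn.TABLE4_SCHEDULE)


# ---------------------------------------------------------------------------
# invariances


def test_metrics_invariant_under_rigid_rotation():
    cfg = syn.BehaviorConfig()
    geom = cfg.geometry()
    traj = syn.generate_trajectory(1.0, 5, 1, cfg, seed=9)
    ang = math.pi / 2
    c, s = math.cos(ang), math.sin(ang)
    rot = mwm.Trajectory(
        t_s=traj.t_s,
        x_m=c * traj.x_m - s * traj.y_m,
        y_m=s * traj.x_m + c * traj.y_m,
        rate_hz=traj.rate_hz,
        day=5, trial=1,
    )
    px, py = geom.platform_center
    geom_rot = mwm.PoolGeometry(
        pool_radius=geom.pool_radius,
        platform_center=(c * px - s * py, s * px + c * py),
        platform_radius=geom.platform_radius,
        wall_zone_width=geom.wall_zone_width,
    )
    assert mwm.path_length(rot) == pytest.approx(mwm.path_length(traj))
    assert mwm.thigmotaxis_fraction(rot, geom_rot) == pytest.approx(
        mwm.thigmotaxis_fraction(traj, geom)
    )
    assert mwm.target_zone_crossings(rot, geom_rot) == mwm.target_zone_crossings(
        traj, geom
    )
    ab = mwm.quadrant_abidance(traj, geom)
    ab_rot = mwm.quadrant_abidance(rot, geom_rot)
    # +90 degrees advances each quadrant counter-clockwise
    mapping = {"NE": "NW", "NW": "SW", "SW": "SE", "SE": "NE"}
    for before, after in mapping.items():
        assert ab_rot[after] == pytest.approx(ab[before])


def test_longer_observation_never_decreases_latency_or_length():
    cfg = syn.BehaviorConfig(memory_gain=0.0)
    geom = cfg.geometry()
    traj = syn.generate_trajectory(0.0, 5, 1, cfg, seed=4)
    for cut in (200, 400, 841):
        short = mwm.Trajectory(
            t_s=traj.t_s[:cut], x_m=traj.x_m[:cut], y_m=traj.y_m[:cut],
            rate_hz=traj.rate_hz,
        )
        assert mwm.path_length(short) <= mwm.path_length(traj) + 1e-12
        assert mwm.latency(short, geom) <= 60.0
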
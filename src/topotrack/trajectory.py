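"""Multiple-object-tracking trajectory simulator.

Items move at constant speed inside a square field with smoothly drifting
headings: at Poisson-distributed instants each item draws a new target
heading, toward which the current heading turns at a bounded rate.  A
look-ahead rule steers items away from the field boundary, so speed is
conserved exactly (no reflection discontinuities).  Individually generated
paths are combined into trials under the constraint that no two items ever
approach closer than ``min_dist``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MotionConfig",
    "TrialTrajectory",
    "TrajectoryError",
    "generate_item_path",
    "generate_path_pool",
    "generate_trial",
    "generate_session",
]

N_CONDITIONS = 5  # probe-match conditions M0..M4, used as split labels


class TrajectoryError(RuntimeError):
    """Raised when motion constraints cannot be satisfied."""


@dataclass(frozen=True)
class MotionConfig:
    """Parameters of the tracking display's motion model.

    All spatial quantities are in degrees of visual angle, times in
    seconds.  Defaults are the tracking-study conditions: 8 items (4
    targets) at 4.1 deg/s in a 14.4 x 14.4 deg field, 0.8 deg minimum
    inter-item distance, 4 s of motion per trial.  ``turn_event_rate``
    (mean rate of new heading draws) and ``turn_rate_limit`` (maximum
    heading change rate) shape the "curved, continuous" random motion;
    the display frame rate is a free choice because every downstream
    stage works in seconds.
    """

    field_size: float = 14.4
    speed: float = 4.1
    n_items: int = 8
    n_targets: int = 4
    min_dist: float = 0.8
    duration: float = 4.0
    frame_rate: float = 100.0
    turn_rate_limit: float = 270.0  # deg of heading per second
    turn_event_rate: float = 1.0  # Hz
    pool_factor: int = 4  # candidate paths per item slot
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.field_size <= 0:
            raise ValueError("field_size must be positive")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not 0 < self.n_targets < self.n_items:
            raise ValueError("need 0 < n_targets < n_items")
        if self.min_dist >= self.field_size:
            raise ValueError("min_dist must be smaller than field_size")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        if self.frame_rate < 2 * max(self.turn_event_rate, 1e-9):
            raise ValueError("frame_rate must be at least twice turn_event_rate")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate)) + 1

    @property
    def step(self) -> float:
        """Per-frame displacement in degrees."""
        return self.speed / self.frame_rate

    @property
    def turning_radius(self) -> float:
        """Minimum turning-circle radius implied by the turn-rate limit."""
        return self.speed / np.deg2rad(self.turn_rate_limit)

    @property
    def boundary_margin(self) -> float:
        """Distance from the wall at which avoidance steering engages.

        A full U-turn (heading momentarily pointing away from the field
        centre near a corner) penetrates up to two turning radii beyond the
        trigger line, so the margin is 2.2 radii with a little slack.
        """
        return 2.2 * self.turning_radius


@dataclass
class TrialTrajectory:
    """Per-frame 2-D positions of all items in one trial.

    ``positions`` has shape (n_items, n_frames, 2); ``target_ids`` is the
    tracked quadruple, the complement being the distractor set.
    ``match_condition`` in 0..4 is the probe-match label used downstream
    purely as a train/test split selector.
    """

    positions: np.ndarray
    frame_rate: float
    target_ids: np.ndarray
    trial_id: int = 0
    match_condition: int = 0

    @property
    def n_items(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.frame_rate

    @property
    def distractor_ids(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_items), self.target_ids)

    def item_set(self, which: str) -> np.ndarray:
        if which == "target":
            return np.asarray(self.target_ids)
        if which == "distractor":
            return self.distractor_ids
        raise ValueError(f"unknown item set {which!r}")

    def min_pairwise_distance(self) -> float:
        """Closest approach between any two items over the whole trial."""
        p = self.positions
        diff = p[:, None, :, :] - p[None, :, :, :]
        d = np.hypot(diff[..., 0], diff[..., 1])
        iu = np.triu_indices(self.n_items, k=1)
        return float(d[iu].min())


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return (a + np.pi) % (2 * np.pi) - np.pi


def generate_path_pool(
    config: MotionConfig,
    n_paths: int,
    rng: np.random.Generator,
    start_xy: np.ndarray | None = None,
    start_heading: np.ndarray | None = None,
) -> np.ndarray:
    """Generate ``n_paths`` independent item paths, shape (n_paths, n_frames, 2).

    Vectorised across paths: each frame advances every path by one constant
    -speed step while headings relax toward per-path target headings at the
    turn-rate limit.  Target headings are redrawn at Poisson instants
    (probability ``turn_event_rate / frame_rate`` per frame) and overridden
    toward the field centre whenever a two-frame look-ahead would leave the
    safe inner box.
    """
    L = config.field_size
    margin = config.boundary_margin
    if 2 * margin >= L:
        raise TrajectoryError(
            "turn-rate limit too low for the field: turning radius "
            f"{config.turning_radius:.2f} deg does not fit in a "
            f"{L:.2f} deg field"
        )
    step = config.step
    max_turn = np.deg2rad(config.turn_rate_limit) / config.frame_rate
    p_redraw = config.turn_event_rate / config.frame_rate
    n_frames = config.n_frames
    center = np.array([L / 2.0, L / 2.0])

    pos = np.empty((n_paths, n_frames, 2))
    if start_xy is None:
        start_xy = rng.uniform(margin, L - margin, size=(n_paths, 2))
    pos[:, 0] = start_xy
    if start_heading is None:
        heading = rng.uniform(-np.pi, np.pi, size=n_paths)
    else:
        heading = np.array(start_heading, dtype=float)
    target_heading = heading.copy()

    xy = pos[:, 0].copy()
    for f in range(1, n_frames):
        redraw = rng.random(n_paths) < p_redraw
        if redraw.any():
            target_heading[redraw] = rng.uniform(-np.pi, np.pi, size=redraw.sum())
        # boundary avoidance: two-frame look-ahead against the safe box
        ahead = xy + 2 * step * np.column_stack([np.cos(heading), np.sin(heading)])
        unsafe = ((ahead < margin) | (ahead > L - margin)).any(axis=1)
        if unsafe.any():
            to_center = center - xy[unsafe]
            target_heading[unsafe] = np.arctan2(to_center[:, 1], to_center[:, 0])
        delta = _wrap_angle(target_heading - heading)
        heading = heading + np.clip(delta, -max_turn, max_turn)
        xy = xy + step * np.column_stack([np.cos(heading), np.sin(heading)])
        if (xy < 0).any() or (xy > L).any():
            raise TrajectoryError(
                "item left the field despite boundary steering; "
                "constraints unreachable for this configuration"
            )
        pos[:, f] = xy
    return pos


def generate_item_path(
    config: MotionConfig,
    rng: np.random.Generator,
    start_xy: tuple[float, float] | None = None,
    start_heading: float | None = None,
) -> np.ndarray:
    """Generate one item path, shape (n_frames, 2). See generate_path_pool."""
    sx = None if start_xy is None else np.asarray([start_xy], dtype=float)
    sh = None if start_heading is None else np.asarray([start_heading], dtype=float)
    return generate_path_pool(config, 1, rng, start_xy=sx, start_heading=sh)[0]


def _compatible(path: np.ndarray, chosen: np.ndarray, min_dist: float) -> tuple[bool, float]:
    """Check min-distance of ``path`` against every path in ``chosen``."""
    if len(chosen) == 0:
        return True, np.inf
    d = np.hypot(*(chosen - path[None]).transpose(2, 0, 1))
    closest = float(d.min())
    return closest >= min_dist, closest


def generate_trial(
    config: MotionConfig,
    rng: np.random.Generator,
    pool: np.ndarray | None = None,
    max_attempts: int = 10_000,
    trial_id: int = 0,
    match_condition: int = 0,
) -> TrialTrajectory:
    """Combine individually generated paths into one trial.

    Paths are drawn (without replacement within the trial) from a pool of
    independently generated candidates and accepted item-by-item only if the
    pairwise distance to all previously accepted paths stays >= ``min_dist``
    on every frame; the pool is extended with fresh paths when exhausted.
    Raises :class:`TrajectoryError` with the closest approach achieved if
    ``max_attempts`` candidate checks do not yield a valid combination.
    """
    if pool is None:
        pool = generate_path_pool(config, config.pool_factor * config.n_items, rng)
    pool = list(pool)
    attempts = 0
    best_closest = -np.inf
    chosen: list[np.ndarray] = []
    available = list(rng.permutation(len(pool)))
    taken: list[int] = []
    while len(chosen) < config.n_items:
        if not available:
            fresh = generate_path_pool(config, config.n_items, rng)
            start = len(pool)
            pool.extend(fresh)
            available = list(rng.permutation(np.arange(start, len(pool))))
        idx = available.pop(0)
        attempts += 1
        if attempts > max_attempts:
            raise TrajectoryError(
                f"rejection budget ({max_attempts}) exhausted with "
                f"{len(chosen)}/{config.n_items} items placed; closest "
                f"approach achieved {best_closest:.3f} deg < "
                f"{config.min_dist} deg"
            )
        ok, closest = _compatible(pool[idx], np.asarray(chosen), config.min_dist)
        if chosen:
            best_closest = max(best_closest, closest)
        if ok:
            chosen.append(pool[idx])
            taken.append(idx)
    positions = np.stack(chosen)
    target_ids = np.sort(rng.choice(config.n_items, size=config.n_targets, replace=False))
    return TrialTrajectory(
        positions=positions,
        frame_rate=config.frame_rate,
        target_ids=target_ids,
        trial_id=trial_id,
        match_condition=match_condition,
    )


def generate_session(
    config: MotionConfig,
    n_trials: int = 300,
    rng: np.random.Generator | int | None = None,
) -> list[TrialTrajectory]:
    """Generate a session of distinct trials with balanced match conditions.

    ``n_trials`` is spread as evenly as possible over the 5 probe-match
    conditions (exactly ``n_trials/5`` each when divisible), randomly
    shuffled.  Each trial draws from a fresh candidate-path pool, so no
    trajectory occurs twice.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base, extra = divmod(n_trials, N_CONDITIONS)
    conditions = np.repeat(np.arange(N_CONDITIONS), base)
    if extra:
        conditions = np.concatenate([conditions, rng.choice(N_CONDITIONS, extra, replace=False)])
    conditions = rng.permutation(conditions)
    trials = []
    for k in range(n_trials):
        trials.append(
            generate_trial(
                config,
                rng,
                trial_id=k,
                match_condition=int(conditions[k]),
            )
        )
    return trials
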
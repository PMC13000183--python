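"""Shortest-path polygon topology of a tracked quadruple.

For four points there are exactly three distinct cyclic orders; the
shortest-path polygon is the one of minimum closed-path length, and it is
always simple.  The convex hull of four points (ignoring the degenerate
coincident/collinear cases) has either three corners — one point interior,
polygon concave — or four corners — polygon convex.  Three kinds of
topological transition follow frame-to-frame:

* ``flip``    — the canonical cyclic item order of the shortest-path
                polygon changes (only possible in concave states);
* ``concave`` — hull corner count drops 4 -> 3;
* ``convex``  — hull corner count rises 3 -> 4.

Only isolated events enter the analyses: events repeating within 500 ms
(same type, by default) are excluded, as are events within 500 ms of
motion onset or offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import TrialTrajectory

__all__ = [
    "EVENT_TYPES",
    "PolygonState",
    "canonical_cycle",
    "shortest_path_polygon",
    "hull_corner_count",
    "polygon_states",
    "detect_transitions",
    "detect_session_events",
    "EVENT_COLUMNS",
]

EVENT_TYPES = ("flip", "concave", "convex")
EVENT_COLUMNS = ["trial_id", "set_label", "event_type", "time_s", "frame"]

# The three cyclic classes of positions (0,1,2,3), as index patterns.
_CYCLE_PATTERNS = np.array([[0, 1, 2, 3], [0, 1, 3, 2], [0, 2, 1, 3]])

DEGENERATE = -1  # hull corner marker for coincident/collinear quadruples


@dataclass(frozen=True)
class PolygonState:
    """Shortest-path polygon of one frame.

    ``cycle`` is the canonical cyclic order of the four item indices (None
    when degenerate), ``hull_corners`` is 3, 4 or ``DEGENERATE``.
    """

    cycle: tuple[int, ...] | None
    hull_corners: int
    perimeter: float
    frame: int = 0

    @property
    def degenerate(self) -> bool:
        return self.hull_corners == DEGENERATE


def canonical_cycle(order) -> tuple[int, ...]:
    """Canonical form of a cyclic order: invariant under rotation and
    reversal, lexicographically minimal rotation starting at the smallest
    index."""
    order = tuple(int(i) for i in order)
    if len(order) != len(set(order)):
        raise ValueError(f"cycle has duplicate indices: {order}")
    n = len(order)
    candidates = []
    for seq in (order, order[::-1]):
        for r in range(n):
            candidates.append(seq[r:] + seq[:r])
    return min(candidates)


def _cycle_perimeters(points: np.ndarray) -> np.ndarray:
    """Closed-path lengths of the 3 cyclic orders.

    ``points`` has shape (..., 4, 2); returns (..., 3).
    """
    p = points[..., _CYCLE_PATTERNS, :]  # (..., 3, 4, 2)
    edges = p - np.roll(p, -1, axis=-2)
    return np.hypot(edges[..., 0], edges[..., 1]).sum(axis=-1)


def _hull_corners_vec(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Hull corner counts for frames of 4 points, shape (..., 4, 2) -> (...).

    A point is interior when the three orientation tests against the
    triangle of the remaining points agree strictly in sign.  Quadruples
    whose every leave-one-out triangle is (near-)degenerate are flagged
    ``DEGENERATE`` (coincident or collinear items).
    """
    others = np.array([[j for j in range(4) if j != i] for i in range(4)])
    tri = points[..., others, :]  # (..., 4, 3, 2)
    pt = points[..., :, None, :]  # (..., 4, 1, 2)
    a = tri
    b = np.roll(tri, -1, axis=-2)
    cross = (b[..., 0] - a[..., 0]) * (pt[..., 1] - a[..., 1]) - (
        b[..., 1] - a[..., 1]
    ) * (pt[..., 0] - a[..., 0])  # (..., 4, 3)
    inside = (cross > tol).all(axis=-1) | (cross < -tol).all(axis=-1)
    n_inside = inside.sum(axis=-1)
    # leave-one-out triangle areas (x2) to detect collinear quadruples
    ta = tri[..., 0, :]
    area2 = np.abs(
        (tri[..., 1, 0] - ta[..., 0]) * (tri[..., 2, 1] - ta[..., 1])
        - (tri[..., 1, 1] - ta[..., 1]) * (tri[..., 2, 0] - ta[..., 0])
    )
    degen = (area2 < tol).all(axis=-1)
    corners = 4 - np.minimum(n_inside, 1)
    return np.where(degen, DEGENERATE, corners)


def hull_corner_count(points) -> int:
    """Convex-hull corner count of 4 points: 4, 3 or ``DEGENERATE``."""
    points = np.asarray(points, dtype=float)
    if points.shape != (4, 2):
        raise ValueError("expected 4 points in 2-D")
    return int(_hull_corners_vec(points[None])[0])


def shortest_path_polygon(points, frame: int = 0) -> PolygonState:
    """Shortest closed path through 4 points, by minimum over the 3 cycles."""
    points = np.asarray(points, dtype=float)
    if points.shape != (4, 2):
        raise ValueError("expected 4 points in 2-D")
    corners = hull_corner_count(points)
    per = _cycle_perimeters(points[None])[0]
    if corners == DEGENERATE:
        return PolygonState(None, DEGENERATE, float(per.min()), frame)
    best = int(per.argmin())
    cycle = canonical_cycle(_CYCLE_PATTERNS[best])
    return PolygonState(cycle, corners, float(per[best]), frame)


def polygon_is_simple(points: np.ndarray, cycle) -> bool:
    """Check that the polygon visiting ``points`` in ``cycle`` order has no
    crossing edges (shared endpoints between adjacent edges excluded)."""
    q = points[list(cycle)]
    edges = [(q[i], q[(i + 1) % 4]) for i in range(4)]

    def _x(a, b):
        return a[0] * b[1] - a[1] * b[0]

    def _seg_cross(s1, s2) -> bool:
        (p1, p2), (p3, p4) = s1, s2
        d1 = _x(p2 - p1, p3 - p1)
        d2 = _x(p2 - p1, p4 - p1)
        d3 = _x(p4 - p3, p1 - p3)
        d4 = _x(p4 - p3, p2 - p3)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    # only the two non-adjacent edge pairs can properly intersect
    return not (_seg_cross(edges[0], edges[2]) or _seg_cross(edges[1], edges[3]))


def polygon_states(points4: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame polygon state for a quadruple's positions.

    ``points4``: (n_frames, 4, 2).  Returns ``(cycle_idx, corners)`` where
    ``cycle_idx`` in {0,1,2} indexes the minimising cyclic class and
    ``corners`` is 3/4/``DEGENERATE``.
    """
    per = _cycle_perimeters(points4)
    cycle_idx = per.argmin(axis=-1)
    corners = _hull_corners_vec(points4)
    return cycle_idx, corners


def _debounce(times: np.ndarray, debounce: float, rule: str) -> np.ndarray:
    """Mask of events surviving the repeat filter.

    ``rule='exclude'`` drops every event that repeats within ``debounce``
    seconds of a neighbour (both members of a close pair go — only isolated
    events are kept).  ``rule='keep-first'`` greedily keeps the earlier
    event of any close pair.
    """
    times = np.asarray(times, dtype=float)
    n = len(times)
    if rule == "exclude":
        keep = np.ones(n, dtype=bool)
        close = np.diff(times) < debounce
        keep[1:][close] = False
        keep[:-1][close] = False
        return keep
    if rule == "keep-first":
        keep = np.zeros(n, dtype=bool)
        last = -np.inf
        for i, t in enumerate(times):
            if t - last >= debounce:
                keep[i] = True
                last = t
        return keep
    raise ValueError("debounce rule must be 'exclude' or 'keep-first'")


def detect_transitions(
    traj: TrialTrajectory,
    item_ids,
    debounce: float = 0.5,
    start_excl: float = 0.5,
    end_excl: float = 0.5,
    set_label: str | None = None,
    debounce_mode: str = "per-type",
    debounce_rule: str = "exclude",
) -> pd.DataFrame:
    """Detect flip / concave / convex transitions for one item quadruple.

    Raw events are recorded at the later frame of each qualifying frame
    pair; degenerate frames carry the last valid state forward and trigger
    no events themselves.  The repeat filter then drops events recurring
    within ``debounce`` seconds — by default per event type and excluding
    every member of a close pair (only isolated events survive;
    ``debounce_rule='keep-first'`` instead keeps the earlier one, and
    ``debounce_mode='global'`` filters across types).  Finally events
    within ``start_excl`` of motion onset or ``end_excl`` of motion offset
    are excluded.
    """
    item_ids = np.asarray(item_ids)
    if item_ids.size != 4:
        raise ValueError("transition detection is defined for quadruples")
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    if debounce_mode not in ("per-type", "global"):
        raise ValueError("debounce_mode must be 'per-type' or 'global'")
    if set_label is None:
        set_label = "target" if np.array_equal(np.sort(item_ids), np.sort(traj.target_ids)) else "distractor"

    pts = traj.positions[item_ids].transpose(1, 0, 2)  # (n_frames, 4, 2)
    cycle_idx, corners = polygon_states(pts)
    valid = corners != DEGENERATE

    rows: list[tuple[str, int]] = []
    last_cycle = None
    last_corners = None
    for f in range(traj.n_frames):
        if not valid[f]:
            continue
        if last_corners is not None:
            if last_corners == 3 and corners[f] == 4:
                rows.append(("convex", f))
            elif last_corners == 4 and corners[f] == 3:
                rows.append(("concave", f))
            if cycle_idx[f] != last_cycle:
                rows.append(("flip", f))
        last_cycle = cycle_idx[f]
        last_corners = int(corners[f])

    frames = np.array([f for _, f in rows], dtype=int)
    types = np.array([t for t, _ in rows], dtype=object)
    times = frames / traj.frame_rate

    if len(rows):
        if debounce_mode == "per-type":
            keep = np.zeros(len(rows), dtype=bool)
            for et in EVENT_TYPES:
                mask = types == et
                keep[mask] = _debounce(times[mask], debounce, debounce_rule)
        else:
            keep = _debounce(times, debounce, debounce_rule)
        frames, types, times = frames[keep], types[keep], times[keep]
        inb = (times >= start_excl) & (times <= traj.duration - end_excl)
        frames, types, times = frames[inb], types[inb], times[inb]

    return pd.DataFrame(
        {
            "trial_id": np.full(len(frames), traj.trial_id, dtype=int),
            "set_label": np.full(len(frames), set_label, dtype=object),
            "event_type": types,
            "time_s": times,
            "frame": frames,
        },
        columns=EVENT_COLUMNS,
    )


def detect_session_events(
    trials: list[TrialTrajectory],
    which: str = "target",
    debounce: float = 0.5,
    start_excl: float = 0.5,
    end_excl: float = 0.5,
    debounce_mode: str = "per-type",
    debounce_rule: str = "exclude",
) -> pd.DataFrame:
    """Event table over a whole session, for the target and/or distractor set."""
    sets = ("target", "distractor") if which == "both" else (which,)
    frames = []
    for traj in trials:
        for s in sets:
            frames.append(
                detect_transitions(
                    traj,
                    traj.item_set(s),
                    debounce=debounce,
                    start_excl=start_excl,
                    end_excl=end_excl,
                    set_label=s,
                    debounce_mode=debounce_mode,
                    debounce_rule=debounce_rule,
                )
            )
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["trial_id", "time_s"], kind="stable").reset_index(drop=True)
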
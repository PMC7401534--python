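"""Factorial geometry and counterbalanced scheduling of the perch-transition study.

The experiment crosses jump direction (up/down), angle class (flat/steep) and
diagonal distance (50/100 cm) into eight conditions. Forty hens of two hybrids
(Nick Chick, Brown Nick) housed in eight pens each complete every condition
once, giving 320 test sessions spread over 16 testing days with half of the
pens tested per day.

Angles are measured from the horizontal at the take-off platform and the
distance is the diagonal platform-to-perch distance, so the landing-perch
height follows as ``platform_height ± distance * sin(angle)`` and the
horizontal offset as ``distance * cos(angle)``. With platform heights of 60 cm
(up) and 135 cm (down) this reproduces the identity that the up/flat/50 and
down/steep/100 perches sit at the same height (85 cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "GeometryLayout",
    "Schedule",
    "ScheduleError",
    "ALL_CONDITIONS",
    "PLATFORM_HEIGHT_CM",
    "angle_for",
    "resolve_geometry",
    "ramp_length",
    "make_schedule",
    "read_schedule",
    "write_schedule",
]

DIRECTIONS = ("up", "down")
ANGLE_CLASSES = ("flat", "steep")
DISTANCES_CM = (50.0, 100.0)

#: Take-off platform height above ground, per jump direction (cm).
PLATFORM_HEIGHT_CM = {"up": 60.0, "down": 135.0}

# Angle from the horizontal, degrees: flat 30/steep 60 upward, flat 15/steep 30
# downward.
_ANGLE_DEG = {
    ("up", "flat"): 30.0,
    ("up", "steep"): 60.0,
    ("down", "flat"): 15.0,
    ("down", "steep"): 30.0,
}


class ScheduleError(ValueError):
    """Raised when a counterbalanced schedule cannot be constructed."""


def angle_for(direction: str, angle_class: str) -> float:
    """Angle from the horizontal, in degrees, for a direction/angle-class pair."""
    try:
        return _ANGLE_DEG[(direction, angle_class)]
    except KeyError:
        raise ValueError(
            f"unknown direction/angle_class combination: {direction!r}/{angle_class!r}"
        ) from None


@dataclass(frozen=True)
class Condition:
    """One cell of the 2x2x2 perch-positioning design."""

    direction: str
    angle_class: str
    distance_cm: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction: {self.direction!r}")
        if self.angle_class not in ANGLE_CLASSES:
            raise ValueError(f"unknown angle_class: {self.angle_class!r}")
        if self.distance_cm <= 0:
            raise ValueError("distance_cm must be positive")

    @property
    def angle_deg(self) -> float:
        return angle_for(self.direction, self.angle_class)

    @property
    def label(self) -> str:
        return f"{self.direction}/{self.angle_class}/{self.distance_cm:g}"

    @property
    def within_direction_label(self) -> str:
        """Condition label ignoring direction (4 levels: distance x angle)."""
        return f"{self.distance_cm:g}cm_{self.angle_class}"


#: The eight conditions, in a fixed canonical order.
ALL_CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(d, a, s) for d in DIRECTIONS for a in ANGLE_CLASSES for s in DISTANCES_CM
)


@dataclass(frozen=True)
class GeometryLayout:
    """Resolved apparatus geometry for one condition (all lengths in cm)."""

    platform_height_cm: float
    perch_height_cm: float
    horizontal_offset_cm: float


def resolve_geometry(condition: Condition) -> GeometryLayout:
    """Resolve platform/perch geometry for a condition.

    The perch is placed at the diagonal distance from the platform edge, above
    it for upward and below it for downward jumps.
    """
    angle = math.radians(condition.angle_deg)
    platform = PLATFORM_HEIGHT_CM[condition.direction]
    rise = condition.distance_cm * math.sin(angle)
    perch = platform + rise if condition.direction == "up" else platform - rise
    return GeometryLayout(
        platform_height_cm=platform,
        perch_height_cm=perch,
        horizontal_offset_cm=condition.distance_cm * math.cos(angle),
    )


def ramp_length(platform_height_m: float, incline_deg: float) -> float:
    """Length of a ramp reaching ``platform_height_m`` at ``incline_deg`` from the floor.

    Returns the hypotenuse in metres, rounded to 2 decimals. The home-pen ramp
    (1.3 m platform, 47 degrees) comes out at 1.78 m.
    """
    if platform_height_m <= 0:
        raise ValueError("platform height must be positive")
    if not 0 < incline_deg <= 90:
        raise ValueError("incline must be in (0, 90] degrees")
    return round(platform_height_m / math.sin(math.radians(incline_deg)), 2)


SCHEDULE_COLUMNS = [
    "session_id",
    "day",
    "order",
    "hen_id",
    "pen",
    "hybrid",
    "direction",
    "angle_class",
    "distance_cm",
]


@dataclass
class Schedule:
    """Ordered table of test sessions plus the seed that produced it."""

    sessions: pd.DataFrame
    seed: int
    balance_tolerance: float = 1.0
    n_jumps: int = 5
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def n_jumps_total(self) -> int:
        return len(self.sessions) * self.n_jumps

    def condition_of(self, row: pd.Series) -> Condition:
        return Condition(row["direction"], row["angle_class"], float(row["distance_cm"]))


def _latin_square(k: int, rng: np.random.Generator) -> np.ndarray:
    """Random k x k Latin square: cyclic square with rows/cols/symbols permuted."""
    base = (np.arange(k)[:, None] + np.arange(k)[None, :]) % k
    rows = rng.permutation(k)
    cols = rng.permutation(k)
    syms = rng.permutation(k)
    return syms[base[rows][:, cols]]


def _balance_diagnostics(sessions: pd.DataFrame) -> dict:
    """Mean within-day rank and mean day-slot per condition label."""
    df = sessions.copy()
    df["cond"] = df["direction"] + "/" + df["angle_class"] + "/" + df["distance_cm"].astype(str)
    # day slot: index of the testing day within each hen's own sequence
    df["day_slot"] = df.groupby("hen_id")["day"].rank(method="dense") - 1
    grand_rank = df["order"].mean()
    grand_slot = df["day_slot"].mean()
    per_cond = df.groupby("cond").agg(mean_order=("order", "mean"), mean_slot=("day_slot", "mean"))
    return {
        "grand_mean_order": float(grand_rank),
        "grand_mean_day_slot": float(grand_slot),
        "max_abs_order_dev": float((per_cond["mean_order"] - grand_rank).abs().max()),
        "max_abs_slot_dev": float((per_cond["mean_slot"] - grand_slot).abs().max()),
        "per_condition": per_cond,
    }


def make_schedule(
    roster: pd.DataFrame,
    n_days: int = 16,
    seed: int = 0,
    balance_tolerance: float = 1.0,
    n_jumps: int = 5,
) -> Schedule:
    """Build a counterbalanced schedule assigning every hen to every condition.

    Pens are split into two day-groups (half of the pens tested per day); each
    hen is tested once per testing day of its group, and the order of the eight
    conditions across a hen's days follows a seeded random Latin square built
    separately within each hybrid stratum, so that within each hybrid every
    condition occupies every day-slot equally often. The within-day testing
    order cycles across days to balance time of day. A tolerance-based balance
    check on within-day rank is applied rather than an exact combinatorial
    optimum.

    Parameters
    ----------
    roster : DataFrame with columns hen_id, pen, hybrid (body-mass columns are
        carried along if present but not used here).
    n_days : number of testing days (16 by default: two pen groups of 8 days).
    """
    required = {"hen_id", "pen", "hybrid"}
    if not required.issubset(roster.columns):
        raise ValueError(f"roster must have columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    k = len(ALL_CONDITIONS)

    pens = sorted(roster["pen"].unique())
    if len(pens) >= 2:
        groups = {pen: i % 2 for i, pen in enumerate(pens)}
        n_groups = 2
    else:
        groups = {pens[0]: 0}
        n_groups = 1
    days_per_group = n_days // n_groups
    if days_per_group < k:
        raise ScheduleError(
            f"{n_days} days with {n_groups} pen group(s) gives only "
            f"{days_per_group} testing days per hen; {k} conditions need {k}"
        )

    # Per-hybrid Latin squares: row i is the condition order of the i-th hen
    # of that hybrid (cycled if more hens than conditions).
    squares = {h: _latin_square(k, rng) for h in sorted(roster["hybrid"].unique())}
    hybrid_counter: dict[str, int] = {}

    hen_orders: dict = {}
    for _, hen in roster.sort_values(["pen", "hen_id"]).iterrows():
        h = hen["hybrid"]
        i = hybrid_counter.get(h, 0)
        hybrid_counter[h] = i + 1
        row = squares[h][i % k]
        if i >= k:  # extra cyclic shift so repeats of a row are staggered
            row = np.roll(row, i // k)
        hen_orders[hen["hen_id"]] = row

    roster_idx = roster.set_index("hen_id")
    records = []
    session_id = 0
    for day in range(1, n_days + 1):
        g = (day - 1) % n_groups
        slot = (day - 1) // n_groups  # this group's day-slot index (0..k-1)
        if slot >= k:
            continue
        day_hens = [h for h in roster["hen_id"] if groups[roster_idx.loc[h, "pen"]] == g]
        # rotate within-day order across slots to balance time of day
        rot = (slot * max(1, len(day_hens) // k)) % max(1, len(day_hens))
        day_hens = day_hens[rot:] + day_hens[:rot]
        for order, hen_id in enumerate(day_hens, start=1):
            cond = ALL_CONDITIONS[hen_orders[hen_id][slot]]
            session_id += 1
            records.append(
                {
                    "session_id": session_id,
                    "day": day,
                    "order": order,
                    "hen_id": hen_id,
                    "pen": roster_idx.loc[hen_id, "pen"],
                    "hybrid": roster_idx.loc[hen_id, "hybrid"],
                    "direction": cond.direction,
                    "angle_class": cond.angle_class,
                    "distance_cm": cond.distance_cm,
                }
            )
    sessions = pd.DataFrame.from_records(records, columns=SCHEDULE_COLUMNS)

    counts = sessions.groupby("hen_id").size()
    if not (counts == k).all():
        raise ScheduleError(f"scheduling failed: per-hen session counts {counts.to_dict()}")
    diag = _balance_diagnostics(sessions)
    # exact slot balance needs >= k hens per stratum; scale the tolerance for
    # smaller studies where only part of each Latin square is used
    effective_tol = balance_tolerance * max(1.0, 2.0 * k / max(len(roster), 1))
    diag["effective_tolerance"] = effective_tol
    if len(roster) >= k and diag["max_abs_slot_dev"] > effective_tol:
        raise ScheduleError(
            "counterbalancing infeasible: max day-slot deviation "
            f"{diag['max_abs_slot_dev']:.3f} exceeds tolerance {effective_tol}"
        )
    return Schedule(sessions, seed=seed, balance_tolerance=balance_tolerance,
                    n_jumps=n_jumps, diagnostics=diag)


def write_schedule(schedule: Schedule, path) -> None:
    schedule.sessions.to_csv(path, index=False)


def read_schedule(path, seed: int = -1, n_jumps: int = 5) -> Schedule:
    df = pd.read_csv(path)
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    return Schedule(df[SCHEDULE_COLUMNS], seed=seed, n_jumps=n_jumps)
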
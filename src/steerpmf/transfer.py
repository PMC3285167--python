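"""Proton-transfer analysis of trajectories.

The transfer coordinate for a donor D, hydrogen H, acceptor A is

    q(t) = d(D, H) − d(A, H)   (Å)

— negative while the hydrogen is closer to the donor, zero exactly at the
midpoint of the donor–acceptor separation, positive after transfer.  This is
the LCOD variable with pairs [(D, H), (A, H)] and coefficients (+1, −1); the
identity is exact and package-wide.  "Heavy-atom departure" coordinates are
expressed with the departing heavy atom in the hydrogen slot of the same
machinery.

Event detection is geometric and deliberately simple: a transfer event is a
sign change that establishes itself beyond a hysteresis band ±h and persists
for at least ``min_dwell_frames`` consecutive frames, so thermal recrossings
shorter than the dwell are excluded.  Precisely:

* each frame has a side: −1 if q < −h, +1 if q > +h, else 0 (inside the band);
* the series is compressed to maximal runs of equal nonzero side; runs
  shorter than ``min_dwell_frames`` are ignored (treated as recrossing
  noise), as are in-band frames;
* the first surviving run fixes the initial side; every subsequent surviving
  run of opposite side registers one event;
* the event's ``crossing_time`` is the first frame at which q has the sign
  of the new side, searched forward from the last frame that was beyond the
  *old* side's threshold; ``post_dwell`` is the length of the establishing
  run and ``pre_dwell`` the length of the run that established the old side.

Two events from different coordinate series are *concomitant* when they fall
within one window of each other (default: the trajectory sampling interval) —
the finest statement the sampling resolution supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import Trajectory
from .lcod import LCODSpec, eval_lcod

__all__ = [
    "TransferCoordinateSeries",
    "TransferEvent",
    "ConcomitancePair",
    "PathwayResult",
    "transfer_coordinate",
    "detect_events",
    "concomitance",
    "classify_pathway",
]


@dataclass
class TransferCoordinateSeries:
    """A d(D,H) − d(A,H) series with its atom identities."""

    times: np.ndarray           # ps
    values: np.ndarray          # Å
    donor: int
    hydrogen: int
    acceptor: int
    sampling_interval: float    # ps
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    @property
    def coordinate_id(self) -> str:
        return self.label or f"d({self.donor},{self.hydrogen})-d({self.acceptor},{self.hydrogen})"


@dataclass(frozen=True)
class TransferEvent:
    """A sustained sign change of a transfer coordinate."""

    crossing_time: float        # ps
    pre_dwell: int              # frames beyond the old side's threshold
    post_dwell: int             # frames beyond the new side's threshold
    coordinate_id: str
    direction: str              # "donor->acceptor" or "acceptor->donor"


@dataclass(frozen=True)
class ConcomitancePair:
    """Two events from different series within one resolution window."""

    event_a: TransferEvent
    event_b: TransferEvent
    delta_t: float
    window: float

    @property
    def note(self) -> str:
        return "concomitant within sampling resolution"


@dataclass
class PathwayResult:
    """Outcome of pathway classification for one trajectory."""

    label: str                                  # "direct" | "water_mediated" | "none"
    events: dict = field(default_factory=dict)  # coordinate name -> list[TransferEvent]
    concomitant: list = field(default_factory=list)
    ambiguous: bool = False
    final_partners: dict = field(default_factory=dict)  # hydrogen -> nearest heavy atom


def transfer_coordinate(
    trajectory: Trajectory, donor: int, hydrogen: int, acceptor: int,
    label: str = "",
) -> TransferCoordinateSeries:
    """Per-frame proton-transfer coordinate d(D,H) − d(A,H).

    Evaluated frame-by-frame through the LCOD machinery (pairs
    [(D,H), (A,H)], coefficients (+1, −1)), so it agrees with
    :func:`steerpmf.lcod.eval_lcod` identically.
    """
    spec = LCODSpec([(donor, hydrogen), (acceptor, hydrogen)], [1.0, -1.0])
    n_atoms = trajectory.positions.shape[1]
    if max(donor, hydrogen, acceptor) >= n_atoms:
        raise IndexError(
            f"atom index out of range for trajectory with {n_atoms} atoms"
        )
    values = np.array([eval_lcod(frame, spec) for frame in trajectory.positions])
    return TransferCoordinateSeries(
        times=trajectory.times.copy(),
        values=values,
        donor=donor,
        hydrogen=hydrogen,
        acceptor=acceptor,
        sampling_interval=trajectory.sampling_interval,
        label=label,
    )


def detect_events(
    series: TransferCoordinateSeries,
    min_dwell_frames: int = 4,
    hysteresis: float = 0.1,
) -> list[TransferEvent]:
    """Detect sustained sign changes of the transfer coordinate.

    See the module docstring for the exact run-based semantics.  Events are
    returned time-ordered; a series that never leaves one side yields an
    empty list.  The detector is invariant under uniform time translation
    and under prepending frames on the initial side.
    """
    if len(series.values) == 0:
        raise ValueError("cannot detect events in an empty series")
    if min_dwell_frames < 1:
        raise ValueError("min_dwell_frames must be >= 1")
    if hysteresis < 0:
        raise ValueError("hysteresis must be >= 0")
    v = series.values
    t = series.times
    side = np.where(v > hysteresis, 1, np.where(v < -hysteresis, -1, 0))

    # maximal runs of equal nonzero side: (side, start_index, length)
    runs: list[tuple[int, int, int]] = []
    i = 0
    n = len(v)
    while i < n:
        s = side[i]
        j = i
        while j < n and side[j] == s:
            j += 1
        if s != 0:
            runs.append((int(s), i, j - i))
        i = j
    surviving = [r for r in runs if r[2] >= min_dwell_frames]
    if not surviving:
        return []

    events: list[TransferEvent] = []
    current_side, cur_start, cur_len = surviving[0]
    for s, start, length in surviving[1:]:
        if s == current_side:
            current_side, cur_start, cur_len = s, start, length
            continue
        # crossing: first frame with the new side's sign after the last frame
        # beyond the old side's threshold
        k = start
        while k > 0 and side[k - 1] != current_side:
            k -= 1
        cross = k
        while cross < start and v[cross] * s <= 0:
            cross += 1
        direction = "donor->acceptor" if s > 0 else "acceptor->donor"
        events.append(TransferEvent(
            crossing_time=float(t[cross]),
            pre_dwell=cur_len,
            post_dwell=length,
            coordinate_id=series.coordinate_id,
            direction=direction,
        ))
        current_side, cur_start, cur_len = s, start, length
    return events


def concomitance(
    events_a: Sequence[TransferEvent],
    events_b: Sequence[TransferEvent],
    window: float,
) -> list[ConcomitancePair]:
    """Pairs of events (one from each list) with |Δt| ≤ window.

    The default window in the pipeline is one trajectory sampling interval:
    events closer than the sampling resolution are indistinguishable from
    simultaneous.
    """
    if not window > 0:
        raise ValueError("concomitance window must be positive")
    pairs = []
    for ea in events_a:
        for eb in events_b:
            dt = abs(ea.crossing_time - eb.crossing_time)
            if dt <= window:
                pairs.append(ConcomitancePair(ea, eb, float(dt), float(window)))
    return pairs


def _forward(events: Sequence[TransferEvent]) -> list[TransferEvent]:
    return [e for e in events if e.direction == "donor->acceptor"]


def classify_pathway(
    trajectory: Trajectory,
    roles: dict,
    min_dwell_frames: int = 4,
    hysteresis: float = 0.1,
    window: float | None = None,
) -> PathwayResult:
    """Classify a dehydration/transfer trajectory as direct, water-mediated
    or unreactive.

    ``roles`` maps role names to atom indices and must contain
    ``donor_acid``, ``acid_hydrogen``, ``water``, ``water_hydrogen`` and
    ``acceptor``.  Three transfer coordinates are scanned:

    * acid → water for the acid hydrogen,
    * water → acceptor for the water hydrogen,
    * acid → acceptor (direct) for the acid hydrogen.

    The trajectory is ``water_mediated`` when sustained forward events occur
    on *both* water legs (their concomitance within one sampling interval is
    reported) and ``direct`` when the acid hydrogen transfers straight to
    the acceptor while the water pattern is absent.  (A lone acid → water
    crossing does not veto ``direct``: any hydrogen that reaches a distant
    acceptor necessarily ends closer to an intervening water than to its
    origin, so that coordinate fires on geometry alone; water *participation*
    requires the water hydrogen to move on as well.)  If both patterns
    appear the result keeps the water-mediated label but carries an
    ``ambiguous`` flag rather than raising.  As provenance, each hydrogen's
    nearest role heavy atom in the final frame is reported — the geometric
    analogue of checking product-structure atom identities.
    """
    required = ("donor_acid", "acid_hydrogen", "water", "water_hydrogen", "acceptor")
    missing = [r for r in required if r not in roles]
    if missing:
        raise KeyError(f"roles missing required entries: {missing}")
    acid = roles["donor_acid"]
    h_acid = roles["acid_hydrogen"]
    water = roles["water"]
    h_water = roles["water_hydrogen"]
    acceptor = roles["acceptor"]

    coords = {
        "acid->water": transfer_coordinate(trajectory, acid, h_acid, water,
                                           label="acid->water"),
        "water->acceptor": transfer_coordinate(trajectory, water, h_water, acceptor,
                                               label="water->acceptor"),
        "acid->acceptor": transfer_coordinate(trajectory, acid, h_acid, acceptor,
                                              label="acid->acceptor"),
    }
    events = {
        name: detect_events(series, min_dwell_frames, hysteresis)
        for name, series in coords.items()
    }
    if window is None:
        window = trajectory.sampling_interval or 1.0

    water_leg_1 = _forward(events["acid->water"])
    water_leg_2 = _forward(events["water->acceptor"])
    direct_leg = _forward(events["acid->acceptor"])

    water_mediated = bool(water_leg_1 and water_leg_2)
    direct = bool(direct_leg)
    both = water_mediated and direct

    if water_mediated:
        label = "water_mediated"
    elif direct:
        label = "direct"
    else:
        label = "none"

    concomitant = (
        concomitance(water_leg_1, water_leg_2, window) if water_mediated else []
    )

    # provenance: nearest role heavy atom to each hydrogen in the last frame
    last = trajectory.positions[-1]
    heavies = {"donor_acid": acid, "water": water, "acceptor": acceptor}
    partners = {}
    for h_name, h_idx in (("acid_hydrogen", h_acid), ("water_hydrogen", h_water)):
        dists = {name: float(np.linalg.norm(last[h_idx] - last[idx]))
                 for name, idx in heavies.items()}
        partners[h_name] = min(dists, key=dists.get)

    return PathwayResult(
        label=label,
        events=events,
        concomitant=concomitant,
        ambiguous=both,
        final_partners=partners,
    )
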
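"""Gameplay analytics: the three per-game outcomes and event-log summaries.

The three reported outcomes per game are

* mean hours in ideal glucose range (5-9 mmol/L for T1D/T2D, 5-7 for GD),
  averaged over every NPC that was ever active;
* metformin errors — the number of distinct NPCs given metformin while
  renally contraindicated (per NPC, not per dose);
* evacuations — the number of NPCs that fainted and were removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .dynamics import GlucoseTrace
from .events import EventRecord
from .world import WorldState

__all__ = ["GameMetrics", "hours_in_ideal_range", "count_metformin_errors",
           "count_evacuations", "summarize_game", "traces_frame"]


@dataclass(frozen=True)
class GameMetrics:
    mean_hours_ideal: float
    metformin_errors: int
    evacuations: int
    per_npc: pd.DataFrame  # npc_id, phenotype, status, hours_ideal

    def to_row(self, **extra) -> dict:
        row = {"mean_hours_ideal": self.mean_hours_ideal,
               "metformin_errors": self.metformin_errors,
               "evacuations": self.evacuations}
        row.update(extra)
        return row


def hours_in_ideal_range(trace: GlucoseTrace,
                         ideal_range: tuple[float, float]) -> float:
    """Hours a trace spends inside the closed target interval.

    Each sub-step interval is counted by its left-endpoint sample, so a trace
    of N samples contributes up to (N-1)*dt hours.  Empty traces yield 0.
    """
    if not trace.values:
        return 0.0
    lo, hi = ideal_range
    n_in = sum(1 for g in trace.values[:-1] if lo <= g <= hi)
    return n_in * trace.dt_hours


def count_metformin_errors(log: Sequence[EventRecord]) -> int:
    """Distinct NPCs with at least one contraindicated metformin dose."""
    flagged = {ev.npc_id for ev in log
               if ev.kind == "action"
               and ev.payload.get("action_kind") == "metformin"
               and ev.payload.get("contraindicated")}
    return len(flagged)


def count_evacuations(log: Sequence[EventRecord]) -> int:
    """Number of faint events (= NPCs evacuated; faints are permanent)."""
    return sum(1 for ev in log if ev.kind == "faint")


def traces_frame(world: WorldState) -> pd.DataFrame:
    """All AGP traces as a long table (npc_id, time_hours, glucose_mmol_per_L).

    Includes removed and evacuated NPCs up to their exit; suitable for CSV
    export and plotting.
    """
    rows = []
    for npc in world.all_ever_active():
        for t, g in zip(npc.trace.times(), npc.trace.values):
            rows.append((npc.id, t, g))
    return pd.DataFrame(rows, columns=["npc_id", "time_hours",
                                       "glucose_mmol_per_L"])


def summarize_game(world: WorldState) -> GameMetrics:
    """Compute the per-game outcome metrics from a finished world.

    The mean-hours denominator is every NPC that was ever active, including
    evacuated and facilitator-removed NPCs (which contribute the hours they
    accrued before leaving).  Frozen intervals count as in-range iff the
    frozen value lies in range — the trace carries the flat samples.
    """
    if not world.game_over:
        raise ValueError("game not over yet")
    npcs = world.all_ever_active()
    if not npcs:
        raise ValueError("no NPCs ever active; mean undefined")
    rows = []
    for npc in npcs:
        h = hours_in_ideal_range(npc.trace, npc.phenotype.ideal_range)
        rows.append({"npc_id": npc.id, "phenotype": npc.phenotype.label,
                     "status": npc.status if npc.id in world.npcs else "removed",
                     "hours_ideal": h})
    per_npc = pd.DataFrame(rows)
    return GameMetrics(
        mean_hours_ideal=float(per_npc["hours_ideal"].mean()),
        metformin_errors=count_metformin_errors(world.events),
        evacuations=count_evacuations(world.events),
        per_npc=per_npc,
    )
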
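"""Facilitator engine: check-in schedule, moderation actions, difficulty
policy, and evacuation explanations.

The facilitator leaves the player alone for the first three in-game hours,
then checks in every two hours ("How are you faring?").  Depending on the
player's feedback they may freeze, unfreeze, add, or remove NPCs — the
difficulty dial of the game.  When an NPC faints, the facilitator explains
the cause in one sentence, attributed by scanning the event log for the
largest culpable dose or un-covered meal in a lookback window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .events import EventRecord
from .world import WorldState, NPC, PHENOTYPES, generate_npc

__all__ = [
    "FacilitatorRequest", "CheckinFeedback", "EvacuationExplanation",
    "checkin_ticks", "apply_request", "moderation_policy",
    "attribute_evacuation_cause",
]

#: Default phenotype mix for facilitator-added NPCs (same 7:2:1 incidence
#: as the starting population).
ADD_WEIGHTS = {"T2D": 7, "T1D": 2, "GD": 1}

OVERWHELMED = "overwhelmed"
COMFORTABLE = "comfortable"
UNDER_CHALLENGED = "under_challenged"


@dataclass(frozen=True)
class FacilitatorRequest:
    kind: str  # add_npc | remove_npc | freeze | unfreeze | no_action
    target: Optional[str] = None  # NPC id (or phenotype label for add_npc)

    def __post_init__(self) -> None:
        if self.kind not in ("add_npc", "remove_npc", "freeze",
                             "unfreeze", "no_action"):
            raise ValueError(f"unknown request kind {self.kind!r}")


@dataclass(frozen=True)
class CheckinFeedback:
    level: str  # overwhelmed | comfortable | under_challenged
    requested_delta: Optional[int] = None

    def __post_init__(self) -> None:
        if self.level not in (OVERWHELMED, COMFORTABLE, UNDER_CHALLENGED):
            raise ValueError(f"unknown feedback level {self.level!r}")


@dataclass(frozen=True)
class EvacuationExplanation:
    npc_id: str
    direction: str  # hypo | hyper
    attributed_cause: str  # event reference like "bolus@5.25h" or "unmanaged"
    message: str


def checkin_ticks(duration_ticks: int) -> list[int]:
    """Check-in schedule: tick 3, then every 2 ticks, while the game lasts.

    The first three ticks are always facilitator-free (the player plays
    solo).  A 12-tick game yields check-ins at {3, 5, 7, 9, 11}.
    """
    if duration_ticks < 0:
        raise ValueError("duration must be >= 0")
    return list(range(3, duration_ticks, 2))


def _distance_from_range(npc: NPC) -> float:
    lo, hi = npc.phenotype.ideal_range
    g = npc.trace.last
    return max(0.0, lo - g, g - hi)


def apply_request(world: WorldState, request: FacilitatorRequest) -> WorldState:
    """Apply one facilitator moderation request to the world.

    Invalid requests (unknown target, unfreeze on a non-frozen NPC, any
    request against an evacuated NPC) are rejected with a logged warning
    rather than an exception — the game never crashes on moderation.
    """
    kind = request.kind
    if kind == "no_action":
        world.log("facilitator_request", payload={"request": "no_action"})
        return world

    if kind == "add_npc":
        label = request.target or "T2D"
        if label not in PHENOTYPES:
            world.log("warning", payload={"reason": f"unknown phenotype {label!r}"})
            return world
        n_in_play = sum(1 for n in world.npcs.values()
                        if n.status != "evacuated")
        if n_in_play >= world.config.max_npcs:
            world.log("warning", payload={"reason": "max_npcs reached"})
            return world
        npc = generate_npc(label, world.rng, world.next_npc_id(),
                           world.config, joined_tick=world.tick)
        world.npcs[npc.id] = npc
        world.log("facilitator_request", npc.id,
                  {"request": "add_npc", "phenotype": label})
        return world

    npc = world.npcs.get(request.target or "")
    if npc is None:
        world.log("warning", request.target,
                  {"reason": "facilitator request targets unknown NPC",
                   "request": kind})
        return world
    if npc.status == "evacuated":
        world.log("warning", npc.id,
                  {"reason": "facilitator request targets evacuated NPC",
                   "request": kind})
        return world

    if kind == "freeze":
        if npc.status == "frozen":
            world.log("warning", npc.id, {"reason": "already frozen"})
            return world
        npc.status = "frozen"
        world.log("facilitator_request", npc.id, {"request": "freeze"})
    elif kind == "unfreeze":
        if npc.status != "frozen":
            world.log("warning", npc.id,
                      {"reason": "unfreeze on non-frozen NPC"})
            return world
        npc.status = "active"
        world.log("facilitator_request", npc.id, {"request": "unfreeze"})
    elif kind == "remove_npc":
        world.removed[npc.id] = world.npcs.pop(npc.id)
        world.log("facilitator_request", npc.id, {"request": "remove_npc"})
    return world


def moderation_policy(feedback: CheckinFeedback, world: WorldState,
                      rng: Optional[np.random.Generator] = None
                      ) -> FacilitatorRequest:
    """Map check-in feedback to a single moderation request.

    * overwhelmed       -> freeze the active NPC furthest from its ideal
                           range (relief without the finality of removal);
    * comfortable       -> no action;
    * under_challenged  -> unfreeze a frozen NPC if one exists, otherwise
                           add a new NPC with phenotype drawn 7:2:1.
    """
    if feedback.level == COMFORTABLE:
        return FacilitatorRequest("no_action")
    if feedback.level == OVERWHELMED:
        active = world.active_npcs()
        if not active:
            return FacilitatorRequest("no_action")
        worst = max(active, key=lambda n: (_distance_from_range(n), n.id))
        return FacilitatorRequest("freeze", worst.id)
    # under_challenged
    frozen = [n for n in sorted(world.npcs.values(), key=lambda n: n.id)
              if n.status == "frozen"]
    if frozen:
        return FacilitatorRequest("unfreeze", frozen[0].id)
    labels = list(ADD_WEIGHTS)
    w = np.array([ADD_WEIGHTS[l] for l in labels], dtype=float)
    if rng is None:
        label = labels[0]
    else:
        label = labels[int(rng.choice(len(labels), p=w / w.sum()))]
    return FacilitatorRequest("add_npc", label)


def _event_time(ev: EventRecord, substeps_per_tick: int) -> float:
    return ev.tick + ev.substep / substeps_per_tick


def attribute_evacuation_cause(log: Sequence[EventRecord], npc_id: str,
                               faint_event: EventRecord,
                               lookback_hours: float = 3.0,
                               substeps_per_tick: int = 12
                               ) -> EvacuationExplanation:
    """Explain why an NPC fainted, from the event log alone.

    Hypoglycaemic faints are attributed to the largest insulin bolus in the
    preceding lookback window; hyperglycaemic faints to the largest meal not
    covered by a later bolus.  Ties break toward the most recent event; with
    nothing culpable in the window the cause is "unmanaged".
    """
    if faint_event.kind != "faint" or faint_event.npc_id != npc_id:
        raise ValueError("faint_event must be a faint event for npc_id")
    t_faint = faint_event.payload.get(
        "time_hours", _event_time(faint_event, substeps_per_tick))
    direction = faint_event.payload.get("direction", "hypo")
    window_start = t_faint - lookback_hours

    def in_window(ev: EventRecord) -> bool:
        t = _event_time(ev, substeps_per_tick)
        return window_start <= t <= t_faint and ev.seq < faint_event.seq

    cause = "unmanaged"
    if direction == "hypo":
        boluses = [ev for ev in log
                   if ev.kind == "action" and ev.npc_id == npc_id
                   and ev.payload.get("action_kind") == "bolus"
                   and ev.payload.get("dose", 0) > 0 and in_window(ev)]
        if boluses:
            best = max(boluses, key=lambda e: (e.payload["dose"], e.seq))
            hrs_ago = t_faint - _event_time(best, substeps_per_tick)
            cause = f"bolus@{_event_time(best, substeps_per_tick):.2f}h"
            msg = (f"{npc_id} received too much bolus insulin "
                   f"({best.payload['dose']:g} units, {hrs_ago:.1f} hours ago) "
                   f"and became hypoglycemic.")
        else:
            msg = (f"{npc_id} became hypoglycemic without a recent insulin "
                   f"dose (unmanaged).")
    else:
        meals = [ev for ev in log
                 if ev.kind == "meal" and ev.npc_id == npc_id and in_window(ev)]
        bolus_times = [_event_time(ev, substeps_per_tick) for ev in log
                       if ev.kind == "action" and ev.npc_id == npc_id
                       and ev.payload.get("action_kind") == "bolus"
                       and ev.payload.get("dose", 0) > 0]
        uncovered = [ev for ev in meals
                     if not any(_event_time(ev, substeps_per_tick) <= bt <= t_faint
                                for bt in bolus_times)]
        if uncovered:
            best = max(uncovered, key=lambda e: (e.payload["carbs"], e.seq))
            hrs_ago = t_faint - _event_time(best, substeps_per_tick)
            cause = f"meal@{_event_time(best, substeps_per_tick):.2f}h"
            msg = (f"{npc_id} ate a large meal "
                   f"({best.payload['carbs']:.0f} g carbs, {hrs_ago:.1f} hours "
                   f"ago) without insulin cover and became hyperglycemic.")
        else:
            msg = (f"{npc_id}'s glucose ran high without correction "
                   f"(unmanaged) and they became hyperglycemic.")
    return EvacuationExplanation(npc_id=npc_id, direction=direction,
                                 attributed_cause=cause, message=msg)
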
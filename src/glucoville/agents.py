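"""Scripted player policies of parameterized skill.

These stand in for human players so that facilitated and unfacilitated games
can be simulated at scale.  The policy is deliberately heuristic — threshold
triggers, proportional doses, an attention budget — not optimal control: its
purpose is to exercise the simulator with behaviour whose quality varies
smoothly with a single ``skill`` knob.

Skill enters in three ways: low-skill players sometimes fail to act at all,
mis-dose more often (a mis-dosed bolus is tripled, a mis-dosed snack
quartered), and neglect to check renal function before giving metformin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import PlayerAction
from .facilitation import (CheckinFeedback, COMFORTABLE, OVERWHELMED,
                           UNDER_CHALLENGED)
from .world import WorldState

__all__ = ["PlayerPolicyParams", "NPCView", "make_player_view",
           "scripted_player", "checkin_feedback"]

BOLUS_MISDOSE_FACTOR = 3.0
SNACK_MISDOSE_FACTOR = 0.25
BASE_MISDOSE_PROB = 0.3
BASE_ACT_PROB = 0.4  # probability of acting at all, at skill 0
METFORMIN_PROB = 0.6  # chance of reaching for metformin on a high T2D NPC


@dataclass(frozen=True)
class PlayerPolicyParams:
    skill: float = 0.5
    reaction_window: int = 2  # ticks of trace inspected for trend
    attention_budget: int = 3  # max NPCs acted on per tick
    misdose_prob: Optional[float] = None  # default: BASE * (1 - skill)

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill <= 1.0:
            raise ValueError("skill must be in [0, 1]")
        if self.attention_budget < 1:
            raise ValueError("attention_budget must be >= 1")
        if self.misdose_prob is not None and not 0.0 <= self.misdose_prob <= 1.0:
            raise ValueError("misdose_prob must be in [0, 1]")

    @property
    def effective_misdose_prob(self) -> float:
        if self.misdose_prob is not None:
            return self.misdose_prob
        return BASE_MISDOSE_PROB * (1.0 - self.skill)

    @property
    def act_prob(self) -> float:
        return BASE_ACT_PROB + (1.0 - BASE_ACT_PROB) * self.skill


@dataclass(frozen=True)
class NPCView:
    """What the player sees of one NPC: trace window, status, history."""

    npc_id: str
    status: str  # active | frozen
    phenotype: str
    ideal_range: tuple[float, float]
    renal_impaired: bool  # visible via clinical history
    metformin_given: bool  # visible via past-action list
    recent: tuple[float, ...]  # most recent trace samples, oldest first


def make_player_view(world: WorldState,
                     reaction_window: int = 2) -> list[NPCView]:
    """Build the player's view of the world; evacuated NPCs are not shown."""
    k = max(2, reaction_window * world.config.substeps_per_tick)
    views = []
    for npc in sorted(world.npcs.values(), key=lambda n: n.id):
        if npc.status == "evacuated":
            continue
        views.append(NPCView(
            npc_id=npc.id, status=npc.status, phenotype=npc.phenotype.label,
            ideal_range=npc.phenotype.ideal_range,
            renal_impaired=npc.physiology.renal_impaired,
            metformin_given=npc.metformin_given,
            recent=tuple(npc.trace.values[-k:]),
        ))
    return views


def _distance(view: NPCView) -> float:
    lo, hi = view.ideal_range
    g = view.recent[-1]
    return max(0.0, lo - g, g - hi)


def _slope_per_hour(view: NPCView, dt_hours: float) -> float:
    if len(view.recent) < 2:
        return 0.0
    span = (len(view.recent) - 1) * dt_hours
    return (view.recent[-1] - view.recent[0]) / span


def scripted_player(view: list[NPCView], params: PlayerPolicyParams,
                    rng: np.random.Generator,
                    dt_hours: float = 1.0 / 12.0) -> list[PlayerAction]:
    """Decide this tick's player actions from the visible NPC traces.

    Out-of-range active NPCs are prioritized by distance from their ideal
    range; at most ``attention_budget`` are acted on.  Above range the player
    gives a corrective bolus proportional to the excess (plus a metformin
    option for T2D NPCs not yet dosed); below range, a rescue snack.  Frozen
    NPCs are never targeted.  All NPCs in range means no actions.
    """
    candidates = [v for v in view if v.status == "active" and _distance(v) > 0]
    candidates.sort(key=lambda v: (-_distance(v), v.npc_id))
    actions: list[PlayerAction] = []
    for v in candidates[:params.attention_budget]:
        if rng.random() > params.act_prob:
            continue  # unskilled players dither
        lo, hi = v.ideal_range
        g = v.recent[-1]
        slope = _slope_per_hour(v, dt_hours)
        misdose = rng.random() < params.effective_misdose_prob
        if g > hi:
            units = max(0.5, (g - hi) / 2.0 + max(slope, 0.0) * 0.5)
            if misdose:
                units *= BOLUS_MISDOSE_FACTOR
            actions.append(PlayerAction("bolus", v.npc_id, round(units, 1)))
            if (v.phenotype == "T2D" and not v.metformin_given
                    and rng.random() < METFORMIN_PROB):
                # skilled players check the clinical history for renal status
                if not (v.renal_impaired and rng.random() < params.skill):
                    actions.append(PlayerAction("metformin", v.npc_id, 1.0))
        else:
            grams = float(np.clip(10.0 * (lo - g) + 10.0, 10.0, 40.0))
            if misdose:
                grams *= SNACK_MISDOSE_FACTOR
            actions.append(PlayerAction("snack", v.npc_id, round(grams, 0)))
    return actions


def checkin_feedback(view: list[NPCView], params: PlayerPolicyParams
                     ) -> CheckinFeedback:
    """The scripted player's answer to "How are you faring?".

    Deterministic in the view: overwhelmed when more NPCs are out of range
    than the player can comfortably track (a threshold rising with skill),
    under-challenged when everything is in range, comfortable otherwise.
    """
    n_out = sum(1 for v in view if v.status == "active" and _distance(v) > 0)
    overwhelm_threshold = 2 + int(round(2 * params.skill))
    if n_out >= overwhelm_threshold:
        return CheckinFeedback(OVERWHELMED, requested_delta=-1)
    if n_out == 0:
        return CheckinFeedback(UNDER_CHALLENGED, requested_delta=+1)
    return CheckinFeedback(COMFORTABLE)
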
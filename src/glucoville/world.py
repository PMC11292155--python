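"""Game world: clock, NPC population, activity schedules, per-tick update loop.

A game lasts ``duration_ticks`` ticks of 1 in-game hour each, subdivided into
``substeps_per_tick`` dynamics sub-steps (default 12, i.e. 5 in-game minutes)
for numerical stability.  The default population is 10 NPCs — 7 with type 2
diabetes, 2 with type 1, and 1 with gestational diabetes — reflecting the
relative incidence of the phenotypes.  Within a tick the order of operations
is fixed: facilitator requests, then player actions, then dynamics sub-steps
with a safety check after each, so that facilitator relief can never be
pre-empted by a faint in the same tick.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .dynamics import (
    PhysiologyParams, GlucoseState, GlucoseTrace, Stimuli, PlayerAction,
    SafetyRules, SAFETY_OK, FAINT_HYPO, apply_action, evaluate_safety,
    step_glucose,
)
from .events import EventRecord

__all__ = [
    "Phenotype", "PHENOTYPES", "ActivitySlot", "ActivitySchedule",
    "GameConfig", "NPC", "WorldState",
    "init_world", "generate_npc", "advance_tick",
]


@dataclass(frozen=True)
class Phenotype:
    """A diabetes phenotype and its ideal (target) glucose range in mmol/L."""

    label: str
    ideal_range: tuple[float, float]


#: Ideal glucose is 5-9 mmol/L for T1D and T2D and 5-7 mmol/L for GD.
PHENOTYPES: dict[str, Phenotype] = {
    "T1D": Phenotype("T1D", (5.0, 9.0)),
    "T2D": Phenotype("T2D", (5.0, 9.0)),
    "GD": Phenotype("GD", (5.0, 7.0)),
}


@dataclass(frozen=True)
class ActivitySlot:
    """One tick of an NPC's day: what they do, how hard, and what they eat."""

    label: str  # work | meal | recreation | rest
    intensity: float  # physical intensity in [0, 1]
    carbs: float = 0.0  # grams, nonzero only for meal/snack slots


@dataclass
class ActivitySchedule:
    slots: list[ActivitySlot]

    def __post_init__(self) -> None:
        for s in self.slots:
            if s.label not in ("work", "meal", "recreation", "rest"):
                raise ValueError(f"unknown activity {s.label!r}")


class ConfigError(ValueError):
    pass


@dataclass
class GameConfig:
    """Game configuration; defaults are the standard study conditions."""

    duration_ticks: int = 12
    substeps_per_tick: int = 12
    phenotype_counts: dict[str, int] = field(
        default_factory=lambda: {"T2D": 7, "T1D": 2, "GD": 1})
    renal_impairment_prevalence: float = 0.4
    safety: SafetyRules = field(default_factory=SafetyRules)
    max_npcs: int = 20
    meal_ticks: tuple[int, ...] = (1, 5, 9)
    seed: int = 0

    def validate(self) -> None:
        if self.duration_ticks < 1:
            raise ConfigError("duration_ticks must be >= 1")
        if self.substeps_per_tick < 1:
            raise ConfigError("substeps_per_tick must be >= 1")
        for label, n in self.phenotype_counts.items():
            if label not in PHENOTYPES:
                raise ConfigError(f"unknown phenotype {label!r}")
            if n < 0:
                raise ConfigError("phenotype counts must be non-negative")
        if not 0.0 <= self.renal_impairment_prevalence <= 1.0:
            raise ConfigError("renal_impairment_prevalence must be in [0, 1]")

    @property
    def dt_hours(self) -> float:
        return 1.0 / self.substeps_per_tick

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["meal_ticks"] = list(self.meal_ticks)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GameConfig":
        d = dict(d)
        if "safety" in d and isinstance(d["safety"], dict):
            d["safety"] = SafetyRules(**d["safety"])
        if "meal_ticks" in d:
            d["meal_ticks"] = tuple(d["meal_ticks"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GameConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


@dataclass
class NPC:
    """One simulated community member with diabetes."""

    id: str
    phenotype: Phenotype
    physiology: PhysiologyParams
    schedule: ActivitySchedule
    state: GlucoseState
    trace: GlucoseTrace
    status: str = "active"  # active | frozen | evacuated
    clinical_history: str = ""
    action_history: list[PlayerAction] = field(default_factory=list)
    metformin_given: bool = False
    joined_tick: int = 0
    evacuated_at: Optional[tuple[int, int]] = None


# Phenotype-specific sampling ranges for physiology generation.
_PHYS_TABLE = {
    # label: (basal mean, basal sd, basal clip, IR range, secretion range)
    "T2D": (8.5, 0.9, (6.5, 11.0), (1.5, 3.0), (0.4, 0.8)),
    "T1D": (8.0, 1.0, (6.0, 11.0), (1.0, 1.0), (0.0, 0.0)),
    "GD": (6.8, 0.6, (5.5, 8.5), (1.2, 2.0), (0.6, 0.9)),
}


def generate_npc(phenotype: str | Phenotype, rng: np.random.Generator,
                 npc_id: str = "npc-000", config: Optional[GameConfig] = None,
                 joined_tick: int = 0) -> NPC:
    """Sample a fresh NPC of the given phenotype.

    Physiology is drawn from phenotype-specific distributions; T1D NPCs have
    zero endogenous secretion by construction.  The activity schedule places
    three meals at fixed tick offsets with randomized carb loads, fills the
    remaining ticks with work/recreation/rest, and may add one snack.  A
    clinical-history sentence is synthesized from the sampled parameters.
    """
    if isinstance(phenotype, str):
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        phenotype = PHENOTYPES[phenotype]
    cfg = config or GameConfig()
    mu, sd, clip, ir_rng, sec_rng = _PHYS_TABLE[phenotype.label]
    basal = float(np.clip(rng.normal(mu, sd), *clip))
    ir = float(rng.uniform(*ir_rng)) if ir_rng[0] < ir_rng[1] else ir_rng[0]
    sec = float(rng.uniform(*sec_rng)) if sec_rng[0] < sec_rng[1] else sec_rng[0]
    renal = bool(rng.random() < cfg.renal_impairment_prevalence)
    phys = PhysiologyParams(
        basal_glucose=basal,
        insulin_sensitivity=3.5,
        endogenous_secretion=sec,
        insulin_resistance=ir,
        renal_impaired=renal,
    )

    slots: list[ActivitySlot] = []
    snack_tick = int(rng.integers(0, cfg.duration_ticks)) \
        if rng.random() < 0.3 else -1
    for t in range(cfg.duration_ticks):
        if t in cfg.meal_ticks:
            carbs = float(np.clip(rng.normal(60.0, 15.0), 20.0, 110.0))
            slots.append(ActivitySlot("meal", 0.1, carbs))
        elif t == snack_tick:
            carbs = float(np.clip(rng.normal(20.0, 5.0), 5.0, 40.0))
            slots.append(ActivitySlot("rest", 0.05, carbs))
        else:
            u = rng.random()
            if u < 0.5:
                slots.append(ActivitySlot("work", 0.3))
            elif u < 0.8:
                slots.append(ActivitySlot("recreation", float(rng.uniform(0.4, 0.9))))
            else:
                slots.append(ActivitySlot("rest", 0.05))

    age = int(rng.integers(24, 78)) if phenotype.label != "GD" \
        else int(rng.integers(22, 42))
    years = int(rng.integers(0, max(1, age - 20)))
    history = (f"{age}-year-old with {phenotype.label} diagnosed "
               f"{years} y ago; renal function "
               f"{'impaired' if renal else 'normal'}; "
               f"typical fasting glucose {basal:.1f} mmol/L.")

    g0 = basal
    trace = GlucoseTrace(dt_hours=cfg.dt_hours, values=[g0],
                         start_hours=float(joined_tick))
    return NPC(id=npc_id, phenotype=phenotype, physiology=phys,
               schedule=ActivitySchedule(slots), state=GlucoseState(G=g0),
               trace=trace, clinical_history=history, joined_tick=joined_tick)


@dataclass
class WorldState:
    """Full mutable state of one running game."""

    config: GameConfig
    seed: int
    tick: int = 0
    npcs: dict[str, NPC] = field(default_factory=dict)
    removed: dict[str, NPC] = field(default_factory=dict)
    events: list[EventRecord] = field(default_factory=list)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    _seq: int = 0
    _npc_counter: int = 0
    _substep: int = 0

    def log(self, kind: str, npc_id: Optional[str] = None,
            payload: Optional[dict[str, Any]] = None) -> EventRecord:
        ev = EventRecord(seq=self._seq, tick=self.tick, substep=self._substep,
                         kind=kind, npc_id=npc_id, payload=payload or {})
        self._seq += 1
        self.events.append(ev)
        return ev

    def next_npc_id(self) -> str:
        self._npc_counter += 1
        return f"npc-{self._npc_counter:03d}"

    def counts(self) -> dict[str, int]:
        c = {"active": 0, "frozen": 0, "evacuated": 0}
        for npc in self.npcs.values():
            c[npc.status] += 1
        c["removed"] = len(self.removed)
        return c

    def active_npcs(self) -> list[NPC]:
        return [n for n in sorted(self.npcs.values(), key=lambda n: n.id)
                if n.status == "active"]

    def all_ever_active(self) -> list[NPC]:
        """Every NPC that ever took part, including removed and evacuated."""
        return sorted([*self.npcs.values(), *self.removed.values()],
                      key=lambda n: n.id)

    @property
    def game_over(self) -> bool:
        return self.tick >= self.config.duration_ticks

    def snapshot(self) -> str:
        """Deterministic JSON serialization for replay/identity tests."""
        def npc_dict(n: NPC) -> dict[str, Any]:
            return {
                "id": n.id, "phenotype": n.phenotype.label,
                "status": n.status, "joined_tick": n.joined_tick,
                "physiology": asdict(n.physiology),
                "state": asdict(n.state),
                "trace": n.trace.values,
                "actions": [asdict(a) for a in n.action_history],
                "history": n.clinical_history,
            }
        doc = {
            "tick": self.tick,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "npcs": [npc_dict(n) for n in sorted(self.npcs.values(),
                                                 key=lambda n: n.id)],
            "removed": [npc_dict(n) for n in sorted(self.removed.values(),
                                                    key=lambda n: n.id)],
            "events": [asdict(e) for e in self.events],
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def init_world(config: GameConfig, seed: int) -> WorldState:
    """Create a fresh, fully reproducible world from a config and seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    world = WorldState(config=config, seed=seed, rng=rng)
    for label in ("T2D", "T1D", "GD"):  # fixed creation order for determinism
        for _ in range(config.phenotype_counts.get(label, 0)):
            npc = generate_npc(label, rng, world.next_npc_id(), config)
            world.npcs[npc.id] = npc
    world.log("game_start", payload={"seed": seed, "config": config.to_dict(),
                                     "n_npcs": len(world.npcs)})
    return world


def _slot_for(npc: NPC, tick: int) -> ActivitySlot:
    idx = tick % len(npc.schedule.slots) if npc.schedule.slots else 0
    if not npc.schedule.slots:
        return ActivitySlot("rest", 0.0)
    return npc.schedule.slots[idx]


def _apply_player_actions(world: WorldState, actions: list[PlayerAction]) -> None:
    for act in actions:
        npc = world.npcs.get(act.npc_id)
        if npc is None:
            world.log("warning", act.npc_id,
                      {"reason": "action targets unknown or removed NPC",
                       "action": asdict(act)})
            continue
        if npc.status == "evacuated":
            world.log("warning", act.npc_id,
                      {"reason": "action targets evacuated NPC",
                       "action": asdict(act)})
            continue
        if npc.status == "frozen":
            world.log("warning", act.npc_id,
                      {"reason": "action targets frozen NPC",
                       "action": asdict(act)})
            continue
        npc.state, flag = apply_action(npc.state, npc.physiology, act)
        npc.action_history.append(act)
        if act.kind == "metformin" and act.dose > 0:
            npc.metformin_given = True
        world.log("action", act.npc_id, {
            "action_kind": act.kind, "dose": act.dose,
            "contraindicated": flag is not None,
        })


def advance_tick(world: WorldState, player_actions: list[PlayerAction],
                 facilitator_requests: list) -> tuple[WorldState, list[EventRecord]]:
    """Advance the game clock by one tick.

    Facilitator requests are applied first, then player actions, then the
    glucose dynamics are stepped for every active NPC across all sub-steps
    with the safety rule evaluated after each sub-step.  Frozen NPCs' traces
    are extended flat.  Returns the world and the events emitted this tick.
    """
    if world.game_over:
        raise ValueError("game is over; cannot advance")
    from .facilitation import apply_request  # local import avoids a cycle

    first_new = len(world.events)
    world._substep = 0
    world.log("tick", payload={"tick": world.tick})

    for req in facilitator_requests:
        apply_request(world, req)

    _apply_player_actions(world, player_actions)

    dt = world.config.dt_hours
    rules = world.config.safety
    for sub in range(world.config.substeps_per_tick):
        world._substep = sub
        for npc in sorted(world.npcs.values(), key=lambda n: n.id):
            if npc.status == "evacuated":
                continue
            if npc.status == "frozen":
                npc.trace.append(npc.trace.last)
                continue
            slot = _slot_for(npc, world.tick)
            carbs = slot.carbs if sub == 0 else 0.0
            if carbs > 0:
                world.log("meal", npc.id, {"carbs": carbs, "label": slot.label})
            stim = Stimuli(activity_intensity=slot.intensity, carbs_in=carbs)
            npc.state = step_glucose(npc.state, npc.physiology, stim, dt)
            npc.trace.append(npc.state.G)
            status = evaluate_safety(npc.trace, rules)
            if status != SAFETY_OK:
                npc.status = "evacuated"
                npc.evacuated_at = (world.tick, sub)
                world.log("faint", npc.id, {
                    "direction": "hypo" if status == FAINT_HYPO else "hyper",
                    "glucose": npc.state.G,
                    "time_hours": world.tick + (sub + 1) * dt,
                })

    world._substep = 0
    world.tick += 1
    if world.game_over:
        world.log("game_over", payload={"tick": world.tick})
    return world, world.events[first_new:]
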
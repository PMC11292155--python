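"""Game and experiment drivers: scripted play, facilitation, replay.

``run_game`` executes one full game with a scripted player (and, when
facilitated, the moderation protocol at the scheduled check-ins).
``run_experiment`` simulates a two-arm trial — facilitator-free control vs
facilitated intervention — and applies the analysis plan to the per-game
metrics.  ``replay_game`` re-executes the player/facilitator events of a
stored log against the same config and seed, which must reproduce the final
world state exactly (log sufficiency).

All randomness flows from a single base seed: game k of an experiment uses
``base XOR k``, and within a game the player and facilitator draw from
streams spawned off the game seed, so world-side randomness is independent
of policy randomness (a prerequisite for replay).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import agents, facilitation
from .analytics import GameMetrics, summarize_game, traces_frame
from .dynamics import PlayerAction
from .events import EventRecord, read_event_log, write_event_log
from .facilitation import (FacilitatorRequest, attribute_evacuation_cause,
                           checkin_ticks, moderation_policy)
from .trial_stats import TestResult, compare_groups
from .world import GameConfig, WorldState, advance_tick, init_world

__all__ = ["RunResult", "ExperimentConfig", "ExperimentResult",
           "run_game", "run_experiment", "replay_game", "derive_seed",
           "metrics_from_log", "simple_randomization"]

_SEED_MOD = 2**31


def derive_seed(base_seed: int, index: int) -> int:
    """Per-game seed: base XOR game index, kept below 2^31."""
    return (base_seed ^ index) % _SEED_MOD


@dataclass
class RunResult:
    metrics: GameMetrics
    world: WorldState
    log_path: Optional[Path] = None


def run_game(config: GameConfig, player: agents.PlayerPolicyParams,
             facilitated: bool, seed: int,
             out_dir: Optional[str | Path] = None,
             game_id: str = "game") -> RunResult:
    """Play one full game with a scripted player.

    In facilitated games the facilitator checks in on tick 3 and every 2
    ticks after, converts the player's feedback into one moderation request,
    and explains every evacuation.  Unfacilitated games emit no facilitator
    events at all.  Deterministic: same (config, player, facilitated, seed)
    gives a byte-identical event log.
    """
    world = init_world(config, seed)
    player_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    fac_rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    cticks = set(checkin_ticks(config.duration_ticks)) if facilitated else set()

    while not world.game_over:
        requests: list[FacilitatorRequest] = []
        view = agents.make_player_view(world, player.reaction_window)
        if world.tick in cticks:
            fb = agents.checkin_feedback(view, player)
            world.log("checkin", payload={"feedback": fb.level,
                                          "requested_delta": fb.requested_delta})
            requests.append(moderation_policy(fb, world, fac_rng))
        actions = agents.scripted_player(view, player, player_rng,
                                         dt_hours=config.dt_hours)
        world, new_events = advance_tick(world, actions, requests)
        if facilitated:
            for ev in [e for e in new_events if e.kind == "faint"]:
                expl = attribute_evacuation_cause(
                    world.events, ev.npc_id, ev,
                    substeps_per_tick=config.substeps_per_tick)
                world.log("evacuation_explained", ev.npc_id, {
                    "direction": expl.direction,
                    "attributed_cause": expl.attributed_cause,
                    "message": expl.message,
                })

    metrics = summarize_game(world)
    log_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_path = write_event_log(world.events, out_dir / f"{game_id}.events.jsonl")
        metrics.per_npc.to_csv(out_dir / f"{game_id}.per_npc.csv", index=False)
        traces_frame(world).to_csv(out_dir / f"{game_id}.agp.csv", index=False)
    return RunResult(metrics=metrics, world=world, log_path=log_path)


def replay_game(log: Sequence[EventRecord],
                config: Optional[GameConfig] = None,
                seed: Optional[int] = None) -> WorldState:
    """Re-execute the logged player actions and facilitator requests.

    Config and seed default to those stored in the log's game_start event.
    Because policy randomness is stream-separated from world randomness, the
    replayed final world state matches the original exactly.
    """
    start = next(e for e in log if e.kind == "game_start")
    if config is None:
        config = GameConfig.from_dict(start.payload["config"])
    if seed is None:
        seed = int(start.payload["seed"])

    actions_by_tick: dict[int, list[PlayerAction]] = {}
    requests_by_tick: dict[int, list[FacilitatorRequest]] = {}
    for ev in log:
        if ev.kind == "action":
            actions_by_tick.setdefault(ev.tick, []).append(PlayerAction(
                kind=ev.payload["action_kind"], npc_id=ev.npc_id,
                dose=ev.payload["dose"]))
        elif ev.kind == "facilitator_request":
            req = ev.payload["request"]
            if req == "add_npc":
                fr = FacilitatorRequest("add_npc", ev.payload["phenotype"])
            elif req == "no_action":
                fr = FacilitatorRequest("no_action")
            else:
                fr = FacilitatorRequest(req, ev.npc_id)
            requests_by_tick.setdefault(ev.tick, []).append(fr)

    world = init_world(config, seed)
    while not world.game_over:
        world, _ = advance_tick(world,
                                actions_by_tick.get(world.tick, []),
                                requests_by_tick.get(world.tick, []))
    return world


def metrics_from_log(path: str | Path) -> GameMetrics:
    """Recompute game metrics from a stored event log via replay."""
    world = replay_game(read_event_log(path))
    return summarize_game(world)


@dataclass
class ExperimentConfig:
    """Two-arm experiment: control (unfacilitated) vs intervention."""

    games_per_arm: int = 20
    skill_mean: float = 0.5
    skill_sd: float = 0.2
    # optional per-arm overrides of the skill mean (e.g. to compare player
    # ability rather than facilitation)
    control_skill_mean: Optional[float] = None
    intervention_skill_mean: Optional[float] = None
    control_facilitated: bool = False
    intervention_facilitated: bool = True
    base_seed: int = 0
    game: GameConfig = field(default_factory=GameConfig)
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.games_per_arm < 2:
            raise ValueError("games_per_arm must be >= 2")


@dataclass
class ExperimentResult:
    games: pd.DataFrame  # game_id, arm, seed, skill, three metrics
    comparisons: dict[str, TestResult]


METRIC_COLUMNS = ("mean_hours_ideal", "metformin_errors", "evacuations")


def simple_randomization(n: int, rng: np.random.Generator) -> list[str]:
    """Coin-flip arm assignment for n subjects (provided for completeness;
    the simulated experiment assigns arms deterministically by config)."""
    return ["intervention" if rng.random() < 0.5 else "control"
            for _ in range(n)]


def run_experiment(exp: ExperimentConfig) -> ExperimentResult:
    """Simulate both arms and compare the three gameplay metrics.

    Player skill is drawn per game from a normal distribution truncated to
    [0, 1], identically in both arms, so any between-arm difference is
    attributable to facilitation.
    """
    exp.validate()
    skill_rng = np.random.default_rng(np.random.SeedSequence((exp.base_seed, 99)))
    rows = []
    idx = 0
    arm_skill = {"control": exp.control_skill_mean,
                 "intervention": exp.intervention_skill_mean}
    for arm, facilitated in (("control", exp.control_facilitated),
                             ("intervention", exp.intervention_facilitated)):
        mu = arm_skill[arm] if arm_skill[arm] is not None else exp.skill_mean
        for g in range(exp.games_per_arm):
            seed = derive_seed(exp.base_seed, idx)
            skill = float(np.clip(skill_rng.normal(mu, exp.skill_sd),
                                  0.0, 1.0))
            player = agents.PlayerPolicyParams(skill=skill)
            game_id = f"{arm}-{g:03d}"
            res = run_game(exp.game, player, facilitated, seed,
                           out_dir=exp.out_dir, game_id=game_id)
            rows.append(res.metrics.to_row(game_id=game_id, arm=arm,
                                           seed=seed, skill=skill))
            idx += 1
    games = pd.DataFrame(rows)
    comparisons = {}
    for col in METRIC_COLUMNS:
        x = games.loc[games.arm == "control", col].to_numpy(float)
        y = games.loc[games.arm == "intervention", col].to_numpy(float)
        comparisons[col] = compare_groups(x, y)
    if exp.out_dir is not None:
        out = Path(exp.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cols = ["game_id", "arm", "seed", "skill", *METRIC_COLUMNS]
        games[cols].to_csv(out / "metrics.csv", index=False)
    return ExperimentResult(games=games, comparisons=comparisons)
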
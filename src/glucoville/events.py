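"""Append-only game event records and their JSONL serialization.

Every state change in a game — clock ticks, NPC meals, player actions,
facilitator requests, check-ins, faints, evacuation explanations, warnings —
is one :class:`EventRecord`.  Logs are written as JSON Lines so that runs are
diffable and replayable line by line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Optional

__all__ = ["EventRecord", "EventLogError", "KINDS",
           "write_event_log", "read_event_log"]

KINDS = frozenset({
    "game_start", "tick", "meal", "action", "facilitator_request",
    "checkin", "faint", "evacuation_explained", "game_over", "warning",
})


@dataclass(frozen=True)
class EventRecord:
    """One time-stamped game event.

    ``seq`` is a strictly increasing per-game sequence number; ``tick`` and
    ``substep`` locate the event on the game clock (1 tick = 1 in-game hour).
    """

    seq: int
    tick: int
    substep: int
    kind: str
    npc_id: Optional[str] = None
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "EventRecord":
        required = {"seq", "tick", "substep", "kind"}
        missing = required - d.keys()
        if missing:
            raise ValueError(f"missing fields {sorted(missing)}")
        unknown = d.keys() - {"seq", "tick", "substep", "kind", "npc_id", "payload"}
        if unknown:
            raise ValueError(f"unknown fields {sorted(unknown)}")
        return cls(seq=int(d["seq"]), tick=int(d["tick"]),
                   substep=int(d["substep"]), kind=str(d["kind"]),
                   npc_id=d.get("npc_id"), payload=d.get("payload", {}))


class EventLogError(ValueError):
    """Raised for malformed event-log files; message names the line."""


def write_event_log(events: Iterable[EventRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")
    return path


def read_event_log(path: str | Path) -> list[EventRecord]:
    """Read a JSONL event log, validating each record.

    Raises :class:`EventLogError` naming the 1-based line number of the first
    malformed line.  An empty file yields an empty list.
    """
    path = Path(path)
    events: list[EventRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
                ev = EventRecord.from_dict(d)
            except (json.JSONDecodeError, ValueError, TypeError) as exc:
                raise EventLogError(f"line {lineno}: {exc}") from exc
            if events and ev.seq <= events[-1].seq:
                raise EventLogError(f"line {lineno}: seq not strictly increasing")
            events.append(ev)
    return events
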
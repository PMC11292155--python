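"""Per-NPC blood-glucose dynamics, player actions, and the fainting rule.

The model is a discrete-time minimal-model-style system in mmol/L with three
compartments per NPC:

* ``G``      plasma glucose (mmol/L),
* ``Q_gut``  carbohydrate remaining in the gut (grams), first-order absorption,
* ``X``      remote insulin action (dimensionless), first-order decay,

plus an oral-agent (metformin) effect level ``M_eff`` with a fixed duration.

Update over a sub-step of ``dt`` in-game hours::

    dG/dt = EGP*(1 - m*M_eff) - (EGP/Gb)*G
            - (S_I/IR) * (X + sigma*s(G)) * G
            - a*activity + k_abs*Q_gut*c_g

    Q_gut <- Q_gut*exp(-k_abs*dt) + carbs_in
    X     <- X*exp(-k_x*dt) + (bolus + basal_rate*dt)*u_x

where ``s(G)`` is a saturating endogenous-secretion term active only above
basal, and the ``EGP/Gb`` term is insulin-independent clearance (glucose
effectiveness) chosen so that basal glucose is an exact equilibrium under
zero stimuli.  T1D NPCs have ``sigma = 0`` (no endogenous secretion); T2D and
GD share the functional form and differ in parameter draws and target range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "PhysiologyParams",
    "GlucoseState",
    "GlucoseTrace",
    "Stimuli",
    "PlayerAction",
    "ContraindicationFlag",
    "SafetyRules",
    "SafetyStatus",
    "step_glucose",
    "apply_action",
    "evaluate_safety",
]


@dataclass(frozen=True)
class PhysiologyParams:
    """Per-NPC physiological parameters.

    Rates are first-order constants per in-game hour.  ``insulin_sensitivity``
    scales how strongly remote insulin action clears glucose;
    ``insulin_resistance`` (>= 1) divides it.  ``endogenous_secretion`` in
    [0, 1] scales the above-basal secretion response and is exactly 0 for T1D.
    """

    basal_glucose: float
    insulin_sensitivity: float
    endogenous_secretion: float
    insulin_resistance: float
    renal_impaired: bool
    carb_absorption_rate: float = 1.5
    insulin_action_decay: float = 0.8
    activity_uptake_rate: float = 1.2
    egp: float = 1.6  # endogenous glucose production, mmol/L per hour
    carb_potency: float = 0.18  # mmol/L glucose appearance per gram absorbed
    insulin_gain: float = 0.05  # units of X added per insulin unit
    metformin_egp_reduction: float = 0.35
    metformin_duration_hours: float = 8.0
    secretion_max: float = 0.2
    secretion_half: float = 2.0  # mmol/L above basal at half-max secretion

    def __post_init__(self) -> None:
        if self.basal_glucose <= 0:
            raise ValueError("basal_glucose must be positive")
        if not 0.0 <= self.endogenous_secretion <= 1.0:
            raise ValueError("endogenous_secretion must be in [0, 1]")
        if self.insulin_resistance < 1.0:
            raise ValueError("insulin_resistance must be >= 1")
        for name in ("carb_absorption_rate", "insulin_action_decay",
                     "activity_uptake_rate", "insulin_sensitivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GlucoseState:
    """Dynamic state of one NPC's glucose system."""

    G: float
    Q_gut: float = 0.0
    X: float = 0.0
    M_eff: float = 0.0
    M_timer_hours: float = 0.0
    M_pending: float = 0.0  # dose armed, takes effect one sub-step later

    def validate(self) -> None:
        if not (self.G > 0 and self.Q_gut >= 0 and self.X >= 0
                and 0.0 <= self.M_eff <= 1.0):
            raise ValueError(f"invalid glucose state: {self}")


@dataclass
class GlucoseTrace:
    """Uniformly sampled ambulatory glucose profile for one NPC.

    ``values[k]`` is the glucose at ``start_hours + k * dt_hours``.
    """

    dt_hours: float
    values: list[float] = field(default_factory=list)
    start_hours: float = 0.0

    def append(self, g: float) -> None:
        self.values.append(g)

    @property
    def last(self) -> float:
        return self.values[-1]

    @property
    def span_hours(self) -> float:
        return max(0, len(self.values) - 1) * self.dt_hours

    def times(self) -> list[float]:
        return [self.start_hours + k * self.dt_hours
                for k in range(len(self.values))]


@dataclass(frozen=True)
class Stimuli:
    """Environmental inputs to one sub-step of the dynamics."""

    activity_intensity: float = 0.0
    carbs_in: float = 0.0
    bolus_units: float = 0.0
    basal_units_per_hour: float = 0.0


@dataclass(frozen=True)
class PlayerAction:
    """A single player intervention on one NPC.

    ``kind`` is one of ``bolus`` (insulin units), ``snack`` (carb grams) or
    ``metformin`` (standard oral doses; any positive dose arms one standard
    effect).
    """

    kind: str
    npc_id: str
    dose: float

    def __post_init__(self) -> None:
        if self.kind not in ("bolus", "snack", "metformin"):
            raise ValueError(f"unknown action kind {self.kind!r}")
        if not math.isfinite(self.dose) or self.dose < 0:
            raise ValueError("action dose must be finite and >= 0")


@dataclass(frozen=True)
class ContraindicationFlag:
    npc_id: str
    reason: str = "metformin with impaired renal function"


@dataclass(frozen=True)
class SafetyRules:
    """Fainting thresholds in mmol/L.

    Defaults follow clinical convention: level-2 hypoglycaemia below 3.0,
    severe hyperglycaemia above 20.0, and the standard 3.9-13.9 band for
    sustained excursions, with fainting after ``extended_hours`` continuously
    outside the band.
    """

    severe_low: float = 3.0
    severe_high: float = 20.0
    extended_low: float = 3.9
    extended_high: float = 13.9
    extended_hours: float = 3.0

    def __post_init__(self) -> None:
        if not (self.severe_low < self.extended_low
                < self.extended_high < self.severe_high):
            raise ValueError("safety thresholds must satisfy "
                             "severe_low < extended_low < extended_high < severe_high")


#: SafetyStatus values
SAFETY_OK = "ok"
FAINT_HYPO = "faint_hypo"
FAINT_HYPER = "faint_hyper"

SafetyStatus = str

_G_FLOOR = 0.2  # numerical floor; severe-hypo fainting triggers long before


def _secretion(g: float, phys: PhysiologyParams) -> float:
    """Saturating endogenous-secretion drive, active only above basal."""
    dg = g - phys.basal_glucose
    if dg <= 0:
        return 0.0
    return phys.secretion_max * dg / (dg + phys.secretion_half)


def step_glucose(state: GlucoseState, phys: PhysiologyParams,
                 stimuli: Stimuli, dt: float) -> GlucoseState:
    """Advance one NPC's glucose system by ``dt`` in-game hours.

    Explicit-Euler update of G using start-of-interval compartment values,
    then exact exponential decay of the gut and insulin compartments with
    end-of-interval input deposition (a meal or bolus at sub-step k first
    influences G during sub-step k+1, matching the one-sub-step metformin
    onset).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for v in (state.G, state.Q_gut, state.X, stimuli.activity_intensity,
              stimuli.carbs_in, stimuli.bolus_units, stimuli.basal_units_per_hour):
        if not math.isfinite(v):
            raise ValueError("non-finite input to step_glucose")
    state.validate()

    g, q, x = state.G, state.Q_gut, state.X
    m_eff, m_timer, m_pending = state.M_eff, state.M_timer_hours, state.M_pending

    clearance_basal = phys.egp / phys.basal_glucose
    insulin_drive = (phys.insulin_sensitivity / phys.insulin_resistance) * (
        x + phys.endogenous_secretion * _secretion(g, phys))
    dg = (phys.egp * (1.0 - phys.metformin_egp_reduction * m_eff)
          - clearance_basal * g
          - insulin_drive * g
          - phys.activity_uptake_rate * stimuli.activity_intensity
          + phys.carb_absorption_rate * q * phys.carb_potency)
    g_new = max(g + dg * dt, _G_FLOOR)

    q_new = q * math.exp(-phys.carb_absorption_rate * dt) + stimuli.carbs_in
    x_new = (x * math.exp(-phys.insulin_action_decay * dt)
             + (stimuli.bolus_units + stimuli.basal_units_per_hour * dt)
             * phys.insulin_gain)

    # metformin bookkeeping: armed dose becomes active after this sub-step
    if m_timer > 0:
        m_timer = max(0.0, m_timer - dt)
        if m_timer == 0.0:
            m_eff = 0.0
    if m_pending > 0:
        m_eff = min(1.0, m_pending)
        m_timer = phys.metformin_duration_hours
        m_pending = 0.0

    out = GlucoseState(G=g_new, Q_gut=q_new, X=x_new, M_eff=m_eff,
                       M_timer_hours=m_timer, M_pending=m_pending)
    out.validate()
    return out


def apply_action(state: GlucoseState, phys: PhysiologyParams,
                 action: PlayerAction) -> tuple[GlucoseState, Optional[ContraindicationFlag]]:
    """Apply a player action to an NPC's glucose state.

    Metformin to a renally impaired NPC returns a contraindication flag but
    still takes effect: the game records player errors, it does not block
    them.  Zero-dose actions are no-ops.
    """
    if action.dose < 0:
        raise ValueError("negative dose")
    if action.dose == 0:
        return state, None
    flag: Optional[ContraindicationFlag] = None
    if action.kind == "bolus":
        state = replace(state, X=state.X + action.dose * phys.insulin_gain)
    elif action.kind == "snack":
        state = replace(state, Q_gut=state.Q_gut + action.dose)
    elif action.kind == "metformin":
        state = replace(state, M_pending=1.0)
        if phys.renal_impaired:
            flag = ContraindicationFlag(npc_id=action.npc_id)
    state.validate()
    return state, flag


def evaluate_safety(trace: GlucoseTrace, rules: SafetyRules) -> SafetyStatus:
    """Decide whether the NPC behind ``trace`` faints, causally.

    Severe excursions faint instantly; sustained excursions faint once the
    trace has been continuously outside the extended band for at least
    ``extended_hours`` (measured as elapsed time between the first and last
    consecutive out-of-band samples at the end of the trace).
    """
    if not trace.values:
        raise ValueError("empty trace")
    g = trace.last
    if g < rules.severe_low:
        return FAINT_HYPO
    if g > rules.severe_high:
        return FAINT_HYPER
    for faint, outside in ((FAINT_HYPO, lambda v: v < rules.extended_low),
                           (FAINT_HYPER, lambda v: v > rules.extended_high)):
        if outside(g):
            k = 0
            for v in reversed(trace.values):
                if outside(v):
                    k += 1
                else:
                    break
            if (k - 1) * trace.dt_hours >= rules.extended_hours:
                return faint
    return SAFETY_OK
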
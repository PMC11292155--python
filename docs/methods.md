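# Methods

This note documents the models and procedures implemented in `glucoville`,
the parameter choices behind them, and what the simulated experiments can
and cannot show.

## Time base

A game lasts `duration_ticks = 12` ticks of one in-game hour. Each tick is
subdivided into `substeps_per_tick = 12` dynamics sub-steps (5 in-game
minutes) so that the explicit-Euler glucose update is numerically stable and
the fainting rule can resolve sub-hour excursions. The tick-level mapping
(1 tick = 1 hour, 12 ticks per game) is the game's defining clock; the
sub-step count is a numerical choice, validated by a discretization test:
halving the sub-step changes end-of-game glucose by less than 0.1 mmol/L on
a fixed stimulus script.

Within a tick, operations are ordered facilitator → player → dynamics →
safety. The ordering is deliberate: relief granted at a check-in (a freeze
or removal) can never be pre-empted by a faint occurring in the same tick.

## Glucose model

No glucose equations are prescribed by the game's published description;
the model here is the package's own, chosen to be the simplest system with
the qualitatively required behaviour (meals raise glucose, boluses lower
it, activity consumes it, phenotypes differ in secretion and resistance,
equilibrium at basal). It is a discrete minimal-model-style system per NPC:

```
dG/dt = EGP·(1 − m·M_eff) − (EGP/G_b)·G − (S_I/IR)·(X + σ·s(G))·G
        − a·activity + k_abs·Q_gut·c_g
```

with exact exponential decay for the gut and insulin compartments and
end-of-step deposition of meals and boluses (so an input at sub-step *k*
first influences glucose during sub-step *k*+1, and metformin's onset is
one sub-step after dosing by the same mechanism).

The insulin-independent clearance coefficient is tied to endogenous
production as `EGP/G_b` (glucose effectiveness), which makes basal glucose
an *exact* equilibrium under zero stimuli — important both as a sanity
anchor and because NPCs spawn at basal. The secretion term
`s(G) = s_max·ΔG/(ΔG + K_s)` (ΔG = G − G_b, active only above basal)
saturates so that endogenous correction cannot grow without bound; T1D sets
σ = 0, abolishing it entirely.

Default parameters (all per in-game hour where dimensional):

| parameter | value | meaning |
|---|---|---|
| `EGP` | 1.6 mmol/L/h | endogenous glucose production |
| `k_abs` | 1.5 /h | carbohydrate absorption rate |
| `k_x` | 0.8 /h | remote insulin action decay |
| `c_g` | 0.18 mmol/L per g | glucose appearance per gram absorbed |
| `u_x` | 0.05 per unit | insulin action per bolus unit |
| `S_I` | 3.5 | insulin sensitivity scale |
| `a` | 1.2 mmol/L/h | uptake per unit activity intensity |
| `m` | 0.35 | fractional EGP suppression by metformin |
| metformin duration | 8 h | effect window after one-sub-step onset |
| `s_max`, `K_s` | 0.2, 2 mmol/L | secretion saturation |

`c_g` and `u_x`·`S_I` are set so that 10 g of carbohydrate raises glucose
by roughly 2 mmol/L and one insulin unit lowers it by roughly 2 mmol/L at
G ≈ 9 — the usual clinical rules of thumb. Phenotypes differ in sampled
basal glucose (T2D ~ N(8.5, 0.9), T1D ~ N(8.0, 1.0), GD ~ N(6.8, 0.6),
clipped), insulin resistance (IR uniform on [1.5, 3] for T2D, 1 for T1D,
[1.2, 2] for GD) and secretion fraction σ (0 for T1D, [0.4, 0.8] for T2D,
[0.6, 0.9] for GD). Renal impairment is a Bernoulli flag with default
prevalence 0.4, surfaced in the NPC's clinical history; metformin given to
an impaired NPC is *recorded* as a contraindication error, never blocked.

## Safety (fainting) rule

The game specifies only that "extended or severe" excursions cause
fainting. Defaults follow clinical convention: severe bounds 3.0 and
20.0 mmol/L (instant faint), extended band 3.9–13.9 mmol/L (the standard
time-in-range band), fainting after 3 consecutive hours outside it. The
rule is causal — evaluated on the trace prefix after every sub-step — and
"3 consecutive hours" is measured as elapsed time between the first and
last of the trailing out-of-band samples, so exactly 3 h faints and 3 h
minus one sub-step does not. A brute-force window-scan oracle cross-checks
this in the tests.

## Schedules

Each NPC's day has three meals at fixed ticks {1, 5, 9} with carb loads ~
N(60, 15) g clipped to [20, 110], an optional snack (probability 0.3), and
work/recreation/rest filling the remaining ticks with intensities 0.3 /
U(0.4, 0.9) / 0.05. Schedules are seed-generated per NPC; no canonical
schedules exist to reproduce, so they are treated as part of the stochastic
world.

## Scripted players

Human players are replaced by a heuristic threshold policy with a single
`skill` knob in [0, 1]. Out-of-range active NPCs are ranked by distance
from their ideal range; at most `attention_budget = 3` are treated per
tick. Above range: a corrective bolus of `(G − hi)/2` units (plus a trend
term), with a 0.6 chance of also starting metformin on an untreated T2D
NPC. Below range: a rescue snack of `10·(lo − G) + 10` grams. Skill acts
through (i) the probability of acting at all (0.4 at skill 0 rising to 1),
(ii) the mis-dose probability `0.3·(1 − skill)` (a mis-dosed bolus is
tripled — the classic over-correction — and a mis-dosed snack quartered),
and (iii) the probability of checking the clinical history for renal
contraindication before metformin (equal to skill). The policy is plumbing
for the experiment, not a model of students; its only validated property is
that mean evacuations are non-increasing in skill (checked over 200 seeds
per skill level with a one-sided tolerance of 0.15 for sampling noise).

At check-ins the scripted player reports *overwhelmed* when the number of
out-of-range NPCs reaches `2 + round(2·skill)`, *under-challenged* when
none are out of range, and *comfortable* otherwise.

## Facilitation

Check-ins occur at tick 3 and every 2 ticks after, never in the first
three ticks and never at or after game end: `checkin_ticks(12) =
{3, 5, 7, 9, 11}`. The moderation rule table maps feedback to one request
per check-in: overwhelmed → freeze the active NPC furthest from its ideal
range (freezing is preferred over removal as it is reversible);
comfortable → nothing; under-challenged → unfreeze the longest-frozen NPC,
else add a new NPC with phenotype drawn 7:2:1. Which NPC to freeze is this
package's rule; a human facilitator exercises judgment.

Evacuation explanations are reconstructed from the event log alone: a
hypoglycaemic faint is attributed to the largest bolus in the preceding
3 h (ties to the most recent); a hyperglycaemic faint to the largest meal
in the window not covered by a subsequent bolus; otherwise "unmanaged".
The 3 h lookback covers the canonical "too much bolus insulin 2 hours ago"
case with margin. Verbal facilitator behaviours beyond these explanations
(answering control questions, withholding knowledge unless asked) have no
game-state consequences and are not modelled.

## Analytics conventions

- *Ideal range* intervals are closed (boundary values count as in range).
- Hours in range are counted per sub-step interval by its left-endpoint
  sample.
- The mean-hours denominator is every NPC ever active; evacuated and
  removed NPCs contribute the hours accrued before exit, frozen intervals
  count iff the frozen value lies in range.
- Metformin errors count distinct NPCs (not doses), matching "number of
  NPCs administered metformin when contraindicated".
- Evacuations equal faint events; facilitator removals are not
  evacuations.

## Trial statistics

FSS scoring uses the instrument's standard item split — fluency
{2,4,5,7,8,9}, absorption {1,3,6,10}, importance {11,12,13} — which is
configurable; the 6/4 split within items 1–10 is corroborated by the
identity `flow = (6·fluency + 4·absorption)/10` holding for the published
group means (4.40 and 4.95 to printed precision). Sample SDs (n−1) are
assumed throughout. The comparison sign convention is control −
intervention. t tests, Mann-Whitney, Shapiro-Wilk and Levene screens are
scipy-backed; the test suite cross-checks them against hand-rolled and
exhaustive-enumeration oracles. Mann-Whitney uses exact enumeration for
tie-free samples of combined n ≤ 12 and the tie-corrected normal
approximation otherwise. The normality screen (Shapiro-Wilk at α = 0.05
per arm, gating the Mann-Whitney fallback; Levene gating Welch) is this
package's concretization of "if normally distributed" — no specific test
was named in the analysis plan it follows.

The sample-size operation reports both the closed-form normal
approximation — which gives **20 per group** at α = 5%, power 90%, means
4 vs 5.05, SD 1 — and the exact noncentral-*t* value (21). The published
plan expected 22 per group from the same inputs; the provenance of the
extra allowance (e.g. dropout inflation) is not stated, so 22 is not
treated as reproducible and the formula values are reported instead.

Reproducing the published comparison table from its *printed* (rounded)
group summaries recovers every statistic to within one unit in the last
printed digit. One row is worth noting: the overall-flow summaries
(4.4 ± 0.89 vs 4.95 ± 0.85) give t = −2.177, which rounds to −2.18 where
−2.17 was printed — the published value was evidently computed from
unrounded means. The hours-in-ideal-range row is compared by magnitude
(|t| = 0.86), as its published sign differs between table and text.

## What the simulation does and does not show

The synthetic experiment reproduces the *mechanics* of the trial: two
arms, identical player-skill distributions, facilitation as the only
difference, the three gameplay metrics compared under the analysis plan.
Simulated games land in the published outcome ranges (mean hours ideal
≈ 2.3–3.3; evacuations ≈ 0–1.5 per game depending on skill) and
facilitation directionally reduces evacuations. Scripted players commit
fewer metformin errors (≈ 1–2 NPCs/game) than the human average (≈ 2.7),
and the simulated facilitation effect on evacuations is weaker than the
human one — scripted players neither fatigue nor panic, which is much of
what a facilitator absorbs.

The trial's primary human outcome — higher flow in the facilitated arm —
is *not* reproducible here: flow is a self-reported psychological state
with no simulated counterpart. The FSS fixture generator (latent flow per
subject, item noise, discretization to 1–7) exercises the scoring and
analysis code paths only; it makes no psychometric claims. Passing tests
therefore validate the simulator's internal properties and the statistics
layer's correctness, not the educational effect of facilitation on people.

## Numerical and degenerate-input choices

- Glucose is floored at 0.2 mmol/L for numerical safety; severe-hypo
  fainting triggers at 3.0 long before the floor matters.
- Zero-dose actions are no-ops; negative doses are errors.
- Empty games (zero NPCs) are constructible but have no defined mean-hours
  metric; summarizing one raises an error.
- Moderation tie-breaks (equal distance from range) go to the
  lexicographically larger NPC id via the max over (distance, id); cause
  attribution ties go to the most recent event.
- All randomness flows from a single seed: world generation from the game
  seed, player and facilitator policies from streams spawned off it, and
  experiment game *k* from `base_seed XOR k` (kept below 2³¹). Replay of a
  logged game therefore reproduces the final world state exactly, which is
  how metrics are recomputed from logs.
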
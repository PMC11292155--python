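"""Independent oracles used by the test suite.

These deliberately re-derive expected behaviour by different means than the
implementation: an RK4 continuous-time integrator for the glucose ODE, a
window-scan fainting check, and exhaustive enumeration of the Mann-Whitney
null distribution.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def rk4_glucose(phys, hours: float, dt: float, carbs0: float = 0.0,
                bolus0: float = 0.0, activity: float = 0.0):
    """RK4 integration of the continuous glucose ODE from equilibrium.

    A meal/bolus impulse at t=0 deposits into the gut/insulin compartment.
    Returns (times, G values) sampled every ``dt`` hours.
    """
    def s(g):
        dg = g - phys.basal_glucose
        if dg <= 0:
            return 0.0
        return phys.secretion_max * dg / (dg + phys.secretion_half)

    def deriv(y):
        g, q, x = y
        dg = (phys.egp
              - (phys.egp / phys.basal_glucose) * g
              - (phys.insulin_sensitivity / phys.insulin_resistance)
              * (x + phys.endogenous_secretion * s(g)) * g
              - phys.activity_uptake_rate * activity
              + phys.carb_absorption_rate * q * phys.carb_potency)
        return np.array([dg, -phys.carb_absorption_rate * q,
                         -phys.insulin_action_decay * x])

    y = np.array([phys.basal_glucose, carbs0, bolus0 * phys.insulin_gain])
    n = int(round(hours / dt))
    ts, gs = [0.0], [y[0]]
    for k in range(n):
        k1 = deriv(y)
        k2 = deriv(y + dt / 2 * k1)
        k3 = deriv(y + dt / 2 * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ts.append((k + 1) * dt)
        gs.append(y[0])
    return np.array(ts), np.array(gs)


def brute_force_faint(values, dt_hours, rules):
    """Window-scan fainting check, formulated independently.

    Faint if the latest sample breaches a severe bound, or if there exists a
    start index i such that every sample from i to the end is outside an
    extended bound and the elapsed span (end - i) * dt is at least
    ``extended_hours``.
    """
    g = values[-1]
    if g < rules.severe_low:
        return "faint_hypo"
    if g > rules.severe_high:
        return "faint_hyper"
    end = len(values) - 1
    for status, outside in (("faint_hypo", lambda v: v < rules.extended_low),
                            ("faint_hyper", lambda v: v > rules.extended_high)):
        for i in range(end + 1):
            if (end - i) * dt_hours >= rules.extended_hours and \
                    all(outside(v) for v in values[i:]):
                return status
    return "ok"


def mann_whitney_exact_p(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of labelings.

    Enumerates all C(n+m, n) assignments of the pooled (tie-free) values to
    the two groups and counts assignments whose U is at least as extreme
    (in |U - nm/2|) as the observed one.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)

    u_obs = u_stat(x, y)
    center = n * m / 2.0
    extreme = 0
    total = 0
    for idx in combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in set(idx)]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return extreme / total


def pooled_t(xa, ya):
    """Hand-rolled pooled two-sample t, independent of scipy."""
    xa, ya = np.asarray(xa, float), np.asarray(ya, float)
    na, nb = len(xa), len(ya)
    sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * ya.var(ddof=1)) / (na + nb - 2)
    return (xa.mean() - ya.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
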
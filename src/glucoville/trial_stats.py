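"""Flow Short Scale scoring and the trial's quantitative analysis plan.

The Flow Short Scale (FSS) has 13 items on a 1-7 Likert scale; overall flow
is the mean of the first 10 items, which partition into fluency of
performance (6 items) and absorption by activity (4 items); items 11-13
measure perceived importance.  Group comparisons use two-sided independent-
samples t tests (pooled variance, with a Welch fallback when variances are
unequal), Mann-Whitney U for non-normal data, and Cohen's d on the pooled
standard deviation for effect sizes.  All of these are computable either
from raw per-subject scores or from printed (n, mean, SD) group summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FSSResponse", "FSSScores", "GroupSummary", "TestResult",
    "DEFAULT_FSS_MAPPING", "score_fss",
    "t_from_summary", "t_from_raw", "cohens_d_from_summary", "cohens_d_from_raw",
    "mann_whitney", "sample_size_two_means", "SampleSizeResult",
    "compare_groups", "reproduce_table2", "TABLE2_SUMMARIES",
    "synthesize_fss_responses", "type_i_error_rate",
]

# --------------------------------------------------------------------------
# Flow Short Scale scoring

#: Standard item split: items 1-10 carry flow (6 fluency + 4 absorption),
#: items 11-13 perceived importance.  Configurable because published
#: translations occasionally reorder items.
DEFAULT_FSS_MAPPING: dict[str, frozenset[int]] = {
    "fluency": frozenset({2, 4, 5, 7, 8, 9}),
    "absorption": frozenset({1, 3, 6, 10}),
    "importance": frozenset({11, 12, 13}),
}

FSSResponse = Sequence[int]


@dataclass(frozen=True)
class FSSScores:
    fluency: float
    absorption: float
    importance: float
    flow: float


def _validate_mapping(mapping: dict[str, frozenset[int]]) -> None:
    flu, absn, imp = (mapping["fluency"], mapping["absorption"],
                      mapping["importance"])
    if len(flu) != 6 or len(absn) != 4 or len(imp) != 3:
        raise ValueError("mapping must split items 6 + 4 + 3")
    if flu | absn != frozenset(range(1, 11)) or flu & absn:
        raise ValueError("fluency and absorption must partition items 1-10")
    if imp != frozenset(range(1, 14)) - (flu | absn):
        raise ValueError("importance must cover the remaining 3 items")


def score_fss(response: FSSResponse,
              mapping: Optional[dict[str, frozenset[int]]] = None) -> FSSScores:
    """Score one 13-item FSS response into subscale means.

    Flow is the mean of items 1-10 and therefore always equals
    ``(6*fluency + 4*absorption) / 10``.
    """
    mapping = mapping or DEFAULT_FSS_MAPPING
    _validate_mapping(mapping)
    items = list(response)
    if len(items) != 13:
        raise ValueError(f"FSS response must have 13 items, got {len(items)}")
    for v in items:
        if not (isinstance(v, (int, np.integer)) and 1 <= v <= 7):
            raise ValueError(f"FSS items must be integers in 1..7, got {v!r}")

    def mean_of(idx: frozenset[int]) -> float:
        return sum(items[i - 1] for i in idx) / len(idx)

    flu = mean_of(mapping["fluency"])
    absn = mean_of(mapping["absorption"])
    imp = mean_of(mapping["importance"])
    flow = sum(items[:10]) / 10.0
    return FSSScores(fluency=flu, absorption=absn, importance=imp, flow=flow)


# --------------------------------------------------------------------------
# Two-sample tests

@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float  # sample SD (n-1 denominator)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_raw(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_two_sided: float
    effect_size: Optional[float] = None
    method: str = "t"


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    return math.sqrt(((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2)
                     / (a.n + b.n - 2))


def t_from_summary(a: GroupSummary, b: GroupSummary,
                   pooled: bool = True) -> TestResult:
    """Independent-samples t test from (n, mean, SD) summaries.

    Statistic sign follows ``a - b``.  ``pooled=False`` applies the Welch
    correction (Satterthwaite df).
    """
    res = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                     equal_var=pooled)
    df = a.n + b.n - 2 if pooled else float(res.df)
    return TestResult(statistic=float(res.statistic), df=float(df),
                      p_two_sided=float(res.pvalue),
                      method="t_pooled" if pooled else "t_welch")


def t_from_raw(x: Sequence[float], y: Sequence[float],
               pooled: bool = True) -> TestResult:
    """Independent-samples t test from raw values; sign follows ``x - y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 values")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    df = len(x) + len(y) - 2 if pooled else float(res.df)
    return TestResult(statistic=float(res.statistic), df=float(df),
                      p_two_sided=float(res.pvalue),
                      method="t_pooled" if pooled else "t_welch")


def cohens_d_from_summary(a: GroupSummary, b: GroupSummary) -> float:
    """Cohen's d = |mean difference| / pooled SD."""
    sp = _pooled_sd(a, b)
    if sp == 0:
        raise ValueError("zero pooled SD; d undefined")
    return abs(a.mean - b.mean) / sp


def cohens_d_from_raw(x: Sequence[float], y: Sequence[float]) -> float:
    return cohens_d_from_summary(GroupSummary.from_raw(x),
                                 GroupSummary.from_raw(y))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U (U for x) with a two-sided p value.

    Uses exact enumeration for small tie-free samples (combined n <= 12) and
    the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), df=float("nan"),
                      p_two_sided=float(res.pvalue),
                      method=f"mann_whitney_{method}")


# --------------------------------------------------------------------------
# Power / sample size

@dataclass(frozen=True)
class SampleSizeResult:
    per_group: int  # from the noncentral-t power function
    normal_approx: int  # classical closed-form value
    power_at_n: float


def _two_sample_power(n: int, delta: float, sd: float, alpha: float) -> float:
    df = 2 * n - 2
    ncp = delta / (sd * math.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, ncp)
                 + stats.nct.cdf(-tcrit, df, ncp))


def sample_size_two_means(alpha: float, power: float, mean_a: float,
                          mean_b: float, sd: float) -> SampleSizeResult:
    """Per-group n for a two-sided two-sample comparison of means.

    Returns both the exact value (smallest n whose noncentral-t power meets
    the target) and the classical normal-approximation value
    ``ceil(2 * sd^2 * (z_{1-alpha/2} + z_power)^2 / delta^2)``.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if mean_a == mean_b:
        raise ValueError("means must differ")
    if sd <= 0:
        raise ValueError("sd must be positive")
    delta = abs(mean_a - mean_b)
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    n_normal = math.ceil(2 * (sd * z / delta) ** 2)
    n = 2
    while _two_sample_power(n, delta, sd, alpha) < power:
        n += 1
        if n > 10**6:
            raise RuntimeError("sample size search did not converge")
    return SampleSizeResult(per_group=n, normal_approx=n_normal,
                            power_at_n=_two_sample_power(n, delta, sd, alpha))


# --------------------------------------------------------------------------
# Analysis plan: normality-gated comparison

def compare_groups(x: Sequence[float], y: Sequence[float],
                   alpha: float = 0.05) -> TestResult:
    """Full analysis-plan comparison of two raw samples.

    Shapiro-Wilk screens each arm for normality at ``alpha``; normal data get
    an independent-samples t test (pooled, or Welch when Levene rejects
    equality of variances); non-normal data fall back to Mann-Whitney U.
    Cohen's d is attached for t-based results.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    def _screens_normal(v: np.ndarray) -> bool:
        if len(v) < 3 or v.std() == 0:  # Shapiro-Wilk needs n >= 3 and spread
            return True
        return bool(stats.shapiro(v).pvalue >= alpha)

    normal = _screens_normal(x) and _screens_normal(y)
    if not normal:
        return mann_whitney(x, y)
    if len(x) < 3 or len(y) < 3 or x.std() == 0 or y.std() == 0:
        equal_var = True  # Levene degenerate on tiny/constant samples
    else:
        equal_var = stats.levene(x, y).pvalue >= alpha
    res = t_from_raw(x, y, pooled=equal_var)
    try:
        d = cohens_d_from_raw(x, y)
    except ValueError:
        d = None
    return TestResult(statistic=res.statistic, df=res.df,
                      p_two_sided=res.p_two_sided, effect_size=d,
                      method=res.method)


# --------------------------------------------------------------------------
# Printed group summaries (control n=26 vs facilitated intervention n=22)
# and their reproduction

TABLE2_SUMMARIES: list[tuple[str, GroupSummary, GroupSummary, bool]] = [
    # (variable, control, intervention, effect size reported)
    ("overall_flow", GroupSummary(26, 4.40, 0.89), GroupSummary(22, 4.95, 0.85), True),
    ("fluency", GroupSummary(26, 4.03, 1.16), GroupSummary(22, 4.52, 1.06), True),
    ("absorption", GroupSummary(26, 4.96, 0.83), GroupSummary(22, 5.60, 0.87), True),
    ("importance", GroupSummary(26, 4.26, 1.39), GroupSummary(22, 4.35, 1.78), True),
    ("hours_ideal_glucose", GroupSummary(26, 2.66, 1.36), GroupSummary(22, 2.35, 1.09), False),
    ("metformin_errors", GroupSummary(26, 2.77, 1.88), GroupSummary(22, 2.73, 1.67), False),
    ("evacuations", GroupSummary(26, 1.58, 1.94), GroupSummary(22, 0.64, 0.95), False),
]


def reproduce_table2(summaries: Optional[list[tuple[str, GroupSummary,
                                                    GroupSummary, bool]]] = None
                     ) -> pd.DataFrame:
    """Recompute every between-group comparison from the group summaries.

    One row per variable with the pooled t statistic (control minus
    intervention), its absolute value, df, two-sided p, and Cohen's d for the
    flow-scale rows.
    """
    summaries = summaries if summaries is not None else TABLE2_SUMMARIES
    rows = []
    for name, ctrl, intv, with_d in summaries:
        res = t_from_summary(ctrl, intv, pooled=True)
        rows.append({
            "variable": name,
            "control_n": ctrl.n, "control_mean": ctrl.mean, "control_sd": ctrl.sd,
            "intervention_n": intv.n, "intervention_mean": intv.mean,
            "intervention_sd": intv.sd,
            "t": res.statistic, "abs_t": abs(res.statistic),
            "df": res.df, "p": res.p_two_sided,
            "cohens_d": cohens_d_from_summary(ctrl, intv) if with_d else float("nan"),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Synthetic FSS responses (latent-flow model) and null calibration

def synthesize_fss_responses(n: int, latent_mean: float,
                             rng: np.random.Generator,
                             latent_sd: float = 0.9,
                             item_noise_sd: float = 0.8) -> np.ndarray:
    """Simulate an arm of 13-item FSS responses.

    Each subject has a latent flow level ``~ N(latent_mean, latent_sd)``;
    each item adds independent noise and is discretized to the 1-7 scale.
    Useful for exercising the raw-data scoring path; real FSS responses are
    human-reported and are not claimed to follow this model.
    """
    latent = rng.normal(latent_mean, latent_sd, size=(n, 1))
    items = latent + rng.normal(0.0, item_noise_sd, size=(n, 13))
    return np.clip(np.rint(items), 1, 7).astype(int)


def type_i_error_rate(n_a: int, n_b: int, alpha: float, n_sims: int,
                      rng: np.random.Generator) -> float:
    """Empirical type-I error of the pooled t test under a common normal null.

    Vectorized over ``n_sims`` replicate trials with arm sizes ``n_a``/``n_b``
    drawn from the same standard normal; returns the rejection fraction at
    ``alpha`` (two-sided).
    """
    xa = rng.standard_normal((n_sims, n_a))
    xb = rng.standard_normal((n_sims, n_b))
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
    t = (ma - mb) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    tcrit = stats.t.ppf(1 - alpha / 2, n_a + n_b - 2)
    return float(np.mean(np.abs(t) > tcrit))
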
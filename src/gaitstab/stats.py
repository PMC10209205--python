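"""Nondimensionalization and the study's statistical comparisons.

All measures are made dimensionless with inverted-pendulum scaling before
group comparisons: lengths divide by the leg length L, velocities by
sqrt(gL), accelerations by g and times by sqrt(L/g).  Two-group contrasts
use unpaired t-tests; three-condition contrasts use a one-way ANOVA
followed by post-hoc t-tests with the Holm-Sidak step-down correction, with
the effect size eta^2 = SS_between / SS_total reported for significant
omnibus results.  The significance level is alpha = 0.05 throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

DEFAULT_ALPHA = 0.05


@dataclass
class NondimScales:
    """Inverted-pendulum scale factors built from leg length and gravity."""

    leg_length: float
    gravity: float = 9.806

    def __post_init__(self) -> None:
        if self.leg_length <= 0 or self.gravity <= 0:
            raise ValueError("leg length and gravity must be positive")

    @property
    def length_scale(self) -> float:
        return self.leg_length

    @property
    def velocity_scale(self) -> float:
        return float(np.sqrt(self.gravity * self.leg_length))

    @property
    def accel_scale(self) -> float:
        return self.gravity

    @property
    def time_scale(self) -> float:
        return float(np.sqrt(self.leg_length / self.gravity))


_KIND_TO_SCALE = {
    "length": "length_scale",
    "velocity": "velocity_scale",
    "acceleration": "accel_scale",
    "time": "time_scale",
}


def nondimensionalize(value, kind: str, scales: NondimScales):
    """Divide ``value`` by the scale matching its physical kind."""
    try:
        attr = _KIND_TO_SCALE[kind]
    except KeyError:
        raise ValueError(
            f"unknown kind {kind!r}; expected one of {sorted(_KIND_TO_SCALE)}"
        ) from None
    return np.asarray(value, float) / getattr(scales, attr)


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison."""

    test: str
    groups: tuple[str, ...]
    statistic: float
    pvalue: float
    eta_squared: float | None = None
    alpha: float = DEFAULT_ALPHA
    posthoc: list["ComparisonResult"] = field(default_factory=list)
    adjusted_pvalue: float | None = None

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def unpaired_t(
    group_a,
    group_b,
    names: tuple[str, str] = ("A", "B"),
    equal_var: bool = True,
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Two-sided unpaired t-test (pooled variance by default, Welch by flag).

    Two groups with zero variance and equal means are degenerate; by
    convention they compare equal (t = 0, p = 1).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0 and np.mean(a) == np.mean(b):
        return ComparisonResult("t", names, 0.0, 1.0, alpha=alpha)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult("t", names, float(t), float(p), alpha=alpha)


def one_way_anova(
    groups: dict[str, np.ndarray] | list,
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """One-way ANOVA with eta^2 = SS_between / SS_total.

    ``groups`` maps group name -> sample (or is a plain list of samples).
    When every observation is identical the test is degenerate: F = 0,
    p = 1, eta^2 = 0 by convention.
    """
    if not isinstance(groups, dict):
        groups = {str(i): g for i, g in enumerate(groups)}
    names = tuple(groups)
    arrays = [np.asarray(g, float) for g in groups.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least 2 observations")
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_total = float(np.sum((allv - grand) ** 2))
    ss_between = float(
        sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    )
    if ss_total == 0.0:
        return ComparisonResult("anova", names, 0.0, 1.0, eta_squared=0.0, alpha=alpha)
    f, p = sps.f_oneway(*arrays)
    eta2 = ss_between / ss_total
    return ComparisonResult(
        "anova", names, float(f), float(p), eta_squared=float(eta2), alpha=alpha
    )


def holm_sidak(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, returned in input order.

    Sort ascending; the k-th smallest (1-based) of m p-values becomes
    ``1 - (1 - p_(k))**(m - k + 1)``; enforce monotone non-decreasing over
    the sorted sequence and cap at 1.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


def posthoc_ttests(
    groups: dict[str, np.ndarray],
    equal_var: bool = True,
    paired: bool = False,
    alpha: float = DEFAULT_ALPHA,
) -> list[ComparisonResult]:
    """All pairwise t-tests with Holm-Sidak adjusted p-values."""
    pairs = list(itertools.combinations(groups, 2))
    raw = []
    results = []
    for a, b in pairs:
        if paired:
            t, p = sps.ttest_rel(groups[a], groups[b])
            res = ComparisonResult("paired-t", (a, b), float(t), float(p), alpha=alpha)
        else:
            res = unpaired_t(groups[a], groups[b], (a, b), equal_var, alpha)
        raw.append(res.pvalue)
        results.append(res)
    for res, adj in zip(results, holm_sidak(raw)):
        res.adjusted_pvalue = float(adj)
    return results


def compare_conditions(
    groups: dict[str, np.ndarray],
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
    paired_posthoc: bool = False,
) -> ComparisonResult:
    """The study's three-condition workflow on one measure.

    One-way ANOVA across the condition groups; if the omnibus test is
    significant, post-hoc pairwise t-tests with Holm-Sidak correction are
    attached.  eta^2 is always computed; report layers may gate it on
    significance.  Groups with missing subjects should be dropped by the
    caller (listwise per comparison).
    """
    res = one_way_anova(groups, alpha=alpha)
    if res.significant:
        res.posthoc = posthoc_ttests(
            groups, equal_var=equal_var, paired=paired_posthoc, alpha=alpha
        )
    return res
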
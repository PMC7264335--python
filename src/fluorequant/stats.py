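"""Group-comparison statistics used by the reporter assays.

One-way ANOVA with Tukey's HSD post hoc test is the workhorse comparison for
multi-condition fraction-positive data; the two-condition in vivo intensity
comparison uses the unpaired two-tailed Student's t-test; replicate spread is
summarized as mean ± SEM.  The replicate unit entering a test is the
independent-experiment (or per-sample) mean, not the per-cell value.

All statistics are computed from the definitional formulas (sums of squares,
pooled variance, Tukey–Kramer standardized range); tail probabilities come
from :mod:`scipy.stats` distributions (``f``, ``t``, ``studentized_range``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = ["StatsResult", "sem", "one_way_anova", "tukey_hsd", "t_test_unpaired"]


@dataclass
class StatsResult:
    """Outcome of one test: the statistic, its degrees of freedom, the
    p-value, and (for Tukey) the pairwise comparisons as a list of dicts with
    keys ``pair, mean_diff, q, adjusted_p``."""

    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    pairwise: list[dict] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value outside [0, 1]: {self.p_value}")


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ParameterError(f"SEM needs n >= 2 values, got {values.size}")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def _validate_groups(groups: dict) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ParameterError(f"need >= 2 groups, got {len(groups)}")
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=np.float64)
        if arr.size < 2:
            raise ParameterError(
                f"group {label!r} has n = {arr.size}; variance-based tests need n >= 2"
            )
        out[str(label)] = arr
    return out


def _anova_decomposition(groups: dict[str, np.ndarray]):
    """Between/within sums of squares and mean squares."""
    all_values = np.concatenate(list(groups.values()))
    grand = all_values.mean()
    k = len(groups)
    n_total = all_values.size
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_between = k - 1
    df_within = n_total - k
    return ss_between, ss_within, df_between, df_within


def one_way_anova(groups: dict) -> StatsResult:
    """One-way fixed-effects ANOVA.

    ``F = MS_between / MS_within`` with ``(k-1, N-k)`` degrees of freedom and
    the p-value from the upper tail of the F distribution.  Zero between- and
    within-group variance together make F undefined (raises).  Zero within-
    group variance with distinct means is reported as ``F = inf, p = 0`` with
    a note.
    """
    groups = _validate_groups(groups)
    ssb, ssw, dfb, dfw = _anova_decomposition(groups)
    msb = ssb / dfb
    msw = ssw / dfw
    if msw == 0.0:
        if msb == 0.0:
            raise ParameterError(
                "all observations identical: F is undefined (0/0)"
            )
        return StatsResult(
            "one_way_anova", float("inf"), (float(dfb), float(dfw)), 0.0,
            note="zero within-group variance with distinct group means",
        )
    f_stat = msb / msw
    p = float(sps.f.sf(f_stat, dfb, dfw))
    return StatsResult("one_way_anova", float(f_stat), (float(dfb), float(dfw)), p)


def tukey_hsd(groups: dict, alpha: float = 0.05) -> StatsResult:
    """Tukey's honestly-significant-difference all-pairs comparison.

    For each pair the standardized range statistic uses the Tukey–Kramer
    standard error, valid for unequal group sizes::

        q_ij = |mean_i - mean_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j))

    and the adjusted p-value is the upper tail of the studentized-range
    distribution with parameters ``(k, N-k)``.  The omnibus F and its p-value
    are reported alongside the pairwise list.
    """
    groups = _validate_groups(groups)
    omnibus = one_way_anova(groups)
    ssb, ssw, dfb, dfw = _anova_decomposition(groups)
    msw = ssw / dfw
    k = len(groups)
    labels = list(groups)
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[labels[i]], groups[labels[j]]
            diff = gi.mean() - gj.mean()
            if msw == 0.0:
                q = float("inf") if diff != 0 else 0.0
                adj_p = 0.0 if diff != 0 else 1.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
                q = abs(diff) / se
                adj_p = float(sps.studentized_range.sf(q, k, dfw))
            pairwise.append(
                {
                    "pair": (labels[i], labels[j]),
                    "mean_diff": float(diff),
                    "q": float(q),
                    "adjusted_p": min(max(adj_p, 0.0), 1.0),
                    "reject": adj_p < alpha,
                }
            )
    return StatsResult(
        "tukey_hsd",
        omnibus.statistic,
        omnibus.df,
        omnibus.p_value,
        pairwise=pairwise,
        note=omnibus.note,
    )


def t_test_unpaired(a, b, two_tailed: bool = True, welch: bool = False) -> StatsResult:
    """Unpaired Student's t-test with pooled variance (Welch behind a flag).

    Pooled form: ``df = n_a + n_b - 2``; two-tailed p by default.  Zero pooled
    variance with equal means is undefined (raises); with unequal means the
    result is reported as ``t = ±inf, p = 0`` with a note.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ParameterError("t-test needs n >= 2 in both samples")
    diff = a.mean() - b.mean()
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0.0:
            if diff == 0.0:
                raise ParameterError("zero variance and equal means: t undefined")
            return StatsResult(
                "t_test_welch", float(np.sign(diff)) * float("inf"), (0.0,), 0.0,
                note="zero variance with unequal means",
            )
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        name = "t_test_welch"
    else:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        if sp2 == 0.0:
            if diff == 0.0:
                raise ParameterError("zero pooled variance and equal means: t undefined")
            return StatsResult(
                "t_test_pooled", float(np.sign(diff)) * float("inf"), (float(df),), 0.0,
                note="zero pooled variance with unequal means",
            )
        se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
        name = "t_test_pooled"
    t_stat = diff / se
    if two_tailed:
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
    else:
        p = float(sps.t.sf(t_stat, df))
    return StatsResult(name, float(t_stat), (float(df),), min(p, 1.0))
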
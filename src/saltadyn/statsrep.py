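"""The study's statistical toolkit: t-tests, one-way ANOVA + Fisher LSD,
and mean ± SEM reporting.

Group comparisons follow the original analysis plan: an unpaired two-sided
Student's t-test whose equal-variance assumption is checked with a two-sided
F-test (falling back to Welch's t when the F-test rejects at 0.05), or a
one-way ANOVA followed by Fisher's LSD post hoc test.  LSD p-values are
deliberately unadjusted — that is what Fisher's LSD is — and every result
records which test was actually run.  Significance stars: *p<0.05,
**p<0.01, ***p<0.001.

The unit of replication is the cell, matching how the study reports n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "PairwiseComparison",
    "ComparisonResult",
    "ttest_unpaired",
    "anova_lsd",
    "summarize",
    "significance_stars",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    statistic: float
    p_value: float


@dataclass
class ComparisonResult:
    test: str  # t_unpaired | welch_t | anova_lsd | f_variance
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    group_summaries: list[GroupSummary] = field(default_factory=list)
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    variance_check: "ComparisonResult | None" = None
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Star coding used throughout the study's figures."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _summaries(groups: dict[str, np.ndarray]) -> list[GroupSummary]:
    out = []
    for label, g in groups.items():
        sem = g.std(ddof=1) / np.sqrt(g.size) if g.size > 1 else 0.0
        out.append(GroupSummary(label, int(g.size), float(g.mean()), float(sem)))
    return out


def _check_sample(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError(f"sample {name!r} needs n >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return arr


def f_variance_test(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-sided variance-ratio F-test for equality of variances."""
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    dfa, dfb = a.size - 1, b.size - 1
    if va == 0 and vb == 0:
        return ComparisonResult(
            "f_variance", np.nan, (dfa, dfb), 1.0, degenerate=True
        )
    f = va / vb if vb > 0 else np.inf
    cdf = sps.f.cdf(f, dfa, dfb)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return ComparisonResult("f_variance", float(f), (dfa, dfb), float(min(p, 1.0)))


def ttest_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    variance_alpha: float = 0.05,
    policy: str = "auto",
) -> ComparisonResult:
    """Unpaired two-sided t-test with an F-test variance check.

    ``policy='auto'`` (default): pooled-variance Student's t when the F-test
    does not reject variance equality at ``variance_alpha``, Welch's t
    otherwise; the decision is recorded in ``test`` and the F-test result in
    ``variance_check``.  ``policy='pooled'`` or ``'welch'`` forces a branch.
    """
    a = _check_sample(a, labels[0])
    b = _check_sample(b, labels[1])
    fres = f_variance_test(a, b)

    if policy == "auto":
        use_pooled = fres.p_value >= variance_alpha
    elif policy in ("pooled", "welch"):
        use_pooled = policy == "pooled"
    else:
        raise ValueError(f"unknown policy {policy!r}")

    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    degenerate = False
    if use_pooled:
        df: float = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        test = "t_unpaired"
    else:
        se = np.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
        test = "welch_t"
    if se == 0:
        # both groups constant; equal means -> no evidence of difference
        tstat, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        degenerate = True
    else:
        tstat = diff / se
        p = 2.0 * sps.t.sf(abs(tstat), df)
    return ComparisonResult(
        test=test,
        statistic=float(tstat),
        df=float(df),
        p_value=float(min(p, 1.0)),
        group_summaries=_summaries({labels[0]: a, labels[1]: b}),
        variance_check=fres,
        degenerate=degenerate,
    )


def anova_lsd(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
) -> ComparisonResult:
    """One-way ANOVA followed by Fisher's LSD post hoc test.

    Pairwise LSD statistics use the ANOVA pooled error term:
    t_ij = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j)) with df = N - k
    and unadjusted two-sided p-values.  With two groups this reduces exactly
    to the pooled-variance t-test.
    """
    if not isinstance(groups, dict):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    data = {k: _check_sample(v, k) for k, v in groups.items()}

    k = len(data)
    ns = {g: arr.size for g, arr in data.items()}
    n_total = sum(ns.values())
    grand = np.concatenate(list(data.values())).mean()
    ss_between = sum(n * (arr.mean() - grand) ** 2 for n, arr in
                     zip(ns.values(), data.values()))
    ss_within = sum(((arr - arr.mean()) ** 2).sum() for arr in data.values())
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    mse = ss_within / df_within

    if mse == 0:
        f = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = ms_between / mse
        p = sps.f.sf(f, df_between, df_within)

    pairwise = []
    for ga, gb in combinations(data, 2):
        diff = data[ga].mean() - data[gb].mean()
        if mse == 0:
            t_ij, p_ij = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        else:
            se = np.sqrt(mse * (1.0 / ns[ga] + 1.0 / ns[gb]))
            t_ij = diff / se
            p_ij = 2.0 * sps.t.sf(abs(t_ij), df_within)
        pairwise.append(
            PairwiseComparison(ga, gb, float(diff), float(t_ij),
                               float(min(p_ij, 1.0)))
        )
    return ComparisonResult(
        test="anova_lsd",
        statistic=float(f),
        df=(float(df_between), float(df_within)),
        p_value=float(min(p, 1.0)),
        group_summaries=_summaries(data),
        pairwise=pairwise,
    )


def summarize(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    p_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-group n / mean / SEM report (the study's 'means ± SEM').

    Optional per-group p-values add a significance-star column.  Empty
    groups are omitted with a warning.
    """
    rows = []
    for label, grp in table.groupby(group_col, sort=False):
        vals = grp[value_col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"group {label!r} is empty; omitted", stacklevel=2)
            continue
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        row = {
            group_col: label,
            "n": vals.size,
            "mean": vals.mean(),
            "sem": sem,
        }
        if p_values is not None and label in p_values:
            row["p"] = p_values[label]
            row["stars"] = significance_stars(p_values[label])
        rows.append(row)
    return pd.DataFrame(rows)
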
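"""Treatment comparison: one-way ANOVA, Fisher's LSD letters,
percent changes against a reference treatment, and the pairwise Pearson
correlation panel.

The multiple-comparison procedure is the classical (unprotected by
default) Fisher least-significant-difference test: every treatment pair
is compared with a t statistic using the pooled ANOVA error, and a
compact letter display summarizes which means differ at the chosen
alpha.  Percent changes are contrasts of treatment means,
``100 * (mean_t - mean_ref) / mean_ref``; they are flagged undefined when
the reference mean is non-positive (relevant for mean-zero composites
such as EMF, whose percent change has no natural denominator).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trial import PlotRecord, records_to_frame

__all__ = [
    "AnovaResult",
    "LsdGrouping",
    "PercentChange",
    "CorrelationPanel",
    "oneway_anova",
    "fisher_lsd",
    "compact_letter_display",
    "percent_changes",
    "correlation_panel",
]


@dataclass
class AnovaResult:
    """Classical fixed-effects one-way ANOVA decomposition."""

    variable: str
    F: float
    p: float
    df_between: int
    df_within: int
    mse_within: float
    means: dict[str, float]
    se: dict[str, float]
    n: dict[str, int]

    @property
    def groups(self) -> list[str]:
        return list(self.means)


def oneway_anova(values, group_labels, variable: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA of ``values`` grouped by label.

    Group order in the result follows first appearance of each label.
    Zero within-group variance with unequal means yields ``F = inf``,
    ``p = 0``; with equal means, ``F = 0``.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if v.shape != labels.shape:
        raise ValueError("values and group labels must have equal length")
    order = list(dict.fromkeys(labels.tolist()))
    if len(order) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    groups = {g: v[labels == g] for g in order}
    for g, x in groups.items():
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    k = len(order)
    N = v.size
    grand = v.mean()
    ss_between = sum(x.size * (x.mean() - grand) ** 2 for x in groups.values())
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in groups.values())
    df_b, df_w = k - 1, N - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = 0.0 if ms_b == 0 else math.inf
        p = 1.0 if ms_b == 0 else 0.0
    else:
        F = ms_b / ms_w
        p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        variable=variable,
        F=float(F),
        p=p,
        df_between=df_b,
        df_within=df_w,
        mse_within=float(ms_w),
        means={g: float(x.mean()) for g, x in groups.items()},
        se={g: float(x.std(ddof=1) / math.sqrt(x.size)) for g, x in groups.items()},
        n={g: int(x.size) for g, x in groups.items()},
    )


@dataclass
class LsdGrouping:
    """Fisher LSD pairwise outcome with a compact letter display."""

    alpha: float
    lsd_value: float  # balanced-design LSD; pairwise values in `significant`
    significant: dict[tuple[str, str], bool]
    p_values: dict[tuple[str, str], float]
    letters: dict[str, str]
    protected: bool
    omnibus_p: float

    def same_group(self, a: str, b: str) -> bool:
        if a == b:
            return True
        key = (a, b) if (a, b) in self.significant else (b, a)
        return not self.significant[key]


def fisher_lsd(anova: AnovaResult, alpha: float = 0.05, protected: bool = False) -> LsdGrouping:
    """Pairwise Fisher LSD test on an ANOVA result.

    A pair (i, j) differs when ``|mean_i - mean_j|`` exceeds
    ``t(1 - alpha/2, df_within) * sqrt(MSE * (1/n_i + 1/n_j))``.  With
    ``protected=True`` no pair is declared different unless the omnibus
    ANOVA is itself significant at ``alpha``.
    """
    if anova.df_within < 1:
        raise ValueError("LSD requires at least 1 within-group df")
    tcrit = float(stats.t.ppf(1 - alpha / 2, anova.df_within))
    gate = (not protected) or (anova.p < alpha)
    sig: dict[tuple[str, str], bool] = {}
    pvals: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(anova.groups, 2):
        se_diff = math.sqrt(anova.mse_within * (1 / anova.n[a] + 1 / anova.n[b]))
        diff = abs(anova.means[a] - anova.means[b])
        if se_diff == 0:
            t_stat = math.inf if diff > 0 else 0.0
        else:
            t_stat = diff / se_diff
        pvals[(a, b)] = float(2 * stats.t.sf(t_stat, anova.df_within))
        sig[(a, b)] = gate and diff > tcrit * se_diff
    n_ref = min(anova.n.values())
    lsd_value = tcrit * math.sqrt(anova.mse_within * 2 / n_ref)
    letters = compact_letter_display(anova.means, sig)
    return LsdGrouping(
        alpha=alpha,
        lsd_value=lsd_value,
        significant=sig,
        p_values=pvals,
        letters=letters,
        protected=protected,
        omnibus_p=anova.p,
    )


def compact_letter_display(
    means: dict[str, float],
    significant: dict[tuple[str, str], bool],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Treatments are processed in descending-mean order (ties broken by
    insertion order of ``means``); two treatments share a letter iff
    their pair is non-significant.  Letters start at "a" for the highest
    mean.
    """
    order = sorted(means, key=lambda g: -means[g])

    def differs(a: str, b: str) -> bool:
        if a == b:
            return False
        return significant.get((a, b), significant.get((b, a), False))

    # insert step: grow letter groups one treatment at a time
    groups: list[set[str]] = [{order[0]}]
    for t in order[1:]:
        inserted = False
        for grp in groups:
            if not any(differs(t, h) for h in grp):
                grp.add(t)
                inserted = True
        if not inserted:
            # duplicate each conflicting group, keeping only compatible members
            for grp in list(groups):
                groups.append({h for h in grp if not differs(t, h)} | {t})
        # absorb step: drop duplicates and groups contained in another
        uniq: list[set[str]] = []
        for grp in groups:
            if grp not in uniq:
                uniq.append(grp)
        groups = [g for g in uniq if not any(g < h for h in uniq)]
    groups.sort(key=lambda g: min(order.index(x) for x in g))
    letters = {g: "" for g in means}
    for idx, grp in enumerate(groups):
        ch = chr(ord("a") + idx)
        for g in grp:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in means}


@dataclass
class PercentChange:
    """Percent change of a treatment mean against the reference mean."""

    variable: str
    treatment: str
    reference: str
    value: float | None  # None when undefined (reference mean <= 0)

    @property
    def defined(self) -> bool:
        return self.value is not None


def percent_changes(
    records: list[PlotRecord] | pd.DataFrame,
    variable: str,
    reference: str = "CK",
) -> list[PercentChange]:
    """Per-treatment percent change of means versus the reference.

    Computed from treatment means of the raw variable (a contrast of
    means, not a mean of per-plot ratios).
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if variable not in frame.columns:
        raise ValueError(f"variable {variable!r} is missing from the plot data")
    means = frame.groupby("treatment", sort=False)[variable].mean()
    if reference not in means.index:
        raise ValueError(f"reference treatment {reference!r} not present")
    ref = float(means[reference])
    out = []
    for trt, m in means.items():
        value = None if ref <= 0 else 100.0 * (float(m) - ref) / ref
        out.append(PercentChange(variable=variable, treatment=str(trt),
                                 reference=reference, value=value))
    return out


@dataclass
class CorrelationPanel:
    """Pairwise Pearson correlations with significance stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        def star(p: float) -> str:
            if np.isnan(p):
                return ""
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return ""

        self.stars = self.p.map(star)
        np.fill_diagonal(self.stars.values, "")


def correlation_panel(
    records: list[PlotRecord] | pd.DataFrame,
    variables: list[str],
) -> CorrelationPanel:
    """Pearson r and two-sided p for every variable pair.

    Constant variables yield NaN r/p for their pairs (flagged, not an
    error), mirroring how such panels are displayed.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    for v in variables:
        if v not in frame.columns:
            raise ValueError(f"variable {v!r} is missing from the plot data")
    if len(frame) < 3:
        raise ValueError("correlation panel needs at least 3 observations")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        x = frame[variables[i]].to_numpy(float)
        y = frame[variables[j]].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
            continue
        res = stats.pearsonr(x, y)
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=variables, columns=variables)
    pdf = pd.DataFrame(p, index=variables, columns=variables)
    return CorrelationPanel(r=rdf, p=pdf)
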
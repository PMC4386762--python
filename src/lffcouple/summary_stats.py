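"""Group-comparison statistics from summary data.

Demographic and clinical group comparisons in small imaging cohorts are
typically reported as mean ± SD per group; every classical test used
here (two-sample t, one-way ANOVA, Pearson chi-square) is an exact
function of (n, mean, SD) or of a contingency table, so the printed
statistics can be recomputed without raw data.

The module also carries the reference three-group dementia cohort
(healthy controls, amnestic MCI, probable AD; 10 subjects each) whose
covariate distributions the synthetic generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "ContingencyTable",
    "two_sample_t",
    "one_way_anova_summary",
    "chi_square_independence",
    "t_critical",
    "round_half_away",
    "REFERENCE_DEMOGRAPHICS",
    "REFERENCE_GENDER_COUNTS",
]


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / SD for one group, as printed in a demographics table."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class ContingencyTable:
    """r x c count table with labels (e.g. groups x gender)."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2D table")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if arr.sum() == 0:
            raise ValueError("contingency table is all zeros")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def two_sample_t(
    a: GroupSummary,
    b: GroupSummary,
    variance: str = "pooled",
    tails: int = 2,
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    ``variance="pooled"`` uses the classical Student t with
    ``df = n_a + n_b - 2``; ``"welch"`` uses the Satterthwaite df.  With
    equal group sizes the t value itself is identical under both.  For
    ``tails=1`` the p-value is for the alternative in the direction of
    the observed difference (mean_a vs mean_b as given).

    Returns ``(t, df, p)``.
    """
    if tails not in (1, 2):
        raise ValueError(f"tails must be 1 or 2, got {tails}")
    va, vb = a.sd**2, b.sd**2
    if va == 0 and vb == 0 and a.mean == b.mean:
        raise ValueError("t undefined: both SDs are zero with equal means")
    if variance == "pooled":
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = float(a.n + b.n - 2)
    elif variance == "welch":
        se = np.sqrt(va / a.n + vb / b.n)
        df = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
    else:
        raise ValueError(f"variance must be 'pooled' or 'welch', got {variance!r}")
    if se == 0:
        raise ValueError("t undefined: standard error is zero")
    t = (a.mean - b.mean) / se
    if tails == 2:
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        p = stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def one_way_anova_summary(groups: list[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA from per-group (n, mean, SD).

    Exact for balanced and unbalanced designs: the between / within sums
    of squares are functions of the summaries alone.  Returns
    ``(F, df1, df2, p)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_total = ns.sum()
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1 = len(groups) - 1
    df2 = int(n_total) - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def chi_square_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns ``(chi2, df, p)`` with ``df = (r-1)(c-1)``.
    """
    obs = table.as_array()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def t_critical(df: float, p_two_tailed: float) -> float:
    """Two-tailed Student t quantile: |t| exceeded with probability p."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not (0 < p_two_tailed < 1):
        raise ValueError(f"p must be in (0, 1), got {p_two_tailed}")
    return float(stats.t.isf(p_two_tailed / 2.0, df))


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of printed tables."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


# ---------------------------------------------------------------------------
# Reference cohort: demographics of the emulated three-group dementia study.
# Values are mean ± SD over n=10 per group; gender counts are (M, F).
# These numbers double as the synthetic generator's covariate defaults.

REFERENCE_DEMOGRAPHICS: dict[str, dict[str, GroupSummary]] = {
    "age": {
        "AD": GroupSummary("AD", 10, 72.3, 8.3),
        "MCI": GroupSummary("MCI", 10, 70.7, 7.1),
        "HC": GroupSummary("HC", 10, 66.0, 9.6),
    },
    "education": {
        "AD": GroupSummary("AD", 10, 8.6, 3.6),
        "MCI": GroupSummary("MCI", 10, 11.1, 3.5),
        "HC": GroupSummary("HC", 10, 14.5, 3.0),
    },
    "mmse": {
        "AD": GroupSummary("AD", 10, 21.5, 3.7),
        "MCI": GroupSummary("MCI", 10, 25.8, 2.3),
        "HC": GroupSummary("HC", 10, 29.30, 0.67),
    },
    "gmv": {
        "AD": GroupSummary("AD", 10, 5.20, 0.51),
        "MCI": GroupSummary("MCI", 10, 6.10, 0.61),
        "HC": GroupSummary("HC", 10, 6.6, 1.0),
    },
}

REFERENCE_GENDER_COUNTS = ContingencyTable(
    counts=((4, 6), (6, 4), (7, 3)),
    row_labels=("AD", "MCI", "HC"),
    col_labels=("M", "F"),
)


def demographics_report(
    demographics: dict[str, dict[str, GroupSummary]] | None = None,
    gender: ContingencyTable | None = None,
) -> dict[str, float]:
    """Recompute the full battery of group-comparison statistics.

    Runs, for each continuous variable, the three-group one-way ANOVA
    and the post-hoc two-sample two-tailed t-tests (AD vs HC, MCI vs HC,
    MCI vs AD), plus the gender chi-square.  Returns a flat dict of
    statistics keyed like ``"mmse_t_ad_vs_hc"``.
    """
    demo = REFERENCE_DEMOGRAPHICS if demographics is None else demographics
    gtab = REFERENCE_GENDER_COUNTS if gender is None else gender
    out: dict[str, float] = {}
    for var, groups in demo.items():
        f, _, _, p = one_way_anova_summary(list(groups.values()))
        out[f"{var}_anova_f"] = f
        out[f"{var}_anova_p"] = p
        for g1, g2 in (("AD", "HC"), ("MCI", "HC"), ("MCI", "AD")):
            t, _, p = two_sample_t(groups[g1], groups[g2])
            out[f"{var}_t_{g1.lower()}_vs_{g2.lower()}"] = t
            out[f"{var}_p_{g1.lower()}_vs_{g2.lower()}"] = p
    chi2, _, p = chi_square_independence(gtab)
    out["gender_chi2"] = chi2
    out["gender_chi2_p"] = p
    return out
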
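"""Sex-stratified cohort statistics: per-measure t-tests and power analysis.

Each of the 21 pelvimetric measures is compared between the female and
male groups with a two-sample Student t-test (pooled variance by default,
df = n1 + n2 − 2; Welch available by flag), two-tailed at α = 0.05.  No
multiple-testing correction is applied to the headline results; Bonferroni
and Benjamini–Hochberg adjusted p-values are emitted as supplementary
columns only.

The a priori power analysis for the two-independent-means design uses the
noncentral t distribution: for effect size d and group sizes n1, n2 the
noncentrality parameter is δ = d·√(n1·n2/(n1+n2)), the critical value is
the central-t quantile t_{1−α/2, df}, and the achieved power is
P(|T| > t_crit) under the noncentral t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .measures import MEASURE_REGISTRY, MEASURE_UNITS, PelvimetryRecord, records_to_frame

__all__ = [
    "GroupSummary",
    "TTestResult",
    "PowerResult",
    "two_sample_t",
    "t_power",
    "cohort_table",
    "CohortComparison",
    "CohortComparisonResults",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one measure in two groups."""

    measure: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    group_names: tuple[str, str] = ("female", "male")

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    mean_difference: float


@dataclass(frozen=True)
class PowerResult:
    """The a priori power quadruple for a two-independent-means t-test."""

    effect_size: float
    alpha: float
    n1: int
    n2: int
    noncentrality: float
    critical_t: float
    df: int
    power: float

    def __str__(self) -> str:
        return (
            f"two-sample t-test power analysis (two-tailed)\n"
            f"  effect size d   = {self.effect_size}\n"
            f"  alpha           = {self.alpha}\n"
            f"  n1, n2          = {self.n1}, {self.n2}\n"
            f"  noncentrality   = {self.noncentrality:.7f}\n"
            f"  critical t      = {self.critical_t:.7f}\n"
            f"  df              = {self.df}\n"
            f"  achieved power  = {self.power:.7f}"
        )


def two_sample_t(summary: GroupSummary, welch: bool = False) -> TTestResult:
    """Two-sample t-test from summary statistics.

    Pooled-variance Student test by default:
    ``s_p² = ((n1−1)s1² + (n2−1)s2²)/(n1+n2−2)`` and
    ``t = (m1−m2)/(s_p·√(1/n1+1/n2))`` with df = n1+n2−2, two-tailed p
    from the central t distribution.  With ``welch=True`` uses unpooled
    variances and Welch–Satterthwaite df.
    """
    n1, n2 = summary.n1, summary.n2
    m1, m2 = summary.mean1, summary.mean2
    s1, s2 = summary.sd1, summary.sd2
    diff = m1 - m2
    if s1 == 0 and s2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=n1 + n2 - 2, p_value=1.0, mean_difference=0.0)
        raise ValueError("both SDs are zero with unequal means: t is infinite")
    if welch:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p_value=float(p), mean_difference=float(diff))


def t_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> PowerResult:
    """A priori power of the two-sided two-sample t-test at effect size ``d``."""
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    delta = d * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = sps.nct.sf(t_crit, df, delta) + sps.nct.cdf(-t_crit, df, delta)
    return PowerResult(
        effect_size=float(d), alpha=float(alpha), n1=int(n1), n2=int(n2),
        noncentrality=float(delta), critical_t=float(t_crit), df=int(df),
        power=float(power),
    )


def _bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(p * len(p), 1.0)


def cohort_table(
    records: Sequence[PelvimetryRecord],
    labels: Sequence[str],
    group_names: tuple[str, str] = ("female", "male"),
    welch: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group summaries and t-tests for all 21 measures, in registry order.

    Returns one row per measure with group n/mean/SD (sample SD, ddof=1),
    the t statistic, df, two-tailed p, a significance flag at ``alpha``,
    and supplementary Bonferroni / Benjamini–Hochberg adjusted p columns.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels must have equal length")
    df_all = records_to_frame(records)
    labels = np.asarray(labels)
    g1, g2 = group_names
    d1 = df_all[labels == g1]
    d2 = df_all[labels == g2]
    if len(d1) < 2 or len(d2) < 2:
        raise ValueError(f"each group needs at least 2 records (got {len(d1)} {g1}, {len(d2)} {g2})")

    rows = []
    for m in MEASURE_REGISTRY:
        summary = GroupSummary(
            measure=m,
            n1=len(d1), mean1=float(d1[m].mean()), sd1=float(d1[m].std(ddof=1)),
            n2=len(d2), mean2=float(d2[m].mean()), sd2=float(d2[m].std(ddof=1)),
            group_names=group_names,
        )
        res = two_sample_t(summary, welch=welch)
        rows.append({
            "measure": m,
            "unit": MEASURE_UNITS[m],
            f"n_{g1}": summary.n1, f"mean_{g1}": summary.mean1, f"sd_{g1}": summary.sd1,
            f"n_{g2}": summary.n2, f"mean_{g2}": summary.mean2, f"sd_{g2}": summary.sd2,
            "mean_difference": res.mean_difference,
            "t": res.t, "df": res.df, "p_value": res.p_value,
            "significant": res.p_value < alpha,
        })
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = _bonferroni(table["p_value"].to_numpy())
    table["p_fdr_bh"] = sps.false_discovery_control(table["p_value"].to_numpy(), method="bh")
    return table


class CohortComparison:
    """Two-group comparison of pelvimetry records, statsmodels-style.

    Parameters
    ----------
    records:
        One :class:`PelvimetryRecord` per subject.
    labels:
        Group label per record (e.g. ``"female"`` / ``"male"``).

    Examples
    --------
    >>> model = CohortComparison(records, labels)
    >>> results = model.fit()
    >>> print(results.summary())        # doctest: +SKIP
    """

    def __init__(
        self,
        records: Sequence[PelvimetryRecord],
        labels: Sequence[str],
        group_names: tuple[str, str] = ("female", "male"),
    ):
        self.records = list(records)
        self.labels = list(labels)
        self.group_names = group_names

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, labels: Sequence[str], **kwargs) -> "CohortComparison":
        """Build from a DataFrame with the 21 registry columns."""
        records = [
            PelvimetryRecord(subject_id=str(idx), **{m: float(row[m]) for m in MEASURE_REGISTRY})
            for idx, row in data.iterrows()
        ]
        return cls(records, labels, **kwargs)

    def fit(self, welch: bool = False, alpha: float = 0.05) -> "CohortComparisonResults":
        table = cohort_table(
            self.records, self.labels, group_names=self.group_names,
            welch=welch, alpha=alpha,
        )
        return CohortComparisonResults(table, self.group_names, alpha=alpha, welch=welch)


class CohortComparisonResults:
    """Fitted cohort comparison: the 21-row table plus summaries."""

    def __init__(self, table: pd.DataFrame, group_names: tuple[str, str],
                 alpha: float = 0.05, welch: bool = False):
        self.table = table
        self.group_names = group_names
        self.alpha = alpha
        self.welch = welch

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self) -> str:
        g1, g2 = self.group_names
        kind = "Welch" if self.welch else "Student (pooled)"
        lines = [
            f"Pelvimetry cohort comparison: {g1} vs {g2}",
            f"two-tailed {kind} t-tests, alpha = {self.alpha}",
            f"{self.n_significant} of {len(self.table)} measures significant",
            "",
            f"{'measure':<26}{'unit':<5}{g1 + ' mean (SD)':>20}{g2 + ' mean (SD)':>20}"
            f"{'t':>9}{'p':>12}",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['measure']:<26}{r['unit']:<5}"
                f"{r[f'mean_{g1}']:>12.2f} ({r[f'sd_{g1}']:.2f})"
                f"{r[f'mean_{g2}']:>12.2f} ({r[f'sd_{g2}']:.2f})"
                f"{r['t']:>9.2f}{r['p_value']:>12.3g}"
                + ("  *" if r["significant"] else "")
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot_group_means(self, measures: Iterable[str] | None = None, ax=None):
        """Bar chart of group means with SD whiskers (requires matplotlib)."""
        import matplotlib.pyplot as plt

        g1, g2 = self.group_names
        sub = self.table if measures is None else self.table[self.table["measure"].isin(list(measures))]
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        x = np.arange(len(sub))
        w = 0.38
        ax.bar(x - w / 2, sub[f"mean_{g1}"], w, yerr=sub[f"sd_{g1}"], label=g1, capsize=2)
        ax.bar(x + w / 2, sub[f"mean_{g2}"], w, yerr=sub[f"sd_{g2}"], label=g2, capsize=2)
        ax.set_xticks(x)
        ax.set_xticklabels(sub["measure"], rotation=90)
        ax.set_ylabel("mean ± SD")
        ax.legend()
        return ax
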
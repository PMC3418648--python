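"""Group-comparison statistics for pooled stiffness biomarkers.

One-way designs only: classical ANOVA and Kruskal-Wallis across groups,
Tukey HSD for all pairwise contrasts, and Dunnett's many-to-one test
against a designated baseline.  Dunnett critical values and p-values
are estimated by seeded Monte-Carlo simulation of the null maximum-|t|
distribution (valid for arbitrary group counts and unbalanced sizes).
The turning-point procedure scans age-ordered groups for the earliest
age whose Dunnett-adjusted difference from the youngest group is
significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["DunnettResult", "GroupComparison", "dunnett_mc",
           "group_compare", "turning_point"]

DEFAULT_MC_DRAWS = 100_000


@dataclass
class DunnettResult:
    """Many-to-one comparisons against a baseline group."""

    baseline: str
    groups: list[str]                  # non-baseline groups, input order
    statistics: np.ndarray             # t statistic per comparison
    pvalues: np.ndarray                # max-|t|-adjusted, Monte-Carlo
    critical_value: float              # two-sided 5 % critical |t|
    n_draws: int

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.pvalues < alpha


@dataclass
class GroupComparison:
    """One-way comparison report across >= 2 groups."""

    groups: list[str]
    group_sizes: dict[str, int]
    anova_f: float
    anova_p: float
    kruskal_h: float
    kruskal_p: float
    tukey: pd.DataFrame | None = None
    dunnett: DunnettResult | None = None
    warnings: list[str] = field(default_factory=list)


def dunnett_mc(samples: dict[str, np.ndarray], baseline: str,
               n_draws: int = DEFAULT_MC_DRAWS,
               seed: int | None = None) -> DunnettResult:
    """Dunnett's test with Monte-Carlo critical values.

    Each non-baseline group is compared to the baseline with a t
    statistic using the pooled within-group variance; the family-wise
    adjusted p-value of comparison i is P(max_j |T_j| >= |t_i|) under
    the null, estimated from ``n_draws`` simulated draws of the
    correlated null statistics (group means share the baseline mean and
    the pooled variance estimate).
    """
    if baseline not in samples:
        raise ValueError(f"baseline group {baseline!r} not in samples")
    others = [g for g in samples if g != baseline]
    if not others:
        raise ValueError("need at least one non-baseline group")
    arrays = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    ns = {g: a.size for g, a in arrays.items()}
    if min(ns.values()) < 2:
        raise ValueError("every group needs n >= 2")
    k = len(arrays)
    n_total = sum(ns.values())
    df = n_total - k
    ss_within = sum(float(np.sum((a - a.mean()) ** 2))
                    for a in arrays.values())
    s2 = ss_within / df
    if s2 <= 0:
        raise ValueError("zero pooled within-group variance")

    x0 = arrays[baseline].mean()
    n0 = ns[baseline]
    tstats = np.array([
        (arrays[g].mean() - x0) / np.sqrt(s2 * (1.0 / ns[g] + 1.0 / n0))
        for g in others])

    rng = np.random.default_rng(seed)
    # null: group means ~ N(0, 1/n_g), pooled sd ~ sqrt(chi2_df / df)
    m0 = rng.normal(0.0, np.sqrt(1.0 / n0), n_draws)
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    max_abs_t = np.zeros(n_draws)
    for g in others:
        mg = rng.normal(0.0, np.sqrt(1.0 / ns[g]), n_draws)
        tg = (mg - m0) / (s * np.sqrt(1.0 / ns[g] + 1.0 / n0))
        np.maximum(max_abs_t, np.abs(tg), out=max_abs_t)
    crit = float(np.quantile(max_abs_t, 0.95))
    pvals = np.array([(np.count_nonzero(max_abs_t >= abs(t)) + 1)
                      / (n_draws + 1) for t in tstats])
    return DunnettResult(baseline=baseline, groups=others,
                         statistics=tstats, pvalues=pvals,
                         critical_value=crit, n_draws=n_draws)


def group_compare(table: pd.DataFrame, value_col: str = "strain",
                  group_col: str = "group", *, baseline: str | None = None,
                  seed: int | None = None,
                  n_draws: int = DEFAULT_MC_DRAWS) -> GroupComparison:
    """One-way group comparison: ANOVA, Kruskal-Wallis, Tukey, Dunnett.

    ``baseline`` enables Dunnett's many-to-one test against that group.
    With zero within-group variance everywhere the parametric tests are
    degenerate: a warning is recorded and only the rank test is run.
    """
    groups = list(pd.unique(table[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: table.loc[table[group_col] == g, value_col].to_numpy(float)
               for g in groups}
    sizes = {g: v.size for g, v in samples.items()}
    if min(sizes.values()) < 2:
        raise ValueError("every group needs n >= 2")

    notes: list[str] = []
    all_tied = all(np.ptp(v) == 0 for v in samples.values())
    if all_tied:
        notes.append("zero within-group variance in all groups; "
                     "parametric tests skipped (exact ties)")
        anova_f = anova_p = np.nan
        tukey_df = None
        dn = None
    else:
        anova_f, anova_p = sps.f_oneway(*samples.values())
        res = pairwise_tukeyhsd(table[value_col].to_numpy(float),
                                table[group_col].to_numpy(str))
        tukey_df = pd.DataFrame(res.summary().data[1:],
                                columns=res.summary().data[0])
        dn = (dunnett_mc(samples, baseline, n_draws=n_draws, seed=seed)
              if baseline is not None else None)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kw_h, kw_p = sps.kruskal(*samples.values())
    except ValueError:
        # all observations identical across every group
        kw_h, kw_p = 0.0, 1.0
        notes.append("all observations identical; H set to 0")
    return GroupComparison(groups=[str(g) for g in groups],
                           group_sizes={str(g): sizes[g] for g in groups},
                           anova_f=float(anova_f), anova_p=float(anova_p),
                           kruskal_h=float(kw_h), kruskal_p=float(kw_p),
                           tukey=tukey_df, dunnett=dn, warnings=notes)


def turning_point(table: pd.DataFrame, value_col: str = "strain",
                  age_col: str = "age", *, baseline: float | None = None,
                  alpha: float = 0.05, seed: int | None = None,
                  n_draws: int = DEFAULT_MC_DRAWS) -> float | None:
    """Earliest age whose Dunnett contrast with the youngest group is
    significant.

    Ages are sorted ascending; the baseline defaults to the youngest.
    Returns None when no age group differs significantly.
    """
    ages = np.sort(pd.unique(table[age_col]))
    if ages.size < 3:
        raise ValueError("need at least 3 age groups")
    if baseline is None:
        baseline = ages[0]
    samples = {float(a): table.loc[table[age_col] == a,
                                   value_col].to_numpy(float)
               for a in ages}
    res = dunnett_mc(samples, float(baseline), n_draws=n_draws, seed=seed)
    sig = res.significant(alpha)
    for age, is_sig in sorted(zip(res.groups, sig)):
        if is_sig:
            return float(age)
    return None
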
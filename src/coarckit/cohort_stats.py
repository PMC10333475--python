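"""Group-comparison statistics for arch-morphometry cohorts.

Reproduces the clinical-table workflow: Kolmogorov-Smirnov normality and
Levene variance screens, two-group t tests (Student or Welch, chosen by the
variance screen), one-way ANOVA — including ANOVA computed directly from
published (mean, SEM, n) summary triplets — Pearson's chi-square for
categorical rows, and assembly of a three-group summary table.

A note on the summary path: published tables often label the +/- column
"M +/- SD" while actually printing the standard error of the mean. The
summary ANOVA here takes the column as SEM and recovers the within-group SD
as sem * sqrt(n); this is the interpretation under which the printed F
statistics of the source table reproduce.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class SummaryTriplet:
    """One (mean, SEM, n) cell of a summary table."""

    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("summary ANOVA needs n >= 2 per group")
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass
class TestResult:
    statistic: float
    df: tuple | float
    p_value: float
    method: str
    group: str | None = None

    def __post_init__(self):
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def anova_from_summary(groups: list[SummaryTriplet]) -> TestResult:
    """One-way fixed-effects ANOVA from per-group (mean, SEM, n) triplets.

    F = [sum n_i (m_i - m)^2 / (k-1)] / [sum (n_i - 1) sd_i^2 / (N-k)]
    with sd_i = sem_i * sqrt(n_i); identical to raw-data ANOVA whenever the
    triplets are computed from the raw data.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = np.array([g.n for g in groups], float)
    m = np.array([g.mean for g in groups], float)
    sd = np.array([g.sd for g in groups], float)
    N, k = n.sum(), len(groups)
    grand = float((n * m).sum() / N)
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * sd**2).sum())
    df = (k - 1, int(N - k))
    F = (ssb / df[0]) / (ssw / df[1])
    return TestResult(F, df, float(stats.f.sf(F, *df)), "anova_summary")


def welch_anova(samples) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA on raw samples."""
    n = np.array([len(x) for x in samples], float)
    m = np.array([np.mean(x) for x in samples])
    v = np.array([np.var(x, ddof=1) for x in samples])
    w = n / v
    mw = float((w * m).sum() / w.sum())
    k = len(samples)
    a = float((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = float((((1 - w / w.sum()) ** 2) / (n - 1)).sum())
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    F = a / b
    df2 = (k**2 - 1) / (3.0 * lam)
    return TestResult(F, (k - 1, df2), float(stats.f.sf(F, k - 1, df2)), "anova_welch")


def group_tests(samples, labels=None, alpha: float = ALPHA) -> list[TestResult]:
    """Normality + variance screens, then the appropriate location test.

    Per group: KS normality against a Normal with the sample's own mean/SD
    (the Lilliefors caveat — estimated parameters make the test mildly
    conservative — applies). Levene (center = mean) across groups; the
    omnibus test is pooled-variance (Student t / classic ANOVA) when Levene
    does not reject at ``alpha``, Welch otherwise.
    """
    samples = [np.asarray(x, float) for x in samples]
    if len(samples) < 2 or any(len(x) < 2 for x in samples):
        raise ValueError("need >= 2 groups with n >= 2 each")
    labels = labels or [f"group{i}" for i in range(len(samples))]
    for lab, x in zip(labels, samples):
        if np.var(x, ddof=1) == 0:
            raise ValueError(f"group '{lab}' is constant; variance tests undefined")
    out = []
    for lab, x in zip(labels, samples):
        ks = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        out.append(TestResult(float(ks.statistic), len(x), float(ks.pvalue),
                              "ks_normality", group=lab))
    lev = stats.levene(*samples, center="mean")
    out.append(TestResult(float(lev.statistic),
                          (len(samples) - 1, sum(map(len, samples)) - len(samples)),
                          float(lev.pvalue), "levene"))
    equal_var = lev.pvalue >= alpha
    if len(samples) == 2:
        t = stats.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        out.append(TestResult(float(t.statistic), float(t.df), float(t.pvalue),
                              "t_student" if equal_var else "t_welch"))
    elif equal_var:
        F, p = stats.f_oneway(*samples)
        k, N = len(samples), sum(map(len, samples))
        out.append(TestResult(float(F), (k - 1, N - k), float(p), "anova_raw"))
    else:
        out.append(welch_anova(samples))
    return out


def chi_square(counts) -> TestResult:
    """Pearson's chi-square for an R x C contingency table (no correction)."""
    obs = np.asarray(counts, float)
    if obs.ndim != 2 or np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("counts must be a non-negative 2-D table with positive total")
    row, col = obs.sum(axis=1), obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("contingency table has a zero margin")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(chi2, df, float(stats.chi2.sf(chi2, df)), "chi_square")


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def group_percentages(ns) -> list[float]:
    """Group shares of the cohort, percent at one decimal."""
    total = sum(ns)
    return [round(100.0 * n / total, 1) for n in ns]


def build_group_table(df: pd.DataFrame, group_col: str = "group",
                 numeric=None, categorical=(), order=None) -> pd.DataFrame:
    """Three-group summary table: mean +/- SEM per group plus the group test.

    Numeric variables get per-group mean/SEM cells and a one-way ANOVA F
    (pooled, via :func:`anova_from_summary` on the per-group summaries,
    equivalent to raw ANOVA); binary categorical variables get count (%)
    cells and Pearson's chi-square. With a single group only the summary
    cells are produced.
    """
    groups = order or list(dict.fromkeys(df[group_col]))
    if any((df[group_col] == g).sum() == 0 for g in groups):
        raise ValueError("empty group in cohort table")
    numeric = numeric if numeric is not None else [
        c for c in df.columns
        if c != group_col and c not in categorical and np.issubdtype(df[c].dtype, np.number)]
    rows = []
    ns = [(df[group_col] == g).sum() for g in groups]
    rows.append({"variable": "n (%)",
                 **{g: f"{n} ({p}%)" for g, n, p in zip(groups, ns, group_percentages(ns))},
                 "statistic": np.nan, "p_value": np.nan, "method": ""})
    for var in numeric:
        cells, trips = {}, []
        for g in groups:
            x = df.loc[df[group_col] == g, var].to_numpy(float)
            sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
            cells[g] = f"{np.mean(x):.4g} ± {sem:.4g}"
            if len(x) > 1:
                trips.append(SummaryTriplet(float(np.mean(x)), sem, len(x)))
        if len(groups) > 1:
            res = anova_from_summary(trips)
            rows.append({"variable": var, **cells, "statistic": res.statistic,
                         "p_value": res.p_value, "method": res.method})
        else:
            rows.append({"variable": var, **cells, "statistic": np.nan,
                         "p_value": np.nan, "method": ""})
    for var in categorical:
        counts = np.array([[int(df.loc[df[group_col] == g, var].sum()),
                            int((df[group_col] == g).sum() - df.loc[df[group_col] == g, var].sum())]
                           for g in groups]).T
        cells = {g: f"{counts[0, i]} ({100.0 * counts[0, i] / ns[i]:.1f}%)"
                 for i, g in enumerate(groups)}
        if len(groups) > 1:
            res = chi_square(counts)
            rows.append({"variable": var, **cells, "statistic": res.statistic,
                         "p_value": res.p_value, "method": res.method})
        else:
            rows.append({"variable": var, **cells, "statistic": np.nan,
                         "p_value": np.nan, "method": ""})
    return pd.DataFrame(rows)
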
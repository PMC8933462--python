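"""Repeated-measures statistics for the signal-strength experiment.

Each metric is an n-subjects x 3-conditions paired matrix (no filter,
OD 0.3, OD 0.6).  Metrics that look normal in every condition
(Shapiro-Wilk p > 0.05) go through one-way repeated-measures ANOVA with
Bonferroni-corrected pairwise paired t-tests; otherwise the Friedman test
with Bonferroni-corrected Wilcoxon signed-rank pairwise tests.  The
device-reported signal strength is discrete and typically routes
nonparametric; the flow metrics typically route parametric.  Associations
between signal strength and each flow metric are Pearson correlations with
ordinary least-squares regression lines, pooling the per-subject condition
means.

The Wilcoxon test drops zero differences (classic convention), uses
mid-ranks for tied magnitudes, and is exact (full sign-assignment
distribution via dynamic programming) up to n = 25; the Friedman statistic
carries the standard tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedMatrix",
    "StatResult",
    "NormalityResult",
    "normality_check",
    "friedman_test",
    "wilcoxon_signed_rank",
    "rm_anova",
    "bonferroni",
    "pearson_with_regression",
    "analyze_cohort",
    "CohortAnalysis",
]

ALPHA = 0.05
_PAIRS = ((0, 1), (1, 2), (0, 2))


@dataclass(frozen=True)
class PairedMatrix:
    """n_subjects x k_conditions matrix of one metric on one device."""

    values: np.ndarray
    metric: str = ""
    device: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("PairedMatrix requires a 2-D array")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need n >= 2 subjects and k >= 2 conditions")
        if not np.isfinite(v).all():
            raise ValueError("PairedMatrix has missing or non-finite cells")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    pairwise: List[Tuple[Tuple[int, int], float, float]] = field(
        default_factory=list)  # (pair, raw p, Bonferroni-adjusted p)
    note: str = ""


@dataclass
class NormalityResult:
    shapiro_p: float
    ks_p: float
    is_normal: bool
    note: str = ""


def normality_check(x: Sequence[float]) -> NormalityResult:
    """Shapiro-Wilk and Lilliefors-corrected Kolmogorov-Smirnov normality.

    ``is_normal`` is True iff the Shapiro-Wilk p-value exceeds 0.05; a
    constant sample is flagged non-normal with a degeneracy note.
    """
    a = np.asarray(x, dtype=float)
    if a.size < 3:
        raise ValueError("normality testing needs n >= 3")
    if np.ptp(a) == 0.0:
        return NormalityResult(np.nan, np.nan, False,
                               note="constant sample; normality undefined")
    shapiro_p = float(sps.shapiro(a).pvalue)
    if a.size >= 4:
        from statsmodels.stats.diagnostic import lilliefors
        ks_p = float(lilliefors(a, dist="norm")[1])
    else:
        ks_p = float("nan")
    return NormalityResult(shapiro_p, ks_p, shapiro_p > ALPHA)


def friedman_test(m: PairedMatrix) -> StatResult:
    """Friedman rank test across conditions with the standard tie correction.

    Within-subject mid-ranks r_ij give

        Q = n^2 (k-1) * sum_j (Rbar_j - rbar)^2 / sum_ij (r_ij - rbar)^2

    which reduces to the classic 12n/(k(k+1)) sum (Rbar_j-(k+1)/2)^2 when
    there are no ties; p from chi-squared with k-1 df.
    """
    v = m.values
    n, k = v.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, v)
    rbar = (k + 1) / 2.0
    col_means = ranks.mean(axis=0)
    denom = float(((ranks - rbar) ** 2).sum())
    if denom == 0.0:
        return StatResult("friedman", 0.0, 1.0,
                          note="all within-subject ranks tied")
    q = n * n * (k - 1) * float(((col_means - rbar) ** 2).sum()) / denom
    p = float(sps.chi2.sf(q, k - 1))
    return StatResult("friedman", q, p)


def _wilcoxon_exact_cdf(ranks2: np.ndarray, w2: float) -> float:
    """P(W+ <= w) for signed-rank sums, ranks doubled to stay integral."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    return float(dist[: int(round(w2)) + 1].sum())


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied magnitudes share mid-ranks.  The
    statistic is W = min(W+, W-).  Exact p for n <= 25 (enumeration of the
    sign-assignment distribution), else a normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return StatResult("wilcoxon", 0.0, 1.0,
                          note="all differences zero; test degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 25:
        # mid-ranks are multiples of 1/2: double them to enumerate exactly
        p = min(1.0, 2.0 * _wilcoxon_exact_cdf(np.round(2 * ranks), 2 * w))
        return StatResult("wilcoxon", w, p)
    mean = n * (n + 1) / 4.0
    tie_counts = np.unique(np.abs(d), return_counts=True)[1]
    var = (n * (n + 1) * (2 * n + 1) / 24.0
           - float(((tie_counts ** 3 - tie_counts) / 48.0).sum()))
    z = (w - mean + 0.5) / np.sqrt(var)
    return StatResult("wilcoxon", w, float(2.0 * sps.norm.sf(abs(z))),
                      note="normal approximation")


def rm_anova(m: PairedMatrix) -> StatResult:
    """One-way repeated-measures ANOVA with Bonferroni paired t post-hocs.

    Total sum of squares is partitioned into subjects, conditions and
    error; F = MS_conditions / MS_error on (k-1, (n-1)(k-1)) df.
    """
    v = m.values
    n, k = v.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs n >= 3")
    grand = v.mean()
    ss_subj = k * float(((v.mean(axis=1) - grand) ** 2).sum())
    ss_cond = n * float(((v.mean(axis=0) - grand) ** 2).sum())
    ss_tot = float(((v - grand) ** 2).sum())
    ss_err = ss_tot - ss_subj - ss_cond
    # guard against catastrophic cancellation on degenerate inputs
    tiny = 1e-12 * (ss_tot + 1e-300)
    if ss_cond < tiny:
        ss_cond = 0.0
    if ss_err < tiny:
        ss_err = 0.0
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        if ms_cond <= 0:
            result = StatResult("rm_anova", 0.0, 1.0,
                                note="zero variance everywhere")
        else:
            result = StatResult("rm_anova", float("inf"), 0.0,
                                note="zero error variance; F unbounded")
    else:
        f = ms_cond / ms_err
        result = StatResult("rm_anova", f, float(sps.f.sf(f, df_cond, df_err)))
    if k == 3:
        raws = []
        for i, j in _PAIRS:
            di = v[:, i] - v[:, j]
            if np.ptp(di) == 0.0:
                # zero-variance difference: identical (p=1) or shifted (p=0)
                raws.append(1.0 if di[0] == 0.0 else 0.0)
            else:
                raws.append(float(sps.ttest_rel(v[:, i], v[:, j]).pvalue))
        adj = bonferroni(raws, 3)
        result.pairwise = [(_PAIRS[i], raws[i], adj[i]) for i in range(3)]
    return result


def bonferroni(ps: Sequence[float], m: int) -> List[float]:
    """Bonferroni adjustment: p -> min(1, p * m)."""
    ps = list(ps)
    if m < len(ps):
        raise ValueError("m must be at least the number of p-values")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in ps]


def pearson_with_regression(ss: Sequence[float], metric: Sequence[float]
                            ) -> Tuple[float, float, float, float]:
    """Pearson r (two-sided p) and OLS slope/intercept of metric on SS."""
    x = np.asarray(ss, dtype=float)
    y = np.asarray(metric, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    return float(r), float(p), float(reg.slope), float(reg.intercept)


# ---------------------------------------------------------------------------
# cohort-level orchestration

_METRIC_COLUMNS = (
    ("SCP", "vd_pct"), ("SCP", "vld_pct"),
    ("DCP", "vd_pct"), ("DCP", "vld_pct"),
    ("CC", "ccfd_pct"),
)


@dataclass
class CohortAnalysis:
    """Omnibus/pairwise tests per metric plus the SS-correlation table."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    results: Dict[Tuple[str, str, str], StatResult]


def _paired_matrix(df: pd.DataFrame, device: str, slab: str, column: str,
                   conditions: Sequence[float]) -> PairedMatrix:
    sub = df[(df["device_model"] == device) & (df["slab"] == slab)]
    wide = sub.pivot(index="subject", columns="od", values=column)
    wide = wide[list(conditions)].dropna()
    return PairedMatrix(wide.to_numpy(), metric=f"{slab}:{column}",
                        device=device)


def _route(m: PairedMatrix) -> StatResult:
    """Nonparametric path iff Shapiro-Wilk flags any condition non-normal."""
    normal = all(normality_check(m.values[:, j]).is_normal
                 for j in range(m.k))
    if normal:
        return rm_anova(m)
    res = friedman_test(m)
    raws = []
    for i, j in _PAIRS:
        raws.append(wilcoxon_signed_rank(m.values[:, i], m.values[:, j]).p_value)
    adj = bonferroni(raws, 3)
    res.pairwise = [(_PAIRS[i], raws[i], adj[i]) for i in range(3)]
    return res


def analyze_cohort(table: pd.DataFrame,
                   conditions: Sequence[float] = (0.0, 0.3, 0.6)
                   ) -> CohortAnalysis:
    """Run the full statistical stage on a cohort table of condition means.

    ``table`` must have one row per (subject, device_model, od, slab) with
    columns vd_pct, vld_pct, ccfd_pct and signal_strength (3-scan means).
    Produces a summary shaped like a per-condition mean +/- SD table with
    omnibus and Bonferroni pairwise p-values, and a correlation table with
    one Pearson r per (device, slab, metric) pooled across conditions.
    """
    required = {"subject", "device_model", "od", "slab", "signal_strength"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    devices = sorted(table["device_model"].unique())
    results: Dict[Tuple[str, str, str], StatResult] = {}
    rows1 = []
    for device in devices:
        # device-reported signal strength (one value per scan; stored per
        # slab row, identical across slabs -> take the SCP rows)
        ss_m = _paired_matrix(table, device, "SCP", "signal_strength",
                              conditions)
        res = _route(ss_m)
        results[(device, "SS", "signal_strength")] = res
        rows1.append(_summary_row(device, "SS", "signal_strength", ss_m,
                                  conditions, res))
        for slab, column in _METRIC_COLUMNS:
            m = _paired_matrix(table, device, slab, column, conditions)
            res = _route(m)
            results[(device, slab, column)] = res
            rows1.append(_summary_row(device, slab, column, m, conditions, res))
    table1 = pd.DataFrame(rows1)

    rows2 = []
    for device in devices:
        ss_vals = _paired_matrix(table, device, "SCP", "signal_strength",
                                 conditions).values.ravel()
        for slab, column in _METRIC_COLUMNS:
            m = _paired_matrix(table, device, slab, column, conditions)
            try:
                r, p, slope, intercept = pearson_with_regression(
                    ss_vals, m.values.ravel())
            except ValueError:  # degenerate (constant) metric or SS
                r = p = slope = intercept = float("nan")
            rows2.append({"device_model": device, "slab": slab,
                          "metric": column, "r": r, "p_value": p,
                          "slope": slope, "intercept": intercept})
    table2 = pd.DataFrame(rows2)
    return CohortAnalysis(table1=table1, table2=table2, results=results)


def _summary_row(device, slab, column, m: PairedMatrix, conditions, res):
    row = {"device_model": device, "slab": slab, "metric": column,
           "test": res.test, "omnibus_p": res.p_value}
    for j, od in enumerate(conditions):
        col = m.values[:, j]
        row[f"mean_od{od}"] = float(col.mean())
        row[f"sd_od{od}"] = float(col.std(ddof=1))
    for (pair, raw, adj) in res.pairwise:
        row[f"p_{pair[0]}v{pair[1]}_adj"] = adj
    return row
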
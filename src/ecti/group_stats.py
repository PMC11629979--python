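"""Cohort-level statistics: CV ablation and the hypothesis-test battery.

The ablation compares the variability (coefficient of variation over the 10
images of each SC tape) of KDE-based densities (ECTI) against whole-image
densities (DTI), per severity group. The test battery mirrors the study
design: Shapiro-Wilk normality per group, Wilcoxon signed-rank for paired
lesional/nonlesional tapes of the same patient (G1-G3), and Wilcoxon
rank-sum for nonlesional severity groups against healthy controls (G4).

Both Wilcoxon tests compute exact two-sided p-values from the full null
distribution (dynamic programming over sign flips / rank subsets, average
ranks doubled to stay integral) for small samples, falling back to the
normal approximation with tie correction otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import EmptyInputError, ParameterError

__all__ = [
    "TestReport",
    "CvSummary",
    "GROUPS",
    "sample_cv",
    "group_mean_cv",
    "cv_summary",
    "cv_reduction_pct",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "run_group_analysis",
    "validate_cohort_table",
]

logger = logging.getLogger(__name__)

GROUPS = ("G1", "G2", "G3", "G4")

REQUIRED_COLUMNS = ("sample_id", "group", "lesional", "image_index", "density", "method")


def significance_band(p: float) -> str:
    """ns / * (p <= 0.05) / ** (p <= 0.01)."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class TestReport:
    """One hypothesis test outcome with its significance band."""

    label: str
    test: str  # shapiro_wilk | wilcoxon_signed_rank | wilcoxon_rank_sum
    statistic: float
    p_value: float
    n: int
    n_pairs: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def band(self) -> str:
        return significance_band(self.p_value)


@dataclass
class CvSummary:
    """Per-tape CVs and per-group mean CVs for one density method."""

    per_sample_cv: dict[tuple[str, bool], float]
    group_mean_cv: dict[str, float]
    method: str


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the CohortTable contract; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"cohort table missing columns {missing}")
    if (table["density"] < 0).any():
        raise ParameterError("densities must be >= 0")
    bad_groups = set(table["group"]) - set(GROUPS)
    if bad_groups:
        raise ParameterError(f"unknown groups {sorted(bad_groups)}")
    if (table.loc[table["group"] == "G4", "lesional"]).any():
        raise ParameterError("G4 (healthy controls) must be nonlesional only")
    dup = table.duplicated(subset=["sample_id", "lesional", "image_index", "method"])
    if dup.any():
        raise ParameterError("duplicate (sample_id, lesional, image_index, method) rows")
    return table


def sample_cv(densities) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) / mean."""
    x = np.asarray(densities, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ParameterError("sample_cv needs >= 2 finite values")
    mean = x.mean()
    if mean <= 0:
        raise ParameterError("sample_cv requires a positive mean")
    return float(x.std(ddof=1) / mean)


def group_mean_cv(table: pd.DataFrame, method: str, group: str) -> float:
    """Arithmetic mean of the per-tape CVs of a severity group.

    Tapes with fewer than 2 density estimates are excluded with a warning
    (the missing-data exclusion rule).
    """
    sub = table[(table["method"] == method) & (table["group"] == group)]
    if sub.empty:
        raise EmptyInputError(f"no rows for method={method!r} group={group!r}")
    cvs = []
    for (sid, les), tape in sub.groupby(["sample_id", "lesional"]):
        if len(tape) < 2:
            logger.warning("tape (%s, lesional=%s) has <2 estimates; excluded from CV", sid, les)
            continue
        cvs.append(sample_cv(tape["density"].to_numpy()))
    if not cvs:
        raise EmptyInputError(f"no tape in {group} has >= 2 estimates")
    return float(np.mean(cvs))


def cv_summary(table: pd.DataFrame, method: str) -> CvSummary:
    """Per-tape and group-mean CVs for one method across all groups present."""
    sub = table[table["method"] == method]
    per_sample: dict[tuple[str, bool], float] = {}
    for (sid, les), tape in sub.groupby(["sample_id", "lesional"]):
        if len(tape) >= 2:
            per_sample[(sid, bool(les))] = sample_cv(tape["density"].to_numpy())
    groups = {}
    for g in sorted(sub["group"].unique()):
        groups[g] = group_mean_cv(table, method, g)
    return CvSummary(per_sample_cv=per_sample, group_mean_cv=groups, method=method)


def cv_reduction_pct(cv_without: float, cv_with: float) -> float:
    """Percent CV reduction from applying KDE; negative means an increase."""
    if cv_without <= 0:
        raise ParameterError("cv_without must be > 0")
    return 100.0 * (cv_without - cv_with) / cv_without


def shapiro_wilk(x, label: str = "") -> TestReport:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ParameterError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    res = sps.shapiro(x)
    return TestReport(label=label, test="shapiro_wilk",
                      statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=int(x.size))


def _doubled_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks multiplied by 2, so ties stay integral."""
    r2 = np.rint(2.0 * sps.rankdata(values)).astype(int)
    return r2


def _two_sided_from_cdf(cdf_le: float, cdf_ge: float) -> float:
    return float(min(1.0, 2.0 * min(cdf_le, cdf_ge)))


def _signed_rank_exact_p(r2: np.ndarray, w2_plus: int) -> float:
    """Exact two-sided p for the signed-rank statistic via sign-flip DP."""
    total = int(r2.sum())
    # coefficient c[s] = number of sign assignments with doubled W+ == s
    c = np.zeros(total + 1)
    c[0] = 1.0
    for r in r2:
        c[r:] = c[r:] + c[:total + 1 - r]
    n_assign = 2.0 ** len(r2)
    cdf_le = c[: w2_plus + 1].sum() / n_assign
    cdf_ge = c[w2_plus:].sum() / n_assign
    return _two_sided_from_cdf(cdf_le, cdf_ge)


def wilcoxon_signed_rank(paired_a, paired_b, label: str = "",
                         exact_max_n: int = 25) -> TestReport:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon convention); with all differences
    zero the test degenerates to p = 1. Exact p from the full sign-flip null
    distribution when the nonzero-pair count is <= ``exact_max_n``, else the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n_pairs = int(len(a))
    n = int(d.size)
    if n == 0:
        logger.warning("all paired differences are zero; degenerate signed-rank test")
        return TestReport(label=label, test="wilcoxon_signed_rank", statistic=0.0,
                          p_value=1.0, n=0, n_pairs=n_pairs)
    r2 = _doubled_ranks(np.abs(d))
    w2_plus = int(r2[d > 0].sum())
    w2_minus = int(r2.sum()) - w2_plus
    statistic = min(w2_plus, w2_minus) / 2.0
    if n <= exact_max_n:
        p = _signed_rank_exact_p(r2, w2_plus)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = (counts.astype(float) ** 3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        w_plus = w2_plus / 2.0
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestReport(label=label, test="wilcoxon_signed_rank", statistic=statistic,
                      p_value=p, n=n, n_pairs=n_pairs)


def _rank_sum_exact_p(r2: np.ndarray, n_x: int, s2_x: int) -> float:
    """Exact two-sided p for the rank-sum statistic via subset-count DP."""
    total = int(r2.sum())
    # c[k, s] = number of k-subsets of the pooled doubled ranks summing to s
    c = np.zeros((n_x + 1, total + 1))
    c[0, 0] = 1.0
    for r in r2:
        c[1:, r:] = c[1:, r:] + c[:-1, : total + 1 - r]
    dist = c[n_x]
    n_subsets = dist.sum()
    cdf_le = dist[: s2_x + 1].sum() / n_subsets
    cdf_ge = dist[s2_x:].sum() / n_subsets
    return _two_sided_from_cdf(cdf_le, cdf_ge)


def wilcoxon_rank_sum(x, y, label: str = "", exact_max_total: int = 30) -> TestReport:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for independent samples.

    Exact p from the full permutation null of the rank-sum statistic
    (valid with ties, via average ranks) when n + m <= ``exact_max_total``,
    else the normal approximation with tie correction and continuity
    correction. The reported statistic is the Mann-Whitney U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("both samples must be nonempty")
    n_x, n_y = int(x.size), int(y.size)
    pooled = np.concatenate([x, y])
    r2 = _doubled_ranks(pooled)
    s2_x = int(r2[:n_x].sum())
    u_x = s2_x / 2.0 - n_x * (n_x + 1) / 2.0
    if n_x + n_y <= exact_max_total:
        p = _rank_sum_exact_p(r2, n_x, s2_x)
    else:
        n = n_x + n_y
        mean = n_x * (n + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts.astype(float) ** 3 - counts).sum()) / (n * (n - 1))
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
        s_x = s2_x / 2.0
        z = (s_x - mean - 0.5 * np.sign(s_x - mean)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestReport(label=label, test="wilcoxon_rank_sum", statistic=float(u_x),
                      p_value=p, n=n_x + n_y, n_pairs=None)


def run_group_analysis(table: pd.DataFrame, method: str = "ecti"
                       ) -> tuple[list[TestReport], pd.DataFrame]:
    """The full study test battery on per-tape mean densities.

    Per tape (sample x lesional status) the mean over its images is taken
    first. Then: Shapiro-Wilk per (group, status); paired signed-rank tests
    lesional vs nonlesional within G1-G3 (samples lacking either tape are
    excluded from pairing but kept elsewhere); rank-sum tests of nonlesional
    G1, G2, G3 against G4. Deterministic; row order never changes a p-value.
    """
    validate_cohort_table(table)
    sub = table[table["method"] == method]
    if sub.empty:
        raise EmptyInputError(f"no rows with method={method!r}")
    # canonical row order first, so results are bit-identical under shuffling
    sub = sub.sort_values(["group", "sample_id", "lesional", "image_index"])
    means = (sub.groupby(["group", "sample_id", "lesional"], as_index=False)["density"]
             .mean()
             .sort_values(["group", "sample_id", "lesional"])
             .reset_index(drop=True))
    reports: list[TestReport] = []

    for (g, les), chunk in means.groupby(["group", "lesional"]):
        status = "lesional" if les else "nonlesional"
        if len(chunk) >= 3:
            reports.append(shapiro_wilk(chunk["density"].to_numpy(),
                                        label=f"{g} {status} normality"))
        else:
            logger.warning("group %s %s has n=%d < 3; Shapiro-Wilk skipped", g, status, len(chunk))

    for g in ("G1", "G2", "G3"):
        gm = means[means["group"] == g]
        les = gm[gm["lesional"]].set_index("sample_id")["density"]
        non = gm[~gm["lesional"]].set_index("sample_id")["density"]
        common = sorted(set(les.index) & set(non.index))
        dropped = (set(les.index) | set(non.index)) - set(common)
        if dropped:
            logger.warning("group %s: unpaired samples excluded from paired test: %s",
                           g, sorted(dropped))
        if not common:
            logger.warning("group %s: no complete pairs; paired comparison skipped", g)
            continue
        reports.append(wilcoxon_signed_rank(
            les.loc[common].to_numpy(), non.loc[common].to_numpy(),
            label=f"{g} lesional vs nonlesional"))

    g4 = means[(means["group"] == "G4") & (~means["lesional"])]["density"].to_numpy()
    for g in ("G1", "G2", "G3"):
        gn = means[(means["group"] == g) & (~means["lesional"])]["density"].to_numpy()
        if len(gn) == 0 or len(g4) == 0:
            logger.warning("comparison %s vs G4 skipped (empty group)", g)
            continue
        reports.append(wilcoxon_rank_sum(gn, g4, label=f"{g} nonlesional vs G4"))

    return reports, means
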
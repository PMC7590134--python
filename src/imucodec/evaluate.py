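"""Benchmark harness: compression ratios, rank statistics, group tests.

Compression performance is reported as the compression ratio

    CR = size of the constant-width CSV file / size of the compressed file

so the text baseline has CR = 1 by definition. Methods are compared the
way classifiers are compared across many datasets: per-test-case ranks
(1 = highest CR) feed a Friedman omnibus test, followed by the Nemenyi
post-hoc critical difference when the omnibus rejects. Differences
between data classes (activities, body segments) for a single method
use one-way ANOVA with Tukey's HSD post hoc, which is appropriate
because per-class CR distributions are near normal even though the
pooled distribution is strongly bimodal (active vs stationary).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .container import compress_file, deflate_size, write_binary, write_fixed_csv
from .io import TestCase
from .predictors import METHOD_NAMES, predictor_from_name

ALPHA = 0.05

#: two-tailed Nemenyi critical values q_{0.05,k} (studentized range at
#: infinite df divided by sqrt(2)), k = number of compared methods
NEMENYI_Q_05 = {
    2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
    7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164,
}

BASELINE_NAMES = ("csv", "binary", "zip")


def first_order_entropy(weights: np.ndarray) -> float:
    """Shannon first-order entropy H = -sum p_i log2 p_i in bits/symbol.

    Accepts raw counts or probabilities (anything non-negative summing
    to a positive total); 0 log 0 is taken as 0.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("counts/probabilities must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("need a positive total weight")
    p = w / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def symbol_entropy(values: np.ndarray) -> float:
    """First-order entropy of an integer sequence's empirical distribution."""
    _, counts = np.unique(np.asarray(values), return_counts=True)
    return first_order_entropy(counts)


def compression_ratio(original_bytes: int, compressed_bytes: int) -> float:
    if original_bytes <= 0 or compressed_bytes <= 0:
        raise ValueError("sizes must be positive")
    return original_bytes / compressed_bytes


def bandwidth_mbps(
    rate_hz: float = 500.0, segments: int = 15, axes: int = 9, bits: int = 32
) -> float:
    """Raw streaming bandwidth of full-body kinematics in Mbit/s.

    The default arguments are the motivating full-body case: 500 Hz x
    15 segments x 9 axes x 32 bits = 2.16 Mbps, comparable to consumer
    HD video and beyond common wireless sensor links.
    """
    return rate_hz * segments * axes * bits / 1e6


# ---------------------------------------------------------------------------
# rank statistics


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    mean_ranks: pd.Series      # method -> mean rank, 1 = best
    n_cases: int


def rank_matrix(cr: pd.DataFrame) -> pd.DataFrame:
    """Per-row ranks of a (cases x methods) CR table; rank 1 = highest CR,
    ties get average ranks."""
    ranks = cr.apply(
        lambda row: stats.rankdata(-row.to_numpy(), method="average"),
        axis=1, result_type="expand",
    )
    ranks.columns = cr.columns
    return ranks


def friedman_test(cr: pd.DataFrame) -> FriedmanResult:
    """Friedman rank test over a (cases x methods) CR matrix.

    chi2_F = 12/(N k (k+1)) * sum_j R_j^2 - 3 N (k+1) with R_j the rank
    sums; the p-value comes from the chi-square distribution with k-1
    degrees of freedom. An all-tied matrix gives statistic 0, p = 1.
    """
    n, k = cr.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 cases and 2 methods")
    ranks = rank_matrix(cr)
    rank_sums = ranks.sum(axis=0).to_numpy()
    statistic = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)
    statistic = max(0.0, statistic)
    p_value = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    return FriedmanResult(statistic, p_value, ranks.mean(axis=0), n)


@dataclass(frozen=True)
class NemenyiResult:
    critical_difference: float
    significant: pd.DataFrame   # boolean method x method matrix
    mean_ranks: pd.Series


def nemenyi_posthoc(
    mean_ranks: pd.Series, n_cases: int, alpha: float = ALPHA
) -> NemenyiResult:
    """Nemenyi critical-difference comparison after a rejected Friedman test.

    CD = q_{alpha,k} * sqrt(k (k+1) / (6 N)); method pairs whose mean
    ranks differ by at least CD perform significantly differently.
    """
    if alpha != 0.05:
        raise ValueError("only the alpha = 0.05 critical-value table is embedded")
    k = len(mean_ranks)
    if k not in NEMENYI_Q_05:
        raise ValueError(f"no critical value tabulated for k={k}")
    cd = NEMENYI_Q_05[k] * math.sqrt(k * (k + 1) / (6.0 * n_cases))
    diffs = np.abs(mean_ranks.to_numpy()[:, None] - mean_ranks.to_numpy()[None, :])
    flags = pd.DataFrame(diffs >= cd, index=mean_ranks.index, columns=mean_ranks.index)
    np.fill_diagonal(flags.values, False)
    return NemenyiResult(cd, flags, mean_ranks)


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    groups: tuple[str, ...]
    tukey_p: pd.DataFrame       # pairwise p-values
    significant: pd.DataFrame   # pairwise flags at alpha


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> AnovaTukeyResult:
    """One-way ANOVA across data classes, Tukey HSD post hoc at ``alpha``."""
    names = tuple(groups)
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 classes with >= 2 observations each")
    if np.ptp(np.concatenate(arrays)) == 0:
        # identical values everywhere: F = 0 by definition, nothing to flag
        eye = pd.DataFrame(False, index=names, columns=names)
        ones = pd.DataFrame(1.0, index=names, columns=names)
        return AnovaTukeyResult(0.0, 1.0, names, ones, eye)
    f_stat, p_value = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    tukey_p = pd.DataFrame(hsd.pvalue, index=names, columns=names)
    flags = tukey_p < alpha
    np.fill_diagonal(flags.values, False)
    return AnovaTukeyResult(float(f_stat), float(p_value), names, tukey_p, flags)


# ---------------------------------------------------------------------------
# the benchmark


@dataclass
class BenchmarkReport:
    """Everything the harness measures on one corpus.

    ``cases`` holds one row per (test case, method) with byte sizes and
    CR (baselines included as pseudo-methods); ``method_summary`` the
    per-method mean and pooled CR; rank statistics cover the proposed
    predictive methods only.
    """

    cases: pd.DataFrame
    method_summary: pd.DataFrame
    cr_matrix: pd.DataFrame
    friedman: FriedmanResult | None = None
    nemenyi: NemenyiResult | None = None
    activity_anova: AnovaTukeyResult | None = None
    failures: list[str] = field(default_factory=list)

    def mean_cr(self, method: str) -> float:
        return float(self.method_summary.loc[method, "mean_cr"])


def run_benchmark(
    corpus: list[TestCase],
    methods: tuple[str, ...] = METHOD_NAMES,
    include_baselines: bool = True,
    rice_mode: str = "exhaustive",
) -> BenchmarkReport:
    """Compress every test case with every method and compile statistics.

    Per-case failures are recorded in ``report.failures`` rather than
    aborting the run. Rank statistics need at least two cases; with
    fewer, the report carries sizes only and a warning is issued.
    """
    if not corpus:
        raise ValueError("empty corpus")
    specs = {name: predictor_from_name(name) for name in methods}
    rows = []
    failures: list[str] = []
    for case in corpus:
        csv_bytes = write_fixed_csv(case.channels)
        n_csv = len(csv_bytes)
        sizes = {"csv": n_csv}
        if include_baselines:
            sizes["binary"] = len(write_binary(case.channels))
            sizes["zip"] = deflate_size(csv_bytes)
        for name, spec in specs.items():
            try:
                sizes[name] = len(compress_file(case.channels, spec, rice_mode))
            except Exception as exc:  # recorded, not fatal
                failures.append(f"{case.case_id}/{name}: {exc}")
        for name, size in sizes.items():
            rows.append(
                {
                    "case_id": case.case_id,
                    "subject": case.subject,
                    "activity": case.activity,
                    "segment": case.segment,
                    "method": name,
                    "csv_bytes": n_csv,
                    "compressed_bytes": size,
                    "cr": compression_ratio(n_csv, size),
                }
            )
    cases = pd.DataFrame(rows)
    method_summary = (
        cases.groupby("method")
        .agg(
            mean_cr=("cr", "mean"),
            pooled_cr=("compressed_bytes", lambda s: float("nan")),
            n_cases=("cr", "size"),
        )
    )
    pooled = cases.groupby("method").agg(
        total_csv=("csv_bytes", "sum"), total_comp=("compressed_bytes", "sum")
    )
    method_summary["pooled_cr"] = pooled["total_csv"] / pooled["total_comp"]

    cr_matrix = (
        cases[cases["method"].isin(methods)]
        .pivot(index="case_id", columns="method", values="cr")
        .loc[:, list(methods)]
    )
    friedman = nemenyi = activity_anova = None
    if len(cr_matrix) >= 2:
        friedman = friedman_test(cr_matrix)
        if friedman.p_value < ALPHA:
            nemenyi = nemenyi_posthoc(friedman.mean_ranks, friedman.n_cases)
        best = friedman.mean_ranks.idxmin()
        by_activity = {
            activity: sub["cr"].to_numpy()
            for activity, sub in cases[cases["method"] == best].groupby("activity")
        }
        if len(by_activity) >= 2 and all(v.size >= 2 for v in by_activity.values()):
            activity_anova = anova_tukey(by_activity)
    else:
        warnings.warn("single-case corpus: rank statistics omitted", stacklevel=2)
    return BenchmarkReport(
        cases, method_summary, cr_matrix, friedman, nemenyi, activity_anova, failures
    )
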
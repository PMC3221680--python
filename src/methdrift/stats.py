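"""Group statistics: Mann-Whitney U, normal-approximation CIs, contingency
tests, and per-locus two-group comparison.

All tests are two-sided. No multiple-testing correction is applied across
loci: each gene's P value is reported as-is, matching the per-gene reporting
convention of candidate-gene methylation studies. Confidence intervals use a
normal (z) multiplier on the sample SD and are NOT truncated at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DEFAULT_CONFIG, ThresholdConfig
from .scoring import _as_frame

__all__ = [
    "MannWhitneyResult", "mann_whitney", "mean_ci",
    "ContingencyResult", "contingency_test", "compare_groups",
]


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float  # U of the first sample
    pvalue: float
    method: str  # "exact" or "asymptotic"


def mann_whitney(a, b, method: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with midranks for ties. The p-value uses
    exact enumeration when both groups have n <= 8 and the pooled values are
    tie-free; otherwise a tie-corrected normal approximation with a signed
    continuity correction (so identical samples give p = 1, as in R's
    ``wilcox.test``). ``method`` in {"auto", "exact", "asymptotic"} overrides
    the choice; "exact" requires tie-free data.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both groups; p = 1",
                      UserWarning, stacklevel=2)
        return MannWhitneyResult(a.size * b.size / 2.0, 1.0, "degenerate")

    n1, n2 = a.size, b.size
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free data")
    use_exact = (method == "exact"
                 or (method == "auto" and n1 <= 8 and n2 <= 8 and not has_ties))
    if use_exact:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue),
                                 "exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # pragma: no cover - guarded by the ptp check above
        return MannWhitneyResult(u1, 1.0, "degenerate")
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(float(u1), float(p), "asymptotic")


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a normal-approximation confidence interval
    (mean +/- z * SD / sqrt(n)); the lower bound is not truncated at zero."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values for a confidence interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    half = sps.norm.ppf(0.5 + level / 2.0) * sd / math.sqrt(x.size)
    return m, m - half, m + half


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    test: str  # "chi_square" or "fisher"
    pvalue: float
    statistic: float | None = None


def contingency_test(counts, method: str = "auto") -> ContingencyResult:
    """Two-sided test of independence on a 2x2 (or 2xk) count table.

    For 2x2 tables, Fisher's exact test is used whenever any expected cell
    count is below 5 (the standard operationalization of "small numbers");
    otherwise the Pearson chi-square test (no continuity correction). Larger
    2xk tables always use chi-square. ``method`` in {"auto", "chi_square",
    "fisher"} overrides the choice; "fisher" requires a 2x2 table.
    """
    table = np.asarray(counts)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError(f"expected a 2xk table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.allclose(table, np.round(table)):
        raise ValueError("counts must be integers")
    table = np.round(table).astype(int)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("a row or column of the table is all zero")

    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()

    if method == "auto":
        use_fisher = table.shape == (2, 2) and (expected < 5).any()
    elif method == "fisher":
        if table.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        use_fisher = True
    elif method == "chi_square":
        use_fisher = False
    else:
        raise ValueError(f"unknown method {method!r}")

    if use_fisher:
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return ContingencyResult(table, "fisher", float(p))
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(table, "chi_square", float(p), float(chi2))


def compare_groups(matrix, meta: pd.DataFrame, grouping: str,
                   cfg: ThresholdConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-locus two-group comparison of continuous methylation.

    ``grouping`` names a metadata column that partitions the analyzed samples
    into exactly two groups; samples whose group value is missing or
    ``"not_applicable"`` (e.g. metastasis specimens when grouping primaries
    by liver-metastasis status) are excluded from the contrast.
    Each locus gets group means with CIs and a two-sided Mann-Whitney test;
    loci where either group is empty (or has < 2 values for the CI) are
    flagged and left untested.
    """
    frame = _as_frame(matrix)
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    common = [s for s in frame.index if s in meta.index]
    groups = meta.loc[common, grouping].dropna()
    groups = groups[groups != "not_applicable"]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(
            f"grouping {grouping!r} must yield exactly two groups, got {labels}")
    g0 = groups.index[groups == labels[0]]
    g1 = groups.index[groups == labels[1]]

    rows = []
    for locus in frame.columns:
        a = frame.loc[g0, locus].dropna().to_numpy()
        b = frame.loc[g1, locus].dropna().to_numpy()
        row = {"locus_id": locus, "group_a": labels[0], "group_b": labels[1],
               "n_a": a.size, "n_b": b.size}
        if a.size < 2 or b.size < 2:
            row.update({"mean_a": np.nan, "ci_a_lower": np.nan,
                        "ci_a_upper": np.nan, "mean_b": np.nan,
                        "ci_b_lower": np.nan, "ci_b_upper": np.nan,
                        "U": np.nan, "pvalue": np.nan, "flag": "too_few"})
            rows.append(row)
            continue
        ma, la, ua = mean_ci(a, cfg.ci_level)
        mb, lb, ub = mean_ci(b, cfg.ci_level)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mw = mann_whitney(a, b)
        row.update({"mean_a": ma, "ci_a_lower": la, "ci_a_upper": ua,
                    "mean_b": mb, "ci_b_lower": lb, "ci_b_upper": ub,
                    "U": mw.statistic, "pvalue": mw.pvalue, "flag": ""})
        rows.append(row)
    return pd.DataFrame(rows)
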
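"""Two-channel methylation-array (MCA microarray) processing.

Metastasis amplicons are labeled Cy5 and cohybridized against Cy3-labeled
primary-tumor amplicons. For each probe we compute the MA coordinates
A = mean log2 intensity and M = log2(Cy5/Cy3), remove the intensity-dependent
dye bias by lowess regression of M on A, average probe M values per gene, and
call a gene hypermethylated in the metastasis when its normalized log2 ratio
strictly exceeds the cutoff (1.0 by default, ~2-fold).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .config import DEFAULT_CONFIG, ThresholdConfig
from .report import fmt_percent
from .stats import ContingencyResult, contingency_test

__all__ = [
    "make_probe_table", "read_probe_table", "TwoChannelLowessNormalizer",
    "lowess_normalize", "GeneCallSet", "call_genes", "OverlapSummary",
    "overlap", "compare_call_rates",
]

MIN_PROBES = 50


def make_probe_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe intensity frame and add MA coordinates.

    Requires columns probe_id, gene_id, cy3, cy5; all intensities must be
    strictly positive. Adds A (mean log2 intensity) and M_raw (log2 Cy5/Cy3).
    """
    for col in ("probe_id", "gene_id", "cy3", "cy5"):
        if col not in df.columns:
            raise ValueError(f"probe table missing column {col!r}")
    out = df.copy()
    out["cy3"] = out["cy3"].astype(float)
    out["cy5"] = out["cy5"].astype(float)
    for chan in ("cy3", "cy5"):
        bad = out.loc[~(out[chan] > 0) | ~np.isfinite(out[chan])]
        if len(bad):
            raise ValueError(
                f"nonpositive {chan} intensity at probe "
                f"{bad['probe_id'].iloc[0]!r}")
    out["A"] = 0.5 * (np.log2(out["cy5"]) + np.log2(out["cy3"]))
    out["M_raw"] = np.log2(out["cy5"]) - np.log2(out["cy3"])
    return out


def read_probe_table(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#")
    return make_probe_table(df)


class TwoChannelLowessNormalizer(TransformerMixin, BaseEstimator):
    """Within-array lowess normalization of the MA plot.

    ``transform`` fits a locally weighted regression of M_raw on A (fraction
    ``span`` of probes per local fit, ``iterations`` robustness iterations)
    and subtracts the fitted trend: M_norm = M_raw - trend(A). Probe order is
    preserved.
    """

    def __init__(self, span: float = 0.4, iterations: int = 1):
        self.span = span
        self.iterations = iterations

    def fit(self, probes: pd.DataFrame, y=None):
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")
        if len(probes) < MIN_PROBES:
            raise ValueError(
                f"need >= {MIN_PROBES} probes for lowess normalization, "
                f"got {len(probes)}")
        if not (np.isfinite(probes["A"]).all()
                and np.isfinite(probes["M_raw"]).all()):
            raise ValueError("non-finite A or M_raw values")
        return self

    def transform(self, probes: pd.DataFrame) -> pd.DataFrame:
        self.fit(probes)
        a = probes["A"].to_numpy(dtype=float)
        m = probes["M_raw"].to_numpy(dtype=float)
        trend = sm_lowess(m, a, frac=self.span, it=self.iterations,
                          return_sorted=False)
        out = probes.copy()
        out["M_norm"] = m - trend
        return out


def lowess_normalize(probes: pd.DataFrame, span: float = 0.4,
                     iterations: int = 1) -> pd.DataFrame:
    """Functional wrapper over :class:`TwoChannelLowessNormalizer`."""
    return TwoChannelLowessNormalizer(span, iterations).transform(probes)


@dataclass
class GeneCallSet:
    """Per-sample gene-level hypermethylation calls against a declared gene
    universe."""
    sample_id: str
    universe: frozenset[str]
    gene_stats: pd.Series          # mean probe M_norm per gene with probes
    called: frozenset[str]
    n_genes_total: int             # genes in the universe with >= 1 probe
    n_hypermethylated: int
    n_no_probe: int
    percent: str


def call_genes(probes: pd.DataFrame,
               universe: Iterable[str] | None = None,
               cfg: ThresholdConfig = DEFAULT_CONFIG,
               sample_id: str = "sample",
               aggregate: str = "mean") -> GeneCallSet:
    """Aggregate normalized probe log-ratios per gene and call
    hypermethylation at a strict cutoff.

    The gene statistic is the mean of the gene's probe M_norm values
    (``aggregate="any"`` instead calls a gene when any probe exceeds the
    cutoff). Universe genes without probes are excluded from the denominator
    and reported in ``n_no_probe``.
    """
    if "M_norm" not in probes.columns:
        raise ValueError("probes must be normalized first (no M_norm column)")
    if len(probes) == 0 or probes["gene_id"].isna().any():
        raise ValueError("every probe must map to a gene")
    per_gene = probes.groupby("gene_id")["M_norm"]
    if aggregate == "mean":
        stats = per_gene.mean()
    elif aggregate == "any":
        stats = per_gene.max()
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")

    if universe is None:
        uni = frozenset(stats.index)
    else:
        uni = frozenset(universe)
        extra = set(stats.index) - uni
        if extra:
            raise ValueError(
                f"probes map to genes outside the declared universe: "
                f"{sorted(extra)[:5]}")
    measured = stats.loc[[g for g in stats.index if g in uni]]
    called = frozenset(measured.index[measured > cfg.mcam_log2_cutoff])
    n_total = len(measured)
    n_no_probe = len(uni) - n_total
    return GeneCallSet(
        sample_id=sample_id, universe=uni, gene_stats=measured,
        called=called, n_genes_total=n_total,
        n_hypermethylated=len(called), n_no_probe=n_no_probe,
        percent=fmt_percent(len(called), n_total, decimals=1),
    )


@dataclass
class OverlapSummary:
    """Venn-region counts for two or three gene call sets."""
    sample_ids: tuple[str, ...]
    region_counts: dict[str, int]
    common: frozenset[str]

    @property
    def n_common(self) -> int:
        return len(self.common)


def overlap(sets: Sequence[GeneCallSet]) -> OverlapSummary:
    """All Venn-partition region counts for 2-3 call sets over one universe.

    Region keys are membership patterns over the sample order, e.g. "110" is
    genes called in the first two samples but not the third.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap requires two or three call sets")
    universes = {s.universe for s in sets}
    if len(universes) != 1:
        raise ValueError("call sets are over different gene universes")
    members = [s.called for s in sets]
    counts: dict[str, int] = {}
    for pattern in product((1, 0), repeat=len(sets)):
        if not any(pattern):
            continue
        # intersect included sets, subtract excluded ones
        inc = [m for m, bit in zip(members, pattern) if bit]
        exc = [m for m, bit in zip(members, pattern) if not bit]
        region = frozenset.intersection(*inc)
        for m in exc:
            region = region - m
        counts["".join(map(str, pattern))] = len(region)
    common = frozenset.intersection(*members)
    return OverlapSummary(sample_ids=tuple(s.sample_id for s in sets),
                          region_counts=counts, common=common)


def compare_call_rates(set_a: GeneCallSet, set_b: GeneCallSet,
                       method: str = "auto") -> ContingencyResult:
    """Chi-square (or Fisher for small counts) on called/not-called gene
    counts between two samples on the same universe."""
    if set_a.universe != set_b.universe:
        raise ValueError("call sets are over different gene universes")
    table = [
        [set_a.n_hypermethylated, set_a.n_genes_total - set_a.n_hypermethylated],
        [set_b.n_hypermethylated, set_b.n_genes_total - set_b.n_hypermethylated],
    ]
    return contingency_test(table, method=method)
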
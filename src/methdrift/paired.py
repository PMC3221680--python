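"""Paired primary-metastasis concordance and methylation-drift calls.

Each measurement pair gets two independent labels:

* concordance — binarize both densities at the density cutoff (strict >15%
  by default); both methylated, both unmethylated, or discordant.
* drift — a meaningful change requires a greater-than-``fold_cutoff``
  (strictly more than two-fold by default) difference AND at least one of the
  two densities above the density cutoff; direction follows the larger value.

The two labels may disagree (a 20% -> 45% pair is concordantly methylated yet
an increase); they answer different questions and are reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import DEFAULT_CONFIG, ThresholdConfig
from .report import fmt_percent

__all__ = [
    "PairedCall", "classify_pair", "classify_pairs", "PairDriftClassifier",
    "PairedSummary", "summarize_pairs", "mutation_concordance",
]

CONCORDANCE_LABELS = ("concordant_methylated", "concordant_unmethylated",
                      "discordant")
DRIFT_LABELS = ("increase", "decrease", "none")


@dataclass(frozen=True)
class PairedCall:
    primary_density: float
    metastasis_density: float
    concordance: str
    drift: str
    fold: float
    patient_id: str | None = None
    locus_id: str | None = None


def _fold(a: float, b: float) -> float:
    lo, hi = min(a, b), max(a, b)
    if hi == 0:
        return 1.0  # both zero: no change
    if lo == 0:
        return math.inf
    return hi / lo


def classify_pair(primary_density: float, metastasis_density: float,
                  cfg: ThresholdConfig = DEFAULT_CONFIG,
                  patient_id: str | None = None,
                  locus_id: str | None = None) -> PairedCall:
    """Classify one primary-metastasis measurement pair.

    Raises on missing input; callers should pre-filter with
    :func:`methdrift.cohort.enumerate_measurement_pairs`.
    """
    for name, v in (("primary", primary_density),
                    ("metastasis", metastasis_density)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing {name} density; pre-filter pairs first")
        if not 0 <= v <= 100:
            raise ValueError(f"{name} density {v!r} outside [0, 100]")

    p, m = float(primary_density), float(metastasis_density)
    p_meth = p > cfg.density_cutoff
    m_meth = m > cfg.density_cutoff
    if p_meth and m_meth:
        concordance = "concordant_methylated"
    elif not p_meth and not m_meth:
        concordance = "concordant_unmethylated"
    else:
        concordance = "discordant"

    fold = _fold(p, m)
    if fold > cfg.fold_cutoff and max(p, m) > cfg.density_cutoff:
        drift = "increase" if m > p else "decrease"
    else:
        drift = "none"
    return PairedCall(p, m, concordance, drift, fold,
                      patient_id=patient_id, locus_id=locus_id)


def classify_pairs(records: pd.DataFrame,
                   cfg: ThresholdConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Vectorized :func:`classify_pair` over an enumeration record frame
    (columns patient_id, locus_id, primary_value, metastasis_value)."""
    calls = [classify_pair(r.primary_value, r.metastasis_value, cfg,
                           patient_id=r.patient_id, locus_id=r.locus_id)
             for r in records.itertuples()]
    return pd.DataFrame({
        "patient_id": [c.patient_id for c in calls],
        "locus_id": [c.locus_id for c in calls],
        "primary_density": [c.primary_density for c in calls],
        "metastasis_density": [c.metastasis_density for c in calls],
        "concordance": [c.concordance for c in calls],
        "drift": [c.drift for c in calls],
        "fold": [c.fold for c in calls],
    })


class PairDriftClassifier(BaseEstimator):
    """Estimator facade over the pair rules: ``predict`` maps an (n, 2)
    array of (primary, metastasis) densities to drift labels."""

    def __init__(self, density_cutoff: float = 15.0, fold_cutoff: float = 2.0):
        self.density_cutoff = density_cutoff
        self.fold_cutoff = fold_cutoff

    def _cfg(self) -> ThresholdConfig:
        return ThresholdConfig(density_cutoff=self.density_cutoff,
                               fold_cutoff=self.fold_cutoff)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (primary, metastasis)")
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        self.fit(X)
        cfg = self._cfg()
        X = np.asarray(X, dtype=float)
        return np.array([classify_pair(p, m, cfg).drift for p, m in X])

    def concordance(self, X) -> np.ndarray:
        self.fit(X)
        cfg = self._cfg()
        X = np.asarray(X, dtype=float)
        return np.array([classify_pair(p, m, cfg).concordance for p, m in X])


@dataclass
class PairedSummary:
    """Cohort-level counts over classified measurement pairs."""
    n_pairs_total: int
    n_concordant: int
    n_concordant_methylated: int
    n_concordant_unmethylated: int
    n_discordant: int
    n_increase: int
    n_decrease: int
    per_locus: pd.DataFrame
    percentages: dict[str, str] = field(default_factory=dict)


def summarize_pairs(calls: pd.DataFrame) -> PairedSummary:
    """Count concordance and drift categories over classified pairs and
    format percentages (denominator = total measurement pairs)."""
    if len(calls) == 0:
        raise ValueError("no measurement pairs to summarize")
    n = len(calls)
    cm = int((calls["concordance"] == "concordant_methylated").sum())
    cu = int((calls["concordance"] == "concordant_unmethylated").sum())
    d = int((calls["concordance"] == "discordant").sum())
    inc = int((calls["drift"] == "increase").sum())
    dec = int((calls["drift"] == "decrease").sum())
    per_locus = (calls.groupby("locus_id", dropna=False)
                 .agg(n_pairs=("concordance", "size"),
                      n_concordant_methylated=("concordance",
                                               lambda s: int((s == "concordant_methylated").sum())),
                      n_concordant_unmethylated=("concordance",
                                                 lambda s: int((s == "concordant_unmethylated").sum())),
                      n_discordant=("concordance",
                                    lambda s: int((s == "discordant").sum())),
                      n_increase=("drift", lambda s: int((s == "increase").sum())),
                      n_decrease=("drift", lambda s: int((s == "decrease").sum())))
                 .reset_index())
    pct = {
        "concordant": fmt_percent(cm + cu, n),
        "concordant_methylated": fmt_percent(cm, n),
        "concordant_unmethylated": fmt_percent(cu, n),
        "discordant": fmt_percent(d, n),
        "increase": fmt_percent(inc, n),
        "decrease": fmt_percent(dec, n),
    }
    return PairedSummary(n_pairs_total=n, n_concordant=cm + cu,
                         n_concordant_methylated=cm,
                         n_concordant_unmethylated=cu, n_discordant=d,
                         n_increase=inc, n_decrease=dec,
                         per_locus=per_locus, percentages=pct)


def mutation_concordance(mut: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mutation concordance across matched pairs.

    ``mut`` is long-format (sample_id, gene, status); ``pairs`` comes from
    :func:`methdrift.cohort.pair_samples`. The discordance denominator is the
    number of pairs with a mutation in at least one member; pairs with a
    missing status in either member are excluded and counted.
    """
    wide = mut.pivot_table(index="sample_id", columns="gene", values="status",
                           aggfunc="first")
    rows = []
    for gene in wide.columns:
        both = prim_only = met_only = neither = excluded = 0
        for _, pair in pairs.iterrows():
            sp = wide[gene].get(pair["primary_sample"], np.nan)
            sm = wide[gene].get(pair["metastasis_sample"], np.nan)
            if pd.isna(sp) or pd.isna(sm):
                excluded += 1
                continue
            pm, mm = sp == "mutant", sm == "mutant"
            if pm and mm:
                both += 1
            elif pm:
                prim_only += 1
            elif mm:
                met_only += 1
            else:
                neither += 1
        involved = both + prim_only + met_only
        discordant = prim_only + met_only
        rows.append({
            "gene": gene, "mutant_in_both": both,
            "primary_only": prim_only, "metastasis_only": met_only,
            "neither": neither, "n_excluded_missing": excluded,
            "n_pairs_with_mutation": involved,
            "n_discordant": discordant,
            "discordance_pct": (fmt_percent(discordant, involved)
                                if involved else None),
        })
    return pd.DataFrame(rows)
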
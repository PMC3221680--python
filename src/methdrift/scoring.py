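"""Binarization, CIMP classification and Z-score panel scoring.

Continuous methylation densities are converted to categorical calls at a
density cutoff (strictly greater than 15% by default). CIMP (CpG island
methylator phenotype) is called positive when at least two of the six panel
markers (MINT1, MINT2, MINT31, p16, p14, MLH1) are methylated. Z-scores
standardize each gene across the analyzed sample universe so that a panel's
scores can be averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import DEFAULT_CONFIG, ThresholdConfig
from .matrix import MethylationMatrix

__all__ = [
    "MethylationBinarizer", "GeneZScorer", "CIMPClassifier",
    "binarize", "binary_labels", "call_cimp", "zscore", "panel_zscore",
    "ZScoreResult",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, MethylationMatrix):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class MethylationBinarizer(TransformerMixin, BaseEstimator):
    """Binarize methylation densities at a strict cutoff.

    A density strictly greater than ``density_cutoff`` is methylated (1.0);
    a density at or below the cutoff is unmethylated (0.0); missing values
    propagate as NaN. Stateless: ``fit`` only validates.
    """

    def __init__(self, density_cutoff: float = 15.0):
        self.density_cutoff = density_cutoff

    def fit(self, X, y=None):
        if not self.density_cutoff > 0:
            raise ValueError("density_cutoff must be > 0")
        self.n_features_in_ = _as_frame(X).shape[1]
        return self

    def transform(self, X):
        frame = _as_frame(X)
        calls = (frame > self.density_cutoff).astype(float)
        calls[frame.isna()] = np.nan
        return calls if isinstance(X, (pd.DataFrame, MethylationMatrix)) \
            else calls.to_numpy()


class GeneZScorer(TransformerMixin, BaseEstimator):
    """Per-gene standardization: z = (x - mean) / SD with the sample SD
    (n-1 denominator), computed over non-missing samples of the fitted
    universe.

    Fitted attributes
    -----------------
    mean_ : pandas.Series  per-gene mean
    scale_ : pandas.Series  per-gene sample SD
    n_samples_ : pandas.Series  non-missing count per gene
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        frame = _as_frame(X)
        n = frame.notna().sum()
        too_few = n[n < 2]
        if len(too_few):
            raise ValueError(
                f"need >= 2 non-missing values per gene; offending genes: "
                f"{list(too_few.index)}")
        sd = frame.std(ddof=self.ddof)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(
                f"zero methylation SD (constant gene): {list(zero.index)}")
        self.mean_ = frame.mean()
        self.scale_ = sd
        self.n_samples_ = n
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X):
        frame = _as_frame(X)
        z = (frame - self.mean_) / self.scale_
        return z if isinstance(X, (pd.DataFrame, MethylationMatrix)) \
            else z.to_numpy()


@dataclass
class ZScoreResult:
    """Z-score matrix with the per-gene moments and the sample universe they
    were computed over (means/SDs depend on the cohort analyzed)."""
    z: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    universe: tuple[str, ...]


class CIMPClassifier(BaseEstimator):
    """CIMP status from panel-marker methylation calls.

    A sample is positive when at least ``min_markers`` measured panel markers
    are methylated (density strictly above ``density_cutoff``); negative when
    even counting every missing panel marker as methylated the total would
    stay below ``min_markers``; indeterminate otherwise.
    """

    def __init__(self, panel: Sequence[str] = DEFAULT_CONFIG.cimp_panel,
                 min_markers: int = 2, density_cutoff: float = 15.0):
        self.panel = panel
        self.min_markers = min_markers
        self.density_cutoff = density_cutoff

    def fit(self, X, y=None):
        frame = _as_frame(X)
        absent = [g for g in self.panel if g not in frame.columns]
        if absent:
            raise ValueError(f"CIMP panel loci absent from matrix: {absent}")
        self.panel_ = tuple(self.panel)
        return self

    def call(self, X) -> pd.DataFrame:
        """Per-sample marker counts and CIMP status."""
        self.fit(X)
        frame = _as_frame(X)[list(self.panel_)]
        binary = MethylationBinarizer(self.density_cutoff).fit_transform(frame)
        n_measured = binary.notna().sum(axis=1)
        n_meth = (binary == 1.0).sum(axis=1)
        n_missing = len(self.panel_) - n_measured
        status = np.where(
            n_meth >= self.min_markers, "positive",
            np.where(n_meth + n_missing < self.min_markers, "negative",
                     "indeterminate"))
        return pd.DataFrame({
            "n_panel_markers_measured": n_measured.astype(int),
            "n_panel_markers_methylated": n_meth.astype(int),
            "status": status,
        }, index=frame.index)

    def predict(self, X) -> np.ndarray:
        return self.call(X)["status"].to_numpy()


# ---------------------------------------------------------------- functions

def binarize(matrix, cfg: ThresholdConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Binary call matrix: 1.0 methylated, 0.0 unmethylated, NaN missing."""
    frame = _as_frame(matrix)
    return MethylationBinarizer(cfg.density_cutoff).fit_transform(frame)


def binary_labels(calls: pd.DataFrame) -> pd.DataFrame:
    """String view of a binary call matrix."""
    out = calls.map(lambda v: "missing" if pd.isna(v)
                    else ("methylated" if v == 1.0 else "unmethylated"))
    return out


def call_cimp(matrix, cfg: ThresholdConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """CIMP status per sample (see :class:`CIMPClassifier`)."""
    clf = CIMPClassifier(panel=cfg.cimp_panel,
                         min_markers=cfg.cimp_min_markers,
                         density_cutoff=cfg.density_cutoff)
    return clf.call(matrix)


def zscore(matrix, universe: Sequence[str] | None = None,
           ddof: int = 1) -> ZScoreResult:
    """Standardize each gene over the given sample universe (default: all
    samples in the matrix). Raises on constant genes, naming them."""
    frame = _as_frame(matrix)
    if universe is not None:
        fit_frame = frame.loc[list(universe)]
    else:
        fit_frame = frame
    scaler = GeneZScorer(ddof=ddof).fit(fit_frame)
    return ZScoreResult(z=scaler.transform(frame), mean=scaler.mean_,
                        sd=scaler.scale_, universe=tuple(fit_frame.index))


def panel_zscore(z: pd.DataFrame, loci: Sequence[str]) -> pd.Series:
    """Per-sample mean z over a locus panel (non-missing values only);
    samples with every panel value missing yield NaN."""
    if len(loci) == 0:
        raise ValueError("empty locus list")
    absent = [l for l in loci if l not in z.columns]
    if absent:
        raise ValueError(f"panel loci absent from z-score matrix: {absent}")
    return z[list(loci)].mean(axis=1, skipna=True)
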
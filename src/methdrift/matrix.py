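"""Methylation-density matrix container and TSV I/O.

Methylation densities are percent values in [0, 100] (the average over the
CpG sites assayed at a locus), one per (sample, locus), with ``NaN`` for
missing measurements. The matrix is a thin validated wrapper around a pandas
DataFrame (samples in rows, loci in columns).
"""

from __future__ import annotations

import io
import os
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "read_methylation_table",
    "write_methylation_table",
]

_MISSING_CODES = ("NA", "")

#: separator between a locus name and a CpG-site index in per-CpG column headers
PER_CPG_SEP = ":"


class MethylationMatrix:
    """Samples x loci methylation densities in percent.

    Parameters
    ----------
    data : pandas.DataFrame
        Float frame indexed by sample ID with locus IDs as columns; values in
        [0, 100] or NaN.
    per_cpg : mapping, optional
        Per-locus DataFrame of per-CpG-site percents (same sample index)
        backing the stored density. When given, every stored density must
        equal the arithmetic mean of its non-missing per-CpG values.
    """

    def __init__(self, data: pd.DataFrame,
                 per_cpg: Mapping[str, pd.DataFrame] | None = None):
        data = data.astype(float)
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate locus IDs: {dups}")
        bad = (data < 0) | (data > 100)
        if bad.any().any():
            sample, locus = next(
                (s, l) for s in data.index for l in data.columns if bad.at[s, l]
            )
            raise ValueError(
                f"methylation density {data.at[sample, locus]!r} out of [0, 100] "
                f"at sample {sample!r}, locus {locus!r}"
            )
        self._data = data
        self._per_cpg = dict(per_cpg) if per_cpg else None
        if self._per_cpg:
            self._check_per_cpg()

    def _check_per_cpg(self) -> None:
        assert self._per_cpg is not None
        for locus, sites in self._per_cpg.items():
            if locus not in self._data.columns:
                raise ValueError(f"per-CpG values for unknown locus {locus!r}")
            means = sites.mean(axis=1, skipna=True).reindex(self._data.index)
            stored = self._data[locus]
            both = means.notna() & stored.notna()
            if not np.allclose(means[both], stored[both], atol=1e-9, rtol=0):
                raise ValueError(
                    f"stored density for locus {locus!r} does not equal the mean "
                    "of its per-CpG values"
                )

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def per_cpg(self) -> dict[str, pd.DataFrame] | None:
        return self._per_cpg

    @property
    def n_missing(self) -> int:
        return int(self._data.isna().sum().sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"MethylationMatrix({len(self.sample_ids)} samples x "
                f"{len(self.locus_ids)} loci, {self.n_missing} missing)")

    @classmethod
    def from_per_cpg(cls, per_cpg: Mapping[str, pd.DataFrame]) -> "MethylationMatrix":
        """Build a matrix by averaging per-CpG-site percents per locus."""
        densities = {locus: sites.mean(axis=1, skipna=True)
                     for locus, sites in per_cpg.items()}
        return cls(pd.DataFrame(densities), per_cpg=per_cpg)


def read_methylation_table(path, sep: str = "\t") -> MethylationMatrix:
    """Read a delimited methylation-density table.

    First column is the sample ID, header row holds locus IDs; missing values
    are encoded ``NA`` (empty fields are also accepted). Lines starting with
    ``#`` are ignored. Columns named ``LOCUS:i`` are treated as per-CpG-site
    measurements and collapsed to the locus density by arithmetic mean.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False, comment="#")
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dups}")

    def _to_float(col: pd.Series) -> pd.Series:
        # float() is correctly rounded, preserving the write/read round-trip
        def parse(v: str) -> float:
            if v in _MISSING_CODES:
                return np.nan
            try:
                return float(v)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric value {v!r} in column {col.name!r}") from exc
        return col.map(parse)

    values = raw.apply(_to_float)
    bad = (values < 0) | (values > 100)
    if bad.any().any():
        sample = bad.any(axis=1).idxmax()
        locus = bad.loc[sample].idxmax()
        raise ValueError(
            f"value {values.at[sample, locus]!r} outside [0, 100] at "
            f"row {sample!r}, column {locus!r}"
        )

    if any(PER_CPG_SEP in str(c) for c in values.columns):
        per_cpg: dict[str, pd.DataFrame] = {}
        plain: dict[str, pd.Series] = {}
        for col in values.columns:
            name = str(col)
            if PER_CPG_SEP in name:
                locus = name.split(PER_CPG_SEP, 1)[0]
                per_cpg.setdefault(locus, pd.DataFrame(index=values.index))
                per_cpg[locus][name] = values[col]
            else:
                plain[name] = values[col]
        densities = {locus: sites.mean(axis=1, skipna=True)
                     for locus, sites in per_cpg.items()}
        data = pd.DataFrame({**plain, **densities}, index=values.index)
        return MethylationMatrix(data, per_cpg=per_cpg)
    return MethylationMatrix(values)


def _format_value(v: float) -> str:
    if pd.isna(v):
        return "NA"
    # shortest positional decimal that round-trips to the same float
    return np.format_float_positional(float(v), unique=True, trim="0")


def write_methylation_table(matrix: MethylationMatrix, path, sep: str = "\t",
                            header_comment: str | None = None) -> None:
    """Write a matrix as delimited text; values round-trip bit-exactly."""
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    buf.write("sample_id" + sep + sep.join(map(str, matrix.locus_ids)) + "\n")
    for sample in matrix.sample_ids:
        row = matrix.data.loc[sample]
        buf.write(str(sample) + sep
                  + sep.join(_format_value(v) for v in row) + "\n")
    with open(os.fspath(path), "w") as fh:
        fh.write(buf.getvalue())
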
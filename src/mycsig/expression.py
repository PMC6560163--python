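"""Reading, validating and normalizing gene-by-sample expression tables.

The in-memory container is :class:`ExpressionMatrix`, a thin wrapper around a
pandas DataFrame (genes in rows, samples in columns) carrying optional
per-sample metadata (model of origin, technical replicate group).  Tables are
exchanged as delimited text: first column header ``gene``, one column per
sample, UTF-8.  This is the plain-text export of an nCounter-style count
table; binary instrument files are not handled here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionValidationError",
    "read_counts",
    "write_counts",
    "read_sample_meta",
    "normalize_housekeeping",
    "average_replicates",
    "log2_transform",
]


class ExpressionValidationError(ValueError):
    """Raised when a count table violates the expression-matrix contract."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of non-negative expression values.

    Parameters
    ----------
    data
        DataFrame with gene symbols as the index and sample identifiers as
        columns.  Values are counts or normalized counts; all must be finite
        and non-negative.
    sample_meta
        Optional DataFrame indexed by sample identifier with columns
        ``model`` (``PDTX`` or ``organoid``) and/or ``replicate_group``.
    log_scale
        True for log-transformed matrices, whose values may be negative;
        linear-scale matrices must be non-negative.
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame | None = field(default=None)
    log_scale: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ExpressionValidationError(f"duplicate gene symbols: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ExpressionValidationError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(self.data)
            raise ExpressionValidationError(
                f"non-numeric value {bad[2]!r} at gene {bad[0]!r}, sample {bad[1]!r}"
            )
        if values.size:
            finite = np.isfinite(values)
            if not finite.all():
                g, s = _locate(self.data, ~finite)
                raise ExpressionValidationError(
                    f"non-finite value at gene {g!r}, sample {s!r}"
                )
            neg = (values < 0) & (not self.log_scale)
            if neg.any():
                g, s = _locate(self.data, neg)
                raise ExpressionValidationError(
                    f"negative value {self.data.at[g, s]} at gene {g!r}, sample {s!r}"
                )
        if self.sample_meta is not None:
            missing = [s for s in cols if s not in self.sample_meta.index]
            if missing:
                raise ExpressionValidationError(
                    f"samples absent from metadata: {missing}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ExpressionValidationError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes].copy(), self.sample_meta, self.log_scale)

    def copy(self) -> "ExpressionMatrix":
        meta = None if self.sample_meta is None else self.sample_meta.copy()
        return ExpressionMatrix(self.data.copy(), meta, self.log_scale)


def _locate(df: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return df.index[i], df.columns[j]


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str, object]:
    for gene, row in df.iterrows():
        for sample, v in row.items():
            try:
                float(v)
            except (TypeError, ValueError):
                return gene, sample, v
    raise AssertionError("no non-numeric cell found")  # pragma: no cover


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(
    path: str | Path,
    sep: str | None = None,
    sample_meta: pd.DataFrame | None = None,
    signature_genes: list[str] | None = None,
) -> ExpressionMatrix:
    """Read a delimited count table into a validated :class:`ExpressionMatrix`.

    The first column must be headed ``gene`` and hold gene symbols; every
    other column is one sample.  Row and column order are preserved.  When
    ``signature_genes`` is given, genes from that list missing from the table
    trigger a warning (scoring will later fail loudly if they are required).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    sep = _sniff_sep(path, sep)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ExpressionValidationError(f"empty or headerless file: {path}")
    first_field = header.split(sep)[0].strip()
    if first_field.lower() != "gene":
        raise ExpressionValidationError(
            f"first header field must be 'gene', got {first_field!r} in {path}"
        )
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = _locate(raw, bad.to_numpy())
        raise ExpressionValidationError(
            f"non-numeric value {raw.at[g, s]!r} at gene {g!r}, sample {s!r}"
        )
    m = ExpressionMatrix(numeric.astype(float), sample_meta)
    if signature_genes:
        absent = [g for g in signature_genes if g not in m.data.index]
        if absent:
            warnings.warn(
                f"signature genes absent from {path.name}: {absent}",
                UserWarning,
                stacklevel=2,
            )
    return m


def write_counts(m: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    """Write a count table in the same delimited-text dialect read_counts accepts."""
    path = Path(path)
    sep = _sniff_sep(path, sep)
    out = m.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=sep, float_format="%.12g", encoding="utf-8")


def read_sample_meta(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read the companion metadata table (columns: sample, model, replicate_group)."""
    path = Path(path)
    sep = _sniff_sep(path, sep)
    meta = pd.read_csv(path, sep=sep, dtype=str)
    if "sample" not in meta.columns:
        raise ExpressionValidationError(f"metadata file {path} lacks a 'sample' column")
    return meta.set_index("sample")


def normalize_housekeeping(m: ExpressionMatrix, hk_genes: list[str]) -> ExpressionMatrix:
    """Rescale each sample so housekeeping content is constant across samples.

    Each sample column is multiplied by a factor that sets the geometric mean
    of its housekeeping genes to the across-sample mean of those geometric
    means.  This is the standard content-normalization convention for
    hybridization count data: it removes per-sample differences in RNA input
    while leaving relative expression within a sample untouched.  Housekeeping
    rows are kept in the output.
    """
    missing = [g for g in hk_genes if g not in m.data.index]
    if missing:
        raise ExpressionValidationError(f"housekeeping genes absent: {missing}")
    if not hk_genes:
        raise ExpressionValidationError("empty housekeeping gene list")
    hk = m.data.loc[hk_genes].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_gm = np.log(hk).mean(axis=0)
    gms = np.exp(log_gm)
    zero = ~np.isfinite(log_gm) | (gms <= 0)
    if zero.any():
        bad = [m.samples[j] for j in np.flatnonzero(zero)]
        raise ExpressionValidationError(
            f"zero housekeeping geometric mean in sample(s): {bad}"
        )
    target = gms.mean()
    scaled = m.data.to_numpy(dtype=float) * (target / gms)[np.newaxis, :]
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=m.data.index, columns=m.data.columns),
        m.sample_meta,
    )


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse technical replicates to one column per replicate group.

    Every sample must carry a ``replicate_group`` annotation; group columns
    are averaged arithmetically and appear in order of first appearance.  The
    output's metadata maps each group to itself (replicates are consumed).
    """
    if m.sample_meta is None or "replicate_group" not in m.sample_meta.columns:
        raise ExpressionValidationError(
            "replicate averaging requires sample_meta with a 'replicate_group' column"
        )
    groups = m.sample_meta.loc[m.samples, "replicate_group"]
    if groups.isna().any():
        bad = list(groups.index[groups.isna()])
        raise ExpressionValidationError(f"samples lacking replicate_group: {bad}")
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for sample, grp in groups.items():
        if grp not in members:
            members[grp] = []
            order.append(grp)
        members[grp].append(sample)
    averaged = pd.DataFrame(
        {grp: m.data[members[grp]].mean(axis=1) for grp in order},
        index=m.data.index,
    )
    meta_cols = {"replicate_group": order}
    if "model" in m.sample_meta.columns:
        meta_cols["model"] = [
            m.sample_meta.loc[members[g][0], "model"] for g in order
        ]
    new_meta = pd.DataFrame(meta_cols, index=pd.Index(order, name="sample"))
    return ExpressionMatrix(averaged, new_meta, m.log_scale)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(v + pseudocount); pseudocount must be positive."""
    if not pseudocount > 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    out = np.log2(m.data.to_numpy(dtype=float) + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        m.sample_meta,
        log_scale=True,
    )
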
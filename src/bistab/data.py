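"""Expression-matrix containers, transforms, and delimited-text I/O.

The unit of analysis is an :class:`ExpressionGroup`: one group of
biological samples (e.g. all individuals collected at one developmental
timepoint) measured over a common gene panel, stored as a samples x genes
matrix of natural-log expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionGroup",
    "log_transform",
    "geometric_mean_normalize",
    "read_expression",
    "write_expression",
    "LowSampleWarning",
]

#: practical floor on the number of samples below which model selection
#: between unimodal and bistable fits becomes unreliable
MIN_RELIABLE_SAMPLES = 10


class LowSampleWarning(UserWarning):
    """Group has fewer samples than the practical floor for model selection."""


@dataclass(frozen=True)
class ExpressionGroup:
    """One group's natural-log expression matrix with row/column labels.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_genes)
        Natural-log expression values. All entries must be finite.
    gene_ids : list of str
        Unique gene identifiers, one per column.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    group_label : str
        Free-form label for the group (e.g. a timepoint such as ``"day15"``).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    group_label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        n, g = values.shape
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries for {g} columns"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"sample_ids has {len(self.sample_ids)} entries for {n} rows"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}; "
                "missing values are not supported"
            )
        if n < 3:
            raise ValueError(
                f"group {self.group_label!r} has {n} samples; "
                "at least 3 are required to define a covariance"
            )
        if n < MIN_RELIABLE_SAMPLES:
            warnings.warn(
                f"group {self.group_label!r} has only {n} samples; model "
                f"selection is unreliable below ~{MIN_RELIABLE_SAMPLES}",
                LowSampleWarning,
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, group_label: str = "", value_scale: str = "log"
    ) -> "ExpressionGroup":
        """Build a group from a samples x genes DataFrame.

        ``value_scale="raw"`` applies the natural-log transform; ``"log"``
        takes the values as already log-space.
        """
        values = df.to_numpy(dtype=float)
        if value_scale == "raw":
            values = log_transform(
                values,
                gene_ids=[str(c) for c in df.columns],
                sample_ids=[str(i) for i in df.index],
            )
        elif value_scale != "log":
            raise ValueError(f"value_scale must be 'raw' or 'log', got {value_scale!r}")
        return cls(
            values=values,
            gene_ids=[str(c) for c in df.columns],
            sample_ids=[str(i) for i in df.index],
            group_label=group_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, idx: np.ndarray, group_label: str | None = None) -> "ExpressionGroup":
        idx = np.asarray(idx)
        return ExpressionGroup(
            values=self.values[idx],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
            group_label=self.group_label if group_label is None else group_label,
        )


def log_transform(
    raw: np.ndarray,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> np.ndarray:
    """Natural-log transform of a strictly positive raw expression matrix.

    Raises ``ValueError`` naming the offending entry if any value is <= 0,
    which signals unnormalized or corrupted input.
    """
    raw = np.asarray(raw, dtype=float)
    bad = ~(raw > 0)
    if np.any(bad):
        i, j = (int(k) for k in np.argwhere(bad)[0])
        sample = sample_ids[i] if sample_ids is not None else f"row {i}"
        gene = gene_ids[j] if gene_ids is not None else f"column {j}"
        raise ValueError(
            f"non-positive expression value {raw[i, j]!r} at sample "
            f"{sample!r}, gene {gene!r}; raw values must be strictly "
            "positive before the natural-log transform"
        )
    return np.log(raw)


def geometric_mean_normalize(
    raw: pd.DataFrame, housekeeping: list[str]
) -> pd.DataFrame:
    """Scale each sample by its housekeeping-gene geometric mean.

    Each sample's values are divided by (that sample's geometric mean over
    the housekeeping genes / the grand mean of those geometric means), so
    that housekeeping geometric means are equalized across samples.  This
    approximates vendor normalization for counting assays and is OFF by
    default in the pipeline.
    """
    missing = [g for g in housekeeping if g not in raw.columns]
    if missing:
        raise ValueError(f"housekeeping genes not present in data: {missing}")
    hk = raw[housekeeping].to_numpy(dtype=float)
    if np.any(hk <= 0):
        i, j = (int(k) for k in np.argwhere(hk <= 0)[0])
        raise ValueError(
            f"non-positive housekeeping value at sample {raw.index[i]!r}, "
            f"gene {housekeeping[j]!r}"
        )
    gm = np.exp(np.mean(np.log(hk), axis=1))  # per-sample geometric mean
    grand = np.exp(np.mean(np.log(gm)))
    factors = gm / grand
    return raw.div(factors, axis=0)


def read_expression(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a samples x genes delimited-text matrix.

    The first row holds gene identifiers, the first column sample
    identifiers.  The separator is inferred from the extension (``.csv`` vs
    ``.tsv``/``.txt``) unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        na_cols = list(df.columns[df.isna().any()])
        raise ValueError(
            f"{path} contains missing values (e.g. in {na_cols[:5]}); "
            "missing data are not supported"
        )
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x genes matrix as delimited text (repr-faithful)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, float_format="%.17g")
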
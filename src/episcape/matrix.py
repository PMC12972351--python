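"""Core containers: the beta-value matrix and per-sample metadata.

A methylation *beta value* is the methylated fraction of a CpG site in a
sample, bounded in [0, 1].  The universal substrate of every analysis in
this package is a sites x samples matrix of beta values with missing
entries allowed, plus a per-sample metadata table (tissue, group label,
age, sex, cell type, exposure).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: metadata columns that must be present
META_REQUIRED = ("sample_id", "tissue", "group")
#: optional metadata columns that are recognised by the analyses
META_OPTIONAL = ("age", "sex", "cell_type", "exposure")

#: values marginally outside [0, 1] by no more than this are clamped
#: (float text artifacts); larger violations are errors.
CLAMP_TOL = 1e-9


def _first_duplicate(index: pd.Index) -> object | None:
    dup = index[index.duplicated()]
    return dup[0] if len(dup) else None


class MethylationMatrix:
    """Sites x samples beta-value matrix with missing-value support.

    Rows are CpG sites (array probe identifiers such as ``cg00000029``),
    columns are samples.  Present values lie in [0, 1]; missing entries
    are NaN.  Identifiers are unique along both axes.

    Parameters
    ----------
    values
        DataFrame with site identifiers as index and sample identifiers
        as columns.  Values are coerced to float.
    """

    def __init__(self, values: pd.DataFrame):
        values = values.astype(float)

        dup = _first_duplicate(values.index)
        if dup is not None:
            raise ValueError(f"duplicate site identifier: {dup!r}")
        dup = _first_duplicate(values.columns)
        if dup is not None:
            raise ValueError(f"duplicate sample identifier: {dup!r}")

        arr = values.to_numpy()
        with np.errstate(invalid="ignore"):
            low = arr < 0.0
            high = arr > 1.0
        if low.any() or high.any():
            bad = low | high
            # clamp float-text artifacts, reject real violations
            mag = np.where(bad, np.maximum(-arr, arr - 1.0), 0.0)
            if np.nanmax(mag) > CLAMP_TOL:
                i, j = np.argwhere(mag > CLAMP_TOL)[0]
                raise ValueError(
                    "beta value outside [0, 1]: "
                    f"site {values.index[i]!r}, sample {values.columns[j]!r}, "
                    f"value {arr[i, j]!r}"
                )
            arr = np.clip(arr, 0.0, 1.0)
            values = pd.DataFrame(arr, index=values.index, columns=values.columns)

        self._df = values

    # -- basic accessors -------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        """The underlying sites x samples DataFrame (do not mutate)."""
        return self._df

    @property
    def site_ids(self) -> pd.Index:
        return self._df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self._df.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_sites, n_samples = self.shape
        return f"MethylationMatrix({n_sites} sites x {n_samples} samples)"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationMatrix):
            return NotImplemented
        return self._df.equals(other._df)

    # -- subsetting ------------------------------------------------------
    def select_sites(self, site_ids: Sequence) -> "MethylationMatrix":
        """Row subset, in the order given; unknown ids raise KeyError."""
        return MethylationMatrix(self._df.loc[list(site_ids)])

    def select_samples(self, sample_ids: Sequence) -> "MethylationMatrix":
        """Column subset, in the order given; unknown ids raise KeyError."""
        return MethylationMatrix(self._df[list(sample_ids)])

    def drop_sites(self, site_ids: Iterable) -> "MethylationMatrix":
        present = self._df.index.intersection(pd.Index(site_ids))
        return MethylationMatrix(self._df.drop(index=present))

    def n_valid_per_site(self) -> pd.Series:
        """Count of non-missing values per site across all samples."""
        return self._df.notna().sum(axis=1)


def validate_sample_meta(meta: pd.DataFrame, matrix: MethylationMatrix | None = None) -> pd.DataFrame:
    """Check a sample-metadata table and normalise its index.

    Requires columns ``sample_id``, ``tissue`` and ``group``; sample ids
    must be unique and, when a matrix is given, match its columns exactly
    (order-insensitive).  Returns the table indexed by ``sample_id``.
    """
    missing = [c for c in META_REQUIRED if c not in meta.columns and meta.index.name != c]
    if meta.index.name == "sample_id" and "sample_id" in missing:
        missing.remove("sample_id")
    if missing:
        raise ValueError(f"sample metadata is missing required column(s): {missing}")
    if meta.index.name != "sample_id":
        meta = meta.set_index("sample_id")
    dup = _first_duplicate(meta.index)
    if dup is not None:
        raise ValueError(f"duplicate sample identifier in metadata: {dup!r}")
    if matrix is not None:
        meta_ids = set(meta.index)
        mat_ids = set(matrix.sample_ids)
        if meta_ids != mat_ids:
            only_meta = sorted(meta_ids - mat_ids)[:3]
            only_mat = sorted(mat_ids - meta_ids)[:3]
            raise ValueError(
                "sample ids in metadata and matrix differ "
                f"(metadata-only: {only_meta}, matrix-only: {only_mat})"
            )
    return meta


def samples_of(meta: pd.DataFrame, tissue: str | None = None, group: str | None = None) -> list:
    """Sample ids matching the given tissue and/or group label."""
    sel = pd.Series(True, index=meta.index)
    if tissue is not None:
        sel &= meta["tissue"] == tissue
    if group is not None:
        sel &= meta["group"] == group
    return list(meta.index[sel])
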
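"""Tissue-unique methylation sites: the quantile + margin criterion.

A site is *unique* for a tissue when the tissue's central methylation
lies at least ``margin`` (default 0.1) beyond an outer empirical
quantile (default the 5% / 95% pair) of the pooled non-missing values
of all other tissues combined:

* direction ``low``:   center_tissue <= q_low(others)  - margin
* direction ``high``:  center_tissue >= q_high(others) + margin

Both inequalities are inclusive ("at least").  Sites with too few valid
values across the whole dataset are omitted; the central statistic is
the mean by default (median available), and quantiles use linear
interpolation between order statistics unless configured otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .matrix import MethylationMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UniqueCriterion:
    """Parameters of the uniqueness test.

    ``min_valid`` is either an absolute count (int >= 1; the published
    compendium analysis used 2000) or a fraction of samples in (0, 1]
    (float; the default 0.5 suits small matrices).
    """

    margin: float = 0.1
    quantile: float = 0.05
    center: Literal["mean", "median"] = "mean"
    min_valid: int | float = 0.5
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 0.5:
            raise ValueError(f"quantile must be in (0, 0.5), got {self.quantile}")
        if self.margin <= 0:
            raise ValueError(f"margin must be positive, got {self.margin}")
        if self.center not in ("mean", "median"):
            raise ValueError(f"center must be 'mean' or 'median', got {self.center!r}")
        if isinstance(self.min_valid, float) and not 0 < self.min_valid <= 1:
            if self.min_valid < 1:
                raise ValueError("fractional min_valid must be in (0, 1]")

    def resolve_min_valid(self, n_samples: int) -> int:
        if isinstance(self.min_valid, float) and self.min_valid <= 1:
            return int(np.ceil(self.min_valid * n_samples))
        return int(self.min_valid)


@dataclass(frozen=True)
class UniqueSiteRecord:
    """One site flagged unique for one tissue, with its evidence."""

    site_id: str
    tissue: str
    direction: Literal["low", "high"]
    tissue_center: float
    other_q_low: float
    other_q_high: float
    n_valid_tissue: int
    n_valid_other: int


RECORD_COLUMNS = (
    "site_id", "tissue", "direction", "tissue_center",
    "other_q_low", "other_q_high", "n_valid_tissue", "n_valid_other",
)


def records_to_frame(records: Sequence[UniqueSiteRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(RECORD_COLUMNS))


def records_from_frame(df: pd.DataFrame) -> list[UniqueSiteRecord]:
    return [
        UniqueSiteRecord(
            site_id=str(r.site_id), tissue=str(r.tissue), direction=str(r.direction),
            tissue_center=float(r.tissue_center), other_q_low=float(r.other_q_low),
            other_q_high=float(r.other_q_high), n_valid_tissue=int(r.n_valid_tissue),
            n_valid_other=int(r.n_valid_other),
        )
        for r in df.itertuples(index=False)
    ]


def identify_unique_sites(
    matrix: MethylationMatrix,
    meta: pd.DataFrame,
    criterion: UniqueCriterion = UniqueCriterion(),
    tissues: Sequence[str] | None = None,
) -> list[UniqueSiteRecord]:
    """Scan every (site, tissue) pair for the uniqueness criterion.

    For each candidate tissue the tissue center is computed over the
    tissue's non-missing values and the outer quantiles over the pooled
    non-missing values of all *other* tissues combined.  Records are
    sorted by tissue then site id.  A site may be unique in more than
    one tissue; each qualifying pair yields its own record.
    """
    all_tissues = list(pd.unique(meta["tissue"]))
    if len(all_tissues) < 2:
        raise ValueError("at least 2 tissues are required to define uniqueness")
    if tissues is None:
        tissues = all_tissues
    else:
        unknown = set(tissues) - set(all_tissues)
        if unknown:
            raise ValueError(f"unknown tissue label(s): {sorted(unknown)}")

    df = matrix.values
    arr = df.to_numpy()
    n_samples = arr.shape[1]
    min_valid = criterion.resolve_min_valid(n_samples)
    n_valid_all = np.sum(~np.isnan(arr), axis=1)
    eligible = n_valid_all >= min_valid

    col_tissue = meta.reindex(df.columns)["tissue"].to_numpy()

    records: list[UniqueSiteRecord] = []
    n_skipped_no_valid = 0
    center_fn = np.nanmean if criterion.center == "mean" else np.nanmedian

    for tissue in sorted(map(str, tissues)):
        in_t = col_tissue == tissue
        t_vals = arr[:, in_t]
        o_vals = arr[:, ~in_t]
        n_valid_t = np.sum(~np.isnan(t_vals), axis=1)
        n_valid_o = np.sum(~np.isnan(o_vals), axis=1)
        usable = eligible & (n_valid_t > 0) & (n_valid_o > 0)
        n_skipped_no_valid += int(np.sum(eligible & ~usable))
        if not usable.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            center = center_fn(t_vals, axis=1)
            q_low, q_high = np.nanquantile(
                o_vals, [criterion.quantile, 1.0 - criterion.quantile],
                axis=1, method=criterion.quantile_method,
            )
        is_low = usable & (center <= q_low - criterion.margin)
        is_high = usable & (center >= q_high + criterion.margin)
        for i in np.nonzero(is_low | is_high)[0]:
            records.append(UniqueSiteRecord(
                site_id=str(df.index[i]), tissue=tissue,
                direction="low" if is_low[i] else "high",
                tissue_center=float(center[i]),
                other_q_low=float(q_low[i]), other_q_high=float(q_high[i]),
                n_valid_tissue=int(n_valid_t[i]), n_valid_other=int(n_valid_o[i]),
            ))
    if n_skipped_no_valid:
        logger.warning(
            "%d (site, tissue) evaluations skipped for lack of valid values",
            n_skipped_no_valid,
        )
    records.sort(key=lambda r: (r.tissue, r.site_id))
    return records


def pan_tissue_mean(
    matrix: MethylationMatrix, meta: pd.DataFrame, focal_tissue: str
) -> pd.Series:
    """Per-site mean over all samples *not* of the focal tissue.

    The pan-tissue mean is the common methylation level the rest of the
    body shows at a site; regression to the mean is movement toward it.
    Missing where no other-tissue values exist.
    """
    if focal_tissue not in set(meta["tissue"]):
        raise ValueError(f"unknown tissue label: {focal_tissue!r}")
    col_tissue = meta.reindex(matrix.sample_ids)["tissue"].to_numpy()
    other = matrix.values.loc[:, col_tissue != focal_tissue]
    if other.shape[1] == 0:
        return pd.Series(np.nan, index=matrix.site_ids, name="pan_tissue_mean")
    return other.mean(axis=1, skipna=True).rename("pan_tissue_mean")


def select_control_sites(
    matrix: MethylationMatrix,
    n: int,
    mode: Literal["random", "high_variability", "low_variability"] = "random",
    exclude: set[str] | frozenset[str] = frozenset(),
    seed: int | None = None,
    samples: Sequence[str] | None = None,
) -> list[str]:
    """Pick control site sets matched in size to a unique-site set.

    ``random`` draws uniformly without replacement (seeded);
    ``high_variability`` / ``low_variability`` take the top / bottom
    ``n`` sites by per-site standard deviation across the analysis
    samples (missing values excluded).  Excluded sites never appear.
    """
    df = matrix.values if samples is None else matrix.values[list(samples)]
    eligible = df.index[~df.index.isin(list(exclude))]
    if n > len(eligible):
        raise ValueError(f"requested {n} control sites but only {len(eligible)} eligible")
    if mode == "random":
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(eligible), size=n, replace=False)
        return [str(eligible[i]) for i in sorted(picked)]
    if mode not in ("high_variability", "low_variability"):
        raise ValueError(f"unknown control-site mode: {mode!r}")
    sd = df.loc[eligible].std(axis=1, skipna=True, ddof=1).dropna()
    if n > len(sd):
        raise ValueError(
            f"requested {n} control sites but only {len(sd)} have a defined SD"
        )
    order = sd.sort_values(ascending=(mode == "low_variability"), kind="stable")
    return [str(s) for s in order.index[:n]]
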
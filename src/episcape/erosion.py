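"""Direction-of-change statistics at tissue-unique methylation sites.

Given a set of tissue-unique sites, each carrying a direction relative
to the rest of the body (``low`` = hypomethylated in the tissue,
``high`` = hypermethylated), a change in disease or aging is classified
per site as

* **regression to the mean** — the tissue moves toward the pan-tissue
  level (a low site gains methylation; a high site loses it), read as
  loss of the tissue's epigenetic information; or
* **divergence** — the opposite movement, strengthening the signature.

Two modes are provided: group comparison (case mean minus control mean)
and correlation (Pearson r of methylation against age or a 0/1 group
indicator).  Calls are aggregated and tested against the null that the
direction of change is random (probability 0.5) with an *exact*
binomial tail computed in log space, so probabilities far below the
smallest positive float (e.g. 10**-1000) remain meaningful; p-values
are therefore always reported as log10 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .matrix import MethylationMatrix, samples_of
from .unique import UniqueSiteRecord, pan_tissue_mean

Call = Literal["regression", "divergence", "tie", "undefined"]

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# exact log-space binomial tail
# ---------------------------------------------------------------------------

def binom_log10_sf(k: int, n: int, p0: float = 0.5, *, two_sided: bool = False) -> float:
    """log10 of the exact binomial upper tail P(X >= k), X ~ Bin(n, p0).

    The tail is summed term by term in log space (log-sum-exp over
    ``log C(n, i) + i log p0 + (n - i) log(1 - p0)``), so results as
    small as 10**-2000 are returned without underflow.  With
    ``two_sided=True`` the doubled tail min(1, 2 P(X >= k)) is used
    (appropriate only for p0 = 0.5, where the distribution is
    symmetric).  Always <= 0.
    """
    k, n = int(k), int(n)
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if k == 0:
        return 0.0
    i = np.arange(k, n + 1, dtype=float)
    log_terms = (
        gammaln(n + 1.0) - gammaln(i + 1.0) - gammaln(n - i + 1.0)
        + i * np.log(p0) + (n - i) * np.log1p(-p0)
    )
    log10_p = float(logsumexp(log_terms)) / _LN10
    if two_sided:
        log10_p = min(0.0, log10_p + np.log10(2.0))
    return min(log10_p, 0.0)


# ---------------------------------------------------------------------------
# per-site calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionCall:
    """Group-comparison call at one tissue-unique site."""

    site_id: str
    direction: Literal["low", "high"]
    control_mean: float
    case_mean: float
    delta: float  # case_mean - control_mean
    call: Call


@dataclass(frozen=True)
class CorrelationCall:
    """Correlation-mode call at one tissue-unique site.

    ``r`` is the raw Pearson correlation of methylation with the
    covariate; ``included`` marks whether the site enters the summary
    (False when |r| is below a robustness threshold).
    """

    site_id: str
    direction: Literal["low", "high"]
    r: float
    call: Call
    included: bool = True


@dataclass
class ErosionSummary:
    """Aggregate of direction calls plus the exact binomial statistic.

    ``fraction_regression`` is a percentage over informative calls
    (regression + divergence; ties and undefined excluded), and
    ``log10_p`` is the one-sided upper tail for the majority direction
    under the random-direction null p0 = 0.5.
    """

    n_evaluated: int
    n_regression: int
    n_divergence: int
    n_tie: int
    n_undefined: int
    fraction_regression: float
    log10_p: float
    majority: Call
    by_direction: dict[str, "ErosionSummary"] = field(default_factory=dict)

    @property
    def n_informative(self) -> int:
        return self.n_regression + self.n_divergence


def _sign_call(direction: str, signed_change: float) -> Call:
    """Sign rule: toward the pan-tissue level = regression.

    ``signed_change`` is the case-minus-control delta or the Pearson r
    against the covariate; at a low site a positive change moves toward
    the (higher) pan-tissue level, at a high site a negative one does.
    """
    if np.isnan(signed_change):
        return "undefined"
    if signed_change == 0.0:
        return "tie"
    toward = signed_change > 0 if direction == "low" else signed_change < 0
    return "regression" if toward else "divergence"


def summarize_calls(
    calls: Sequence[DirectionCall | CorrelationCall],
    *,
    two_sided: bool = False,
    _nest: bool = True,
) -> ErosionSummary:
    """Count calls and compute the majority-direction binomial tail."""
    included = [c for c in calls if getattr(c, "included", True)]
    n_reg = sum(c.call == "regression" for c in included)
    n_div = sum(c.call == "divergence" for c in included)
    n_tie = sum(c.call == "tie" for c in included)
    n_und = sum(c.call == "undefined" for c in included)
    n_info = n_reg + n_div
    if n_info > 0:
        frac = 100.0 * n_reg / n_info
        majority: Call = "regression" if n_reg >= n_div else "divergence"
        log10_p = binom_log10_sf(max(n_reg, n_div), n_info, 0.5, two_sided=two_sided)
    else:
        frac, majority, log10_p = float("nan"), "tie", float("nan")
    summary = ErosionSummary(
        n_evaluated=len(included), n_regression=n_reg, n_divergence=n_div,
        n_tie=n_tie, n_undefined=n_und, fraction_regression=frac,
        log10_p=log10_p, majority=majority,
    )
    if _nest:
        for d in ("low", "high"):
            sub = [c for c in included if c.direction == d]
            if sub:
                summary.by_direction[d] = summarize_calls(
                    sub, two_sided=two_sided, _nest=False)
    return summary


def call_direction_group(
    matrix: MethylationMatrix,
    meta: pd.DataFrame,
    records: Sequence[UniqueSiteRecord],
    control_label: str,
    case_label: str,
    *,
    two_sided: bool = False,
) -> tuple[list[DirectionCall], ErosionSummary]:
    """Classify each unique site's case-vs-control change.

    Means are taken over non-missing values of the focal tissue's
    samples in each group.  A low site whose case mean exceeds its
    control mean (or a high site with the reverse) regresses to the
    mean; ties and sites with an undefined mean are counted but never
    enter the binomial statistic.
    """
    if not records:
        raise ValueError("no unique-site records given")
    groups = set(meta["group"])
    for label in (control_label, case_label):
        if label not in groups:
            raise ValueError(f"group label {label!r} not present in metadata")

    df = matrix.values
    calls: list[DirectionCall] = []
    cache: dict[tuple[str, str], list] = {}
    for rec in records:
        for label in (control_label, case_label):
            key = (rec.tissue, label)
            if key not in cache:
                cache[key] = samples_of(meta, tissue=rec.tissue, group=label)
        ctrl_cols, case_cols = cache[(rec.tissue, control_label)], cache[(rec.tissue, case_label)]
        if rec.site_id not in df.index or not ctrl_cols or not case_cols:
            calls.append(DirectionCall(rec.site_id, rec.direction,
                                       float("nan"), float("nan"), float("nan"),
                                       "undefined"))
            continue
        row = df.loc[rec.site_id]
        c_mean = float(row[ctrl_cols].mean(skipna=True))
        d_mean = float(row[case_cols].mean(skipna=True))
        delta = d_mean - c_mean
        calls.append(DirectionCall(rec.site_id, rec.direction, c_mean, d_mean,
                                   delta, _sign_call(rec.direction, delta)))
    return calls, summarize_calls(calls, two_sided=two_sided)


def _pearson_rows(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> np.ndarray:
    """Row-wise Pearson r of a (sites x samples) block against y,
    pairwise-complete over missing entries; NaN when fewer than
    ``min_n`` pairs or either side is constant."""
    valid = ~np.isnan(x) & ~np.isnan(y)[None, :]
    n = valid.sum(axis=1)
    xz = np.where(valid, x, 0.0)
    yz = np.where(valid, y[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xz.sum(axis=1) / n
        my = yz.sum(axis=1) / n
        dx = np.where(valid, x - mx[:, None], 0.0)
        dy = np.where(valid, y[None, :] - my[:, None], 0.0)
        cov = (dx * dy).sum(axis=1)
        r = cov / np.sqrt((dx * dx).sum(axis=1) * (dy * dy).sum(axis=1))
    r = np.where(n >= min_n, r, np.nan)
    return r


def call_direction_correlation(
    matrix: MethylationMatrix,
    meta: pd.DataFrame,
    records: Sequence[UniqueSiteRecord],
    covariate: str = "age",
    min_abs_r: float | None = None,
    *,
    group_labels: tuple[str, str] | None = None,
    two_sided: bool = False,
) -> tuple[list[CorrelationCall], ErosionSummary]:
    """Correlation-mode direction calls at unique sites.

    ``covariate='age'`` correlates methylation with the metadata age of
    the focal tissue's samples; ``covariate='group'`` uses a 0/1 group
    indicator built from ``group_labels`` (control first).  Sites with
    ``|r| < min_abs_r`` remain in the call list but are excluded from
    the summary; constant methylation or fewer than 3 covariate pairs
    gives an undefined call.
    """
    if not records:
        raise ValueError("no unique-site records given")
    if covariate == "age":
        if "age" not in meta.columns:
            raise ValueError("covariate 'age' requires an age metadata column")
        cov_all = meta["age"].astype(float)
    elif covariate == "group":
        if group_labels is None:
            raise ValueError("covariate 'group' requires group_labels=(control, case)")
        control_label, case_label = group_labels
        cov_all = meta["group"].map({control_label: 0.0, case_label: 1.0})
    else:
        raise ValueError(f"unknown covariate {covariate!r} (use 'age' or 'group')")

    df = matrix.values
    calls: list[CorrelationCall] = []
    by_tissue: dict[str, list] = {}
    for rec in records:
        if rec.tissue not in by_tissue:
            by_tissue[rec.tissue] = samples_of(meta, tissue=rec.tissue)
        cols = by_tissue[rec.tissue]
        if rec.site_id not in df.index or not cols:
            calls.append(CorrelationCall(rec.site_id, rec.direction, float("nan"),
                                         "undefined"))
            continue
        x = df.loc[[rec.site_id], cols].to_numpy()
        y = cov_all.reindex(cols).to_numpy(float)
        r = float(_pearson_rows(x, y)[0])
        call = _sign_call(rec.direction, r)
        included = True
        if min_abs_r is not None and (np.isnan(r) or abs(r) < min_abs_r):
            included = False
        calls.append(CorrelationCall(rec.site_id, rec.direction, r, call, included))
    return calls, summarize_calls(calls, two_sided=two_sided)


# ---------------------------------------------------------------------------
# cohort-level context statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalTrend:
    """Fraction of sites gaining methylation case-vs-control.

    ``frac_increased_all`` is the percentage of sites with a strictly
    higher case mean among all sites with both means defined;
    ``frac_increased_robust`` restricts to sites whose methylation
    correlates with the 0/1 disease indicator at |r| > r_threshold.
    Ties support neither direction and are only disclosed.
    """

    frac_increased_all: float
    frac_increased_robust: float
    n_sites_all: int
    n_sites_robust: int
    n_ties: int
    r_threshold: float


def global_trend(
    matrix: MethylationMatrix,
    meta: pd.DataFrame,
    control_label: str,
    case_label: str,
    r_threshold: float = 0.3,
    tissue: str | None = None,
) -> GlobalTrend:
    """Genome-wide methylation trend between two groups."""
    ctrl = samples_of(meta, tissue=tissue, group=control_label)
    case = samples_of(meta, tissue=tissue, group=case_label)
    if not ctrl or not case:
        raise ValueError(
            f"need samples in both groups ({control_label!r}: {len(ctrl)}, "
            f"{case_label!r}: {len(case)})"
        )
    df = matrix.values
    c_mean = df[ctrl].mean(axis=1, skipna=True).to_numpy()
    d_mean = df[case].mean(axis=1, skipna=True).to_numpy()
    defined = ~np.isnan(c_mean) & ~np.isnan(d_mean)
    up = defined & (d_mean > c_mean)
    down = defined & (d_mean < c_mean)
    ties = int(defined.sum() - up.sum() - down.sum())
    strict = up.sum() + down.sum()
    frac_all = 100.0 * up.sum() / strict if strict else float("nan")

    cols = ctrl + case
    y = np.array([0.0] * len(ctrl) + [1.0] * len(case))
    r = _pearson_rows(df[cols].to_numpy(), y)
    robust = defined & ~np.isnan(r) & (np.abs(r) > r_threshold)
    r_up = (robust & (d_mean > c_mean)).sum()
    r_strict = r_up + (robust & (d_mean < c_mean)).sum()
    frac_robust = 100.0 * r_up / r_strict if r_strict else float("nan")
    return GlobalTrend(
        frac_increased_all=float(frac_all),
        frac_increased_robust=float(frac_robust),
        n_sites_all=int(strict), n_sites_robust=int(r_strict),
        n_ties=ties, r_threshold=r_threshold,
    )


def delta_vs_pan_mean(
    matrix: MethylationMatrix,
    meta: pd.DataFrame,
    records: Sequence[UniqueSiteRecord],
    control_label: str,
    case_label: str,
) -> pd.DataFrame:
    """Distance of each group from the pan-tissue level, per site.

    Returns a table with ``control_delta`` and ``case_delta`` (group
    mean minus pan-tissue mean), the sign-rule call, the magnitude-rule
    call (regression iff |case - pan| < |control - pan|) and whether
    the two rules agree.  The magnitude rule also detects overshoot
    past the pan-tissue level, which the sign rule reads as regression.
    Sites without a pan-tissue mean are skipped.
    """
    calls, _ = call_direction_group(matrix, meta, records, control_label, case_label)
    pan_by_tissue = {
        t: pan_tissue_mean(matrix, meta, t) for t in {r.tissue for r in records}
    }
    rows = []
    for rec, call in zip(records, calls):
        pan = float(pan_by_tissue[rec.tissue].get(rec.site_id, np.nan))
        if np.isnan(pan) or call.call == "undefined":
            continue
        c_delta = call.control_mean - pan
        d_delta = call.case_mean - pan
        if abs(d_delta) < abs(c_delta):
            mag_call: Call = "regression"
        elif abs(d_delta) > abs(c_delta):
            mag_call = "divergence"
        else:
            mag_call = "tie"
        rows.append({
            "site_id": rec.site_id, "tissue": rec.tissue, "direction": rec.direction,
            "control_delta": c_delta, "case_delta": d_delta,
            "sign_call": call.call, "magnitude_call": mag_call,
            "agree": call.call == mag_call,
        })
    return pd.DataFrame(
        rows, columns=["site_id", "tissue", "direction", "control_delta",
                       "case_delta", "sign_call", "magnitude_call", "agree"],
    )
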
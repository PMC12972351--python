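"""Synthetic multi-tissue methylation cohorts with known ground truth.

The generator emits a sites x samples beta-value matrix whose statistical
structure mirrors what the downstream analyses assume about real array
data:

* a bimodal genome-wide background — most CpG sites are either mostly
  unmethylated or mostly methylated, with a minority at intermediate
  levels — shared across tissues;
* planted *tissue-unique* sites where one tissue's generating mean sits
  far below ("low") or above ("high") the level common to every other
  tissue, emulating the published single-tissue signatures;
* optional *erosion* of those signatures in a case group: the case
  generating mean is pulled toward (lambda > 0) or pushed away from
  (lambda < 0) the other-tissue level — regression to, or divergence
  from, the pan-tissue mean;
* optional age-correlated drift at the planted sites;
* per-observation Beta sampling noise with concentration kappa, i.e.
  value ~ Beta(mu*kappa, (1-mu)*kappa), matching the bounded, mean-
  dependent noise of beta values; and
* independent missing entries.

Everything is driven by one integer seed; identical configuration gives
bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MethylationMatrix, samples_of

MEAN_CLIP = (0.01, 0.99)  # keeps both Beta shape parameters positive

# generating-mean windows for planted unique sites; the displacement
# between the two windows always exceeds any admissible planted_margin
_LOW_TISSUE = (0.05, 0.15)
_LOW_OTHER = (0.70, 0.90)

_TISSUE_NAMES = (
    "liver", "kidney", "brain", "lung", "muscle",
    "adipose", "skin", "colon", "pancreas", "heart",
    "spleen", "thyroid", "bladder", "stomach", "breast",
)


class PlantedSite(NamedTuple):
    site_id: str
    tissue: str
    direction: Literal["low", "high"]
    clean_tissue_mean: float
    clean_other_mean: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design and effect sizes for one synthetic cohort.

    Attributes
    ----------
    n_tissues, samples_per_tissue_per_group, n_sites, n_unique_per_tissue
        Cohort dimensions.  Each tissue contributes a control and a case
        group of equal size; planted unique sites are split evenly
        between the low and high directions.
    planted_margin
        Minimum generating-mean displacement between the focal tissue
        and all other tissues at a planted site (beta-value units).
    concentration
        Beta-noise concentration kappa; observation SD near mu = 0.5 is
        roughly sqrt(0.25 / (kappa + 1)) (~0.07 at the default 50).
    erosion_lambda
        Case-group pull toward the other-tissue mean at planted sites:
        1 = full regression to the pan-tissue level, 0 = none, negative
        values amplify the tissue signature (divergence).
    age_slope
        Beta-value change per year at planted sites (sign is oriented
        per site so a positive value models regression to the mean).
    missing_rate
        Independent per-entry missing probability.
    """

    n_tissues: int = 8
    samples_per_tissue_per_group: int = 20
    n_sites: int = 20_000
    n_unique_per_tissue: int = 50
    planted_margin: float = 0.15
    concentration: float = 50.0
    erosion_lambda: float = 0.0
    age_slope: float = 0.0
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tissues", "samples_per_tissue_per_group", "n_sites"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.n_unique_per_tissue < 0:
            raise ValueError("n_unique_per_tissue must be non-negative")
        if self.n_unique_per_tissue * self.n_tissues > self.n_sites:
            raise ValueError(
                "n_unique_per_tissue x n_tissues exceeds n_sites: "
                f"{self.n_unique_per_tissue} x {self.n_tissues} > {self.n_sites}"
            )
        max_margin = _LOW_OTHER[0] - _LOW_TISSUE[1]
        if not (0 < self.planted_margin <= max_margin):
            raise ValueError(
                f"planted_margin must be in (0, {max_margin}] (got {self.planted_margin})"
            )
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not -1.0 <= self.erosion_lambda <= 1.0:
            raise ValueError("erosion_lambda must be in [-1, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted: the key for scoring every downstream stage."""

    unique_sites: list[PlantedSite]
    eroded_sites: list[tuple[str, float]]
    age_sites: list[tuple[str, int]]
    #: clean (pre-erosion, pre-drift) generating means, sites x tissues
    site_means: pd.DataFrame = field(repr=False)
    concentration: float = 50.0
    seed: int = 0

    def unique_ids(self, tissue: str | None = None) -> set[str]:
        return {
            p.site_id for p in self.unique_sites
            if tissue is None or p.tissue == tissue
        }


def _sub_rng(seed: int, *tags: object) -> np.random.Generator:
    """Deterministic sub-stream keyed on the seed plus string/number tags."""
    key = [int(seed) & 0x7FFFFFFF]
    key += [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(key)


def _background_means(n: int, rng: np.random.Generator) -> np.ndarray:
    """Bimodal genome-wide mixture: 45% low, 45% high, 10% uniform."""
    comp = rng.choice(3, size=n, p=[0.45, 0.45, 0.10])
    mu = np.empty(n)
    mu[comp == 0] = rng.beta(2, 8, size=(comp == 0).sum())
    mu[comp == 1] = rng.beta(8, 2, size=(comp == 1).sum())
    mu[comp == 2] = rng.uniform(0, 1, size=(comp == 2).sum())
    return np.clip(mu, *MEAN_CLIP)


def generate_multitissue(config: SyntheticConfig) -> tuple[MethylationMatrix, pd.DataFrame, GroundTruth]:
    """Generate a multi-tissue case/control cohort with planted signal.

    Returns the beta matrix, a sample-metadata table (indexed by
    sample_id, with tissue, group, age, sex, cell_type columns) and the
    :class:`GroundTruth` record of planted sites and applied effects.
    """
    cfg = config
    tissues = [
        _TISSUE_NAMES[i] if i < len(_TISSUE_NAMES) else f"tissue{i + 1:02d}"
        for i in range(cfg.n_tissues)
    ]
    site_ids = [f"cg{i:08d}" for i in range(cfg.n_sites)]

    rng_mu = _sub_rng(cfg.seed, "background")
    rng_plant = _sub_rng(cfg.seed, "plant")
    rng_meta = _sub_rng(cfg.seed, "meta")
    rng_obs = _sub_rng(cfg.seed, "observe")
    rng_miss = _sub_rng(cfg.seed, "missing")

    # clean generating means, sites x tissues
    background = _background_means(cfg.n_sites, rng_mu)
    means = np.tile(background[:, None], (1, cfg.n_tissues))

    planted: list[PlantedSite] = []
    if cfg.n_unique_per_tissue > 0:
        pool = rng_plant.permutation(cfg.n_sites)[: cfg.n_unique_per_tissue * cfg.n_tissues]
        for t_idx, tissue in enumerate(tissues):
            chunk = pool[t_idx * cfg.n_unique_per_tissue:(t_idx + 1) * cfg.n_unique_per_tissue]
            n_low = cfg.n_unique_per_tissue // 2 + cfg.n_unique_per_tissue % 2
            for j, s_idx in enumerate(chunk):
                direction = "low" if j < n_low else "high"
                mu_t = rng_plant.uniform(*_LOW_TISSUE)
                mu_o = rng_plant.uniform(*_LOW_OTHER)
                if direction == "high":
                    mu_t, mu_o = 1.0 - mu_t, 1.0 - mu_o
                means[s_idx, :] = mu_o
                means[s_idx, t_idx] = mu_t
                planted.append(PlantedSite(site_ids[s_idx], tissue, direction,
                                           float(mu_t), float(mu_o)))

    site_means = pd.DataFrame(means, index=site_ids, columns=tissues)

    # samples: control + case per tissue
    rows = []
    for tissue in tissues:
        for group in ("control", "case"):
            for k in range(cfg.samples_per_tissue_per_group):
                rows.append({
                    "sample_id": f"{tissue}_{group}_{k + 1:02d}",
                    "tissue": tissue,
                    "group": group,
                    "age": float(np.round(rng_meta.uniform(25, 85), 1)),
                    "sex": "F" if rng_meta.random() < 0.5 else "M",
                    "cell_type": "bulk",
                })
    meta = pd.DataFrame(rows).set_index("sample_id")

    # per-sample generating means with erosion and age drift
    t_index = {t: i for i, t in enumerate(tissues)}
    sample_mu = np.empty((cfg.n_sites, len(meta)))
    for j, (sid, row) in enumerate(meta.iterrows()):
        sample_mu[:, j] = means[:, t_index[row["tissue"]]]

    eroded: list[tuple[str, float]] = []
    site_pos = {s: i for i, s in enumerate(site_ids)}
    if cfg.erosion_lambda != 0.0 and planted:
        case_cols = {
            t: [j for j, (_, r) in enumerate(meta.iterrows())
                if r["tissue"] == t and r["group"] == "case"]
            for t in tissues
        }
        for p in planted:
            i = site_pos[p.site_id]
            target = p.clean_tissue_mean + cfg.erosion_lambda * (
                p.clean_other_mean - p.clean_tissue_mean)
            sample_mu[i, case_cols[p.tissue]] = np.clip(target, *MEAN_CLIP)
            eroded.append((p.site_id, cfg.erosion_lambda))

    age_sites: list[tuple[str, int]] = []
    if cfg.age_slope != 0.0 and planted:
        ages = meta["age"].to_numpy(float)
        mean_age = ages.mean()
        tissue_cols = {
            t: [j for j, (_, r) in enumerate(meta.iterrows()) if r["tissue"] == t]
            for t in tissues
        }
        for p in planted:
            i = site_pos[p.site_id]
            sign = 1 if p.direction == "low" else -1
            cols = tissue_cols[p.tissue]
            shift = sign * cfg.age_slope * (ages[cols] - mean_age)
            sample_mu[i, cols] = np.clip(sample_mu[i, cols] + shift, *MEAN_CLIP)
            age_sites.append((p.site_id, sign))

    kappa = cfg.concentration
    values = rng_obs.beta(sample_mu * kappa, (1.0 - sample_mu) * kappa)
    if cfg.missing_rate > 0:
        mask = rng_miss.random(values.shape) < cfg.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = MethylationMatrix(
        pd.DataFrame(values, index=pd.Index(site_ids, name="site_id"), columns=meta.index)
    )
    truth = GroundTruth(
        unique_sites=planted, eroded_sites=eroded, age_sites=age_sites,
        site_means=site_means, concentration=kappa, seed=cfg.seed,
    )
    return matrix, meta, truth


def _resample_shifted(
    matrix: MethylationMatrix,
    row_pos: np.ndarray,
    col_pos: np.ndarray,
    new_means: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> MethylationMatrix:
    """Redraw the (row, col) block from Beta at ``new_means``.

    Uses inverse-CDF sampling on uniforms drawn independently of the
    shift, so for a fixed seed the redrawn values are monotone in the
    generating mean (the Beta family at fixed concentration is
    stochastically ordered in its mean).  The missing pattern is kept.
    """
    arr = matrix.values.to_numpy().copy()
    u = rng.random((len(row_pos), len(col_pos)))
    mu = np.clip(new_means, *MEAN_CLIP)
    block = stats.beta.ppf(u, mu * kappa, (1.0 - mu) * kappa)
    old = arr[np.ix_(row_pos, col_pos)]
    arr[np.ix_(row_pos, col_pos)] = np.where(np.isnan(old), np.nan, block)
    return MethylationMatrix(
        pd.DataFrame(arr, index=matrix.site_ids, columns=matrix.sample_ids)
    )


def apply_erosion(
    matrix: MethylationMatrix,
    meta: pd.DataFrame,
    truth: GroundTruth,
    tissue: str,
    group_label: str,
    erosion_lambda: float,
) -> MethylationMatrix:
    """Erode one tissue's unique-site signature in one sample group.

    The generating mean at every planted unique site of ``tissue`` is
    moved from mu_tissue to ``mu_tissue + lambda * (mu_other -
    mu_tissue)`` for the samples of ``group_label``, then the affected
    entries are redrawn from the Beta observation model.  lambda = 1
    places the group at the pan-tissue level in expectation; negative
    lambda amplifies the deviation (clipped so the mean stays in (0, 1)).
    """
    if not -1.0 <= erosion_lambda <= 1.0:
        raise ValueError(f"erosion lambda must be in [-1, 1], got {erosion_lambda}")
    cols = samples_of(meta, tissue=tissue, group=group_label)
    if not cols:
        raise ValueError(f"no samples with tissue={tissue!r}, group={group_label!r}")
    sites = [p for p in truth.unique_sites if p.tissue == tissue]
    if not sites:
        return matrix

    row_pos = np.array([matrix.site_ids.get_loc(p.site_id) for p in sites])
    col_pos = np.array([matrix.sample_ids.get_loc(c) for c in cols])
    targets = np.array([
        p.clean_tissue_mean + erosion_lambda * (p.clean_other_mean - p.clean_tissue_mean)
        for p in sites
    ])
    new_means = np.tile(targets[:, None], (1, len(col_pos)))
    rng = _sub_rng(truth.seed, "erode", tissue, group_label)
    return _resample_shifted(matrix, row_pos, col_pos, new_means,
                             truth.concentration, rng)


def apply_age_drift(
    matrix: MethylationMatrix,
    meta: pd.DataFrame,
    truth: GroundTruth,
    sites: Sequence[str],
    slope: float,
    ages: pd.Series | None = None,
) -> MethylationMatrix:
    """Add age-correlated drift at the given sites and redraw them.

    For a planted unique site the drift applies to its focal tissue's
    samples and its sign is oriented so a positive ``slope`` models
    regression to the mean (low-direction sites gain methylation with
    age, high-direction sites lose it); any other site drifts with the
    raw sign across all samples.  Ages default to the metadata ``age``
    column and must be defined for every affected sample.
    """
    if ages is None:
        if "age" not in meta.columns:
            raise ValueError("no ages given and metadata has no 'age' column")
        ages = meta["age"]
    ages = ages.astype(float)

    planted_by_id = {p.site_id: p for p in truth.unique_sites}
    arr_matrix = matrix
    mean_lookup = truth.site_means

    # group sites by (tissue-or-all, sign) so each block is one redraw
    for site_id in sites:
        if site_id not in matrix.site_ids:
            raise KeyError(f"site {site_id!r} not in matrix")

    for k, site_id in enumerate(sites):
        p = planted_by_id.get(site_id)
        if p is None:
            cols = list(meta.index)
            sign = 1
            base = mean_lookup.loc[site_id].to_numpy().mean()
            base_per_col = np.array([
                mean_lookup.loc[site_id, meta.loc[c, "tissue"]] for c in cols
            ])
        else:
            cols = samples_of(meta, tissue=p.tissue)
            sign = 1 if p.direction == "low" else -1
            base_per_col = np.full(len(cols), p.clean_tissue_mean)
        col_ages = ages.reindex(cols)
        if col_ages.isna().any():
            missing = col_ages.index[col_ages.isna()][0]
            raise ValueError(f"age missing for affected sample {missing!r}")
        shift = sign * slope * (col_ages.to_numpy() - col_ages.mean())
        new_means = (base_per_col + shift)[None, :]
        row_pos = np.array([arr_matrix.site_ids.get_loc(site_id)])
        col_pos = np.array([arr_matrix.sample_ids.get_loc(c) for c in cols])
        rng = _sub_rng(truth.seed, "agedrift", site_id)
        arr_matrix = _resample_shifted(arr_matrix, row_pos, col_pos, new_means,
                                       truth.concentration, rng)
    return arr_matrix
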
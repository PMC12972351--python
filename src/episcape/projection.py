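"""PCA projection of samples on a site set and distance-model classification.

Samples are observations and CpG sites dimensions; the data are
mean-centered per site (no variance scaling by default — beta values
share a scale) and projected onto 2 or 3 principal components.  Three
distance models classify a projected sample against labeled reference
coordinates:

``ratio``
    Mean Euclidean distance to the healthy members vs to the sick
    members; the smaller mean wins.
``centroid``
    Distance to each group's center of mass (unweighted mean of member
    coordinates); the nearer centroid wins.
``radius2sd``
    Sick iff the distance to the sick centroid is less than twice the
    sick group's standard deviation about its own centroid (the RMS
    member-to-centroid distance; an alternative reading — the SD of the
    scalar member distances — is available via ``spread="distance_sd"``).

Accuracy is estimated by leave-one-out validation: the component basis
is refit without the held-out sample, which is then projected with the
retained loadings and classified against the remaining samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .matrix import MethylationMatrix

logger = logging.getLogger(__name__)

Model = Literal["ratio", "centroid", "radius2sd"]
MODELS: tuple[Model, ...] = ("ratio", "centroid", "radius2sd")


@dataclass
class ProjectionModel:
    """A fitted principal-component basis over a fixed site set.

    ``loadings`` has shape (n_components, n_sites), rows orthonormal;
    the sign convention makes each component's largest-magnitude
    loading positive, so fits are deterministic.
    """

    site_ids: list[str]
    means: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    dropped_sites: list[str] = field(default_factory=list)
    scaled: bool = False
    scales: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_projection(
    matrix: MethylationMatrix,
    site_ids: Sequence[str],
    n_components: int = 2,
    sample_ids: Sequence[str] | None = None,
    scale: bool = False,
) -> ProjectionModel:
    """Fit a PCA basis on the given sites over the training samples.

    Sites with any missing value among the training samples are dropped
    (and recorded) rather than imputed.  Raises when fewer sites than
    components survive, or when there are not at least
    ``n_components + 1`` samples.
    """
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    site_ids = [str(s) for s in site_ids]
    sub = matrix.select_sites(site_ids)
    if sample_ids is not None:
        sub = sub.select_samples(list(sample_ids))
    if sub.shape[1] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} samples, got {sub.shape[1]}"
        )
    complete = sub.values.notna().all(axis=1)
    dropped = [str(s) for s in sub.site_ids[~complete]]
    if dropped:
        logger.info("fit_projection dropped %d sites with missing values", len(dropped))
    kept = [s for s in site_ids if s not in set(dropped)]
    if len(kept) < n_components:
        raise ValueError(
            f"only {len(kept)} complete sites remain, fewer than "
            f"{n_components} components"
        )
    x = sub.values.loc[kept].to_numpy().T  # samples x sites
    scales = None
    if scale:
        scales = x.std(axis=0, ddof=0)
        scales[scales == 0] = 1.0
        x = x / scales
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    loadings = pca.components_.copy()
    for c in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[c]))
        if loadings[c, j] < 0:
            loadings[c] = -loadings[c]
    return ProjectionModel(
        site_ids=kept, means=pca.mean_.copy(), loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        dropped_sites=dropped, scaled=scale, scales=scales,
    )


def _sample_vector(model: ProjectionModel, values: "pd.Series | dict | np.ndarray") -> np.ndarray:
    if isinstance(values, dict):
        values = pd.Series(values)
    if isinstance(values, pd.Series):
        v = values.reindex(model.site_ids)
        if v.isna().any():
            missing = v.index[v.isna()][0]
            raise ValueError(f"sample is missing a value for model site {missing!r}")
        v = v.to_numpy(float)
    else:
        v = np.asarray(values, dtype=float)
        if v.shape != (len(model.site_ids),):
            raise ValueError(
                f"expected {len(model.site_ids)} values, got shape {v.shape}"
            )
        if np.isnan(v).any():
            missing = model.site_ids[int(np.argmax(np.isnan(v)))]
            raise ValueError(f"sample is missing a value for model site {missing!r}")
    return v


def project_sample(model: ProjectionModel, values) -> np.ndarray:
    """Project one sample (site -> beta mapping or aligned vector)."""
    v = _sample_vector(model, values)
    if model.scaled and model.scales is not None:
        v = v / model.scales
    return (v - model.means) @ model.loadings.T


def project_samples(model: ProjectionModel, matrix: MethylationMatrix,
                    sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Project many samples; returns a (samples x components) frame."""
    ids = list(sample_ids) if sample_ids is not None else list(matrix.sample_ids)
    coords = np.vstack([
        project_sample(model, matrix.values.loc[model.site_ids, s]) for s in ids
    ])
    cols = [f"PC{i + 1}" for i in range(model.n_components)]
    return pd.DataFrame(coords, index=pd.Index(ids, name="sample_id"), columns=cols)


# ---------------------------------------------------------------------------
# distance-model classification
# ---------------------------------------------------------------------------

def classify_sample(
    coords: np.ndarray,
    healthy_coords: np.ndarray,
    sick_coords: np.ndarray,
    model: Model = "ratio",
    spread: Literal["rms", "distance_sd"] = "rms",
) -> Literal["healthy", "sick"]:
    """Assign a projected sample to the healthy or sick group.

    Ties break to healthy (conservative toward no-disease).  The
    ``radius2sd`` model needs at least two sick members to define the
    spread of the sick group.
    """
    coords = np.asarray(coords, float)
    healthy = np.atleast_2d(np.asarray(healthy_coords, float))
    sick = np.atleast_2d(np.asarray(sick_coords, float))
    if healthy.shape[0] == 0 or sick.shape[0] == 0:
        raise ValueError("both reference groups must be non-empty")

    if model == "ratio":
        d_h = np.linalg.norm(healthy - coords, axis=1).mean()
        d_s = np.linalg.norm(sick - coords, axis=1).mean()
        return "sick" if d_s < d_h else "healthy"
    if model == "centroid":
        d_h = np.linalg.norm(healthy.mean(axis=0) - coords)
        d_s = np.linalg.norm(sick.mean(axis=0) - coords)
        return "sick" if d_s < d_h else "healthy"
    if model == "radius2sd":
        if sick.shape[0] < 2:
            raise ValueError(
                "radius2sd needs >= 2 sick reference samples to define an SD"
            )
        centroid = sick.mean(axis=0)
        dists = np.linalg.norm(sick - centroid, axis=1)
        sd = np.sqrt(np.mean(dists**2)) if spread == "rms" else dists.std(ddof=0)
        if sd == 0.0:
            raise ValueError("sick reference group is degenerate (zero spread)")
        return "sick" if np.linalg.norm(coords - centroid) < 2.0 * sd else "healthy"
    raise ValueError(f"unknown classification model: {model!r}")


@dataclass
class ClassifierReport:
    """Leave-one-out classification outcome for one distance model."""

    model: Model
    table: pd.DataFrame  # sample_id index; true, predicted, PC coords
    confusion: dict[tuple[str, str], int]
    accuracy: float  # percent

    @property
    def n_samples(self) -> int:
        return len(self.table)


def loo_accuracy(
    matrix: MethylationMatrix,
    meta: pd.DataFrame,
    site_ids: Sequence[str],
    label_pair: tuple[str, str],
    model: Model = "ratio",
    n_components: int = 2,
) -> ClassifierReport:
    """Leave-one-out accuracy of one distance model.

    ``label_pair`` is (healthy_label, sick_label), matched against the
    metadata ``group`` column.  Each iteration refits the component
    basis without the held-out sample, projects it with the retained
    loadings, and classifies it against the coordinates of the
    remaining labeled samples.
    """
    healthy_label, sick_label = label_pair
    sel = meta["group"].isin(label_pair)
    ids = [s for s in matrix.sample_ids if sel.get(s, False)]
    truth = meta.loc[ids, "group"]
    for label in label_pair:
        if (truth == label).sum() < 2:
            raise ValueError(f"need >= 2 samples labeled {label!r} for leave-one-out")

    rows = []
    for held in ids:
        rest = [s for s in ids if s != held]
        try:
            pm = fit_projection(matrix, site_ids, n_components=n_components,
                                sample_ids=rest)
            ref = project_samples(pm, matrix, rest)
            coords = project_sample(pm, matrix.values.loc[pm.site_ids, held])
            healthy = ref.loc[[s for s in rest if truth[s] == healthy_label]].to_numpy()
            sick = ref.loc[[s for s in rest if truth[s] == sick_label]].to_numpy()
            pred_hs = classify_sample(coords, healthy, sick, model=model)
        except ValueError as exc:
            raise ValueError(f"leave-one-out failed at sample {held!r}: {exc}") from exc
        pred = healthy_label if pred_hs == "healthy" else sick_label
        rows.append({"sample_id": held, "true": truth[held], "predicted": pred,
                     **{f"PC{i + 1}": float(c) for i, c in enumerate(coords)}})

    table = pd.DataFrame(rows).set_index("sample_id")
    confusion: dict[tuple[str, str], int] = {}
    for t in label_pair:
        for p in label_pair:
            confusion[(t, p)] = int(((table["true"] == t) & (table["predicted"] == p)).sum())
    accuracy = 100.0 * (table["true"] == table["predicted"]).mean()
    return ClassifierReport(model=model, table=table, confusion=confusion,
                            accuracy=float(accuracy))
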
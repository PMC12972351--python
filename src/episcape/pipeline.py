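"""End-to-end runs: read -> filter -> unique sites -> erosion / classify.

A :class:`RunConfig` (built in code, from CLI flags, or from a YAML
file whose keys match the field names) drives the stages in order and
writes CSV artifacts plus a machine-readable ``manifest.json`` to the
output directory.  Every CSV carries a comment header embedding the
tool version, the seed and the criterion parameters, so a run is
reproducible from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .erosion import (
    ErosionSummary,
    call_direction_correlation,
    call_direction_group,
)
from .io import (
    filter_probes,
    read_beta_matrix,
    read_probe_blacklist,
    read_sample_meta,
)
from .projection import MODELS, loo_accuracy
from .unique import (
    UniqueCriterion,
    identify_unique_sites,
    records_from_frame,
    records_to_frame,
    select_control_sites,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs."""

    matrix: str
    meta: str
    out_dir: str
    records: str | None = None
    blacklist: str | None = None
    matrix_format: str = "tsv"
    # uniqueness criterion
    margin: float = 0.1
    quantile: float = 0.05
    center: str = "mean"
    min_valid: float = 0.5
    # analysis
    mode: str = "group"  # group | correlation
    control_label: str = "control"
    case_label: str = "case"
    covariate: str = "age"
    min_abs_r: float | None = None
    models: tuple[str, ...] = ()
    site_mode: str = "unique"  # unique | random | high_variability | low_variability
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "models" in data and data["models"] is not None:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def criterion(self) -> UniqueCriterion:
        min_valid = self.min_valid
        if isinstance(min_valid, float) and min_valid >= 1:
            min_valid = int(min_valid)
        return UniqueCriterion(margin=self.margin, quantile=self.quantile,
                               center=self.center, min_valid=min_valid)

    def validate_paths(self) -> None:
        for name in ("matrix", "meta", "records", "blacklist"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _header_lines(config: RunConfig, extra: dict | None = None) -> str:
    pairs = {
        "episcape_version": __version__,
        "seed": config.seed,
        "margin": config.margin,
        "quantile": config.quantile,
        "center": config.center,
        "min_valid": config.min_valid,
    }
    if extra:
        pairs.update(extra)
    return "".join(f"# {k} = {v}\n" for k, v in pairs.items())


def write_csv(df: pd.DataFrame, path: Path, config: RunConfig,
              extra: dict | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config, extra))
        df.to_csv(fh, index=index, lineterminator="\n")


def read_result_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the '#' comment header."""
    return pd.read_csv(path, comment="#")


def summary_frame(summary: ErosionSummary) -> pd.DataFrame:
    rows = [{"subset": "all", **_summary_row(summary)}]
    for d, sub in summary.by_direction.items():
        rows.append({"subset": d, **_summary_row(sub)})
    return pd.DataFrame(rows)


def _summary_row(s: ErosionSummary) -> dict:
    return {
        "n_evaluated": s.n_evaluated, "n_regression": s.n_regression,
        "n_divergence": s.n_divergence, "n_tie": s.n_tie,
        "n_undefined": s.n_undefined,
        "fraction_regression_pct": s.fraction_regression,
        "majority": s.majority, "log10_p": s.log10_p,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    Stage order: read matrix and metadata, optional probe-blacklist
    filter, unique-site identification (or loading of an existing
    record table), then the requested analysis — group or correlation
    direction calls with the binomial summary, and/or leave-one-out
    classification for the selected distance models.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "episcape_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "outputs": {},
    }

    matrix = read_beta_matrix(config.matrix, format=config.matrix_format)
    meta = read_sample_meta(config.meta, matrix)
    if config.blacklist:
        matrix = filter_probes(matrix, read_probe_blacklist(config.blacklist))

    if config.records:
        records = records_from_frame(read_result_csv(config.records))
        logger.info("loaded %d unique-site records", len(records))
    else:
        records = identify_unique_sites(matrix, meta, config.criterion())
        logger.info("identified %d unique-site records", len(records))
    rec_path = out_dir / "unique_sites.csv"
    write_csv(records_to_frame(records), rec_path, config)
    manifest["outputs"]["unique_sites"] = rec_path.name
    manifest["n_unique_records"] = len(records)

    if config.mode == "group":
        calls, summary = call_direction_group(
            matrix, meta, records, config.control_label, config.case_label)
        calls_df = pd.DataFrame([c.__dict__ for c in calls])
    elif config.mode == "correlation":
        calls, summary = call_direction_correlation(
            matrix, meta, records, covariate=config.covariate,
            min_abs_r=config.min_abs_r,
            group_labels=(config.control_label, config.case_label)
            if config.covariate == "group" else None,
        )
        calls_df = pd.DataFrame([c.__dict__ for c in calls])
    else:
        raise ValueError(f"unknown analysis mode: {config.mode!r}")

    calls_path = out_dir / "direction_calls.csv"
    write_csv(calls_df, calls_path, config, {"mode": config.mode})
    summary_path = out_dir / "erosion_summary.csv"
    write_csv(summary_frame(summary), summary_path, config, {"mode": config.mode})
    manifest["outputs"]["direction_calls"] = calls_path.name
    manifest["outputs"]["erosion_summary"] = summary_path.name
    manifest["fraction_regression_pct"] = summary.fraction_regression
    manifest["log10_p"] = summary.log10_p

    models = config.models
    if models == ("all",):
        models = MODELS
    if models:
        site_ids = _analysis_sites(config, matrix, meta, records)
        manifest["classifier"] = {}
        for model in models:
            report = loo_accuracy(matrix, meta, site_ids,
                                  (config.control_label, config.case_label),
                                  model=model)
            path = out_dir / f"classifier_{model}.csv"
            write_csv(report.table, path, config,
                      {"model": model, "accuracy_pct": report.accuracy},
                      index=True)
            manifest["outputs"][f"classifier_{model}"] = path.name
            manifest["classifier"][model] = report.accuracy

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _analysis_sites(config: RunConfig, matrix, meta, records) -> list[str]:
    unique_ids = sorted({r.site_id for r in records})
    if config.site_mode == "unique":
        return unique_ids
    return select_control_sites(
        matrix, n=len(unique_ids), mode=config.site_mode,
        exclude=set(unique_ids), seed=config.seed,
    )
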
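"""Reading and writing beta matrices, metadata, blacklists and BED exports.

Supported matrix formats:

``tsv``
    Plain tab-separated table, sites as rows, samples as columns, first
    column holding the site identifier.

``series_matrix``
    The GEO Series Matrix dialect: header lines, then a table delimited
    by the ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
    sentinel lines with an ``ID_REF`` identifier column.  Everything
    outside the sentinels is ignored.

Missing-value sentinels accepted on read: empty string, ``NA``, ``NaN``,
``null`` (case-insensitive).  Missing values are written as ``NA`` and
floats with 6 significant digits, so a write -> read round trip is the
identity up to that documented precision.

BED export uses 0-based half-open coordinates (note that the Illumina
array manifests are 1-based: positions taken from a manifest are
interpreted as 0-based here; convert before constructing the manifest
if your source is 1-based).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .matrix import MethylationMatrix, validate_sample_meta

logger = logging.getLogger(__name__)

NA_SENTINELS = ["", "NA", "Na", "na", "nA", "NaN", "NAN", "nan", "null", "NULL", "Null"]
_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path, format: str = "tsv") -> MethylationMatrix:
    """Read a beta-value matrix from ``path``.

    Unparsable or sentinel entries become missing; row and column order
    is preserved from the file.  Duplicate identifiers and values
    outside [0, 1] (beyond float-text tolerance) are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    if format == "tsv":
        df = pd.read_csv(
            path, sep="\t", index_col=0,
            na_values=NA_SENTINELS, keep_default_na=False,
        )
    elif format == "series_matrix":
        df = _read_series_matrix_table(path)
    else:
        raise ValueError(f"unknown matrix format: {format!r}")
    df.index = df.index.astype(str)
    df.index.name = "site_id"
    return MethylationMatrix(df)


def _read_series_matrix_table(path: Path) -> pd.DataFrame:
    lines: list[str] = []
    inside = False
    seen_begin = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.lower().startswith(_TABLE_BEGIN):
                inside, seen_begin = True, True
                continue
            if stripped.lower().startswith(_TABLE_END):
                inside = False
                continue
            if inside and stripped:
                lines.append(line)
    if not seen_begin:
        raise ValueError(f"no {_TABLE_BEGIN} sentinel found in {path}")
    if not lines:
        raise ValueError(f"empty series-matrix table in {path}")
    df = pd.read_csv(
        _io.StringIO("".join(lines)), sep="\t", index_col=0,
        na_values=NA_SENTINELS, keep_default_na=False, quotechar='"',
    )
    if str(df.index.name).strip('"') != "ID_REF":
        raise ValueError(
            f"series-matrix table must have an ID_REF column, got {df.index.name!r}"
        )
    df.index = df.index.astype(str).str.strip('"')
    return df


def write_beta_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with NA for missing, 6 significant digits."""
    matrix.values.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path: str | Path, matrix: MethylationMatrix | None = None) -> pd.DataFrame:
    """Read a TSV metadata table (sample_id, tissue, group, [age, sex, ...])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    meta = pd.read_csv(path, sep="\t", na_values=NA_SENTINELS, keep_default_na=False)
    return validate_sample_meta(meta, matrix)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# probe blacklists
# ---------------------------------------------------------------------------

def read_probe_blacklist(path: str | Path) -> set[str]:
    """One site id per line; '#' comment lines ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split("\t")[0])
    return out


def filter_probes(matrix: MethylationMatrix, blacklist: Iterable[str]) -> MethylationMatrix:
    """Drop blacklisted sites (e.g. cross-reactive probes).

    An empty intersection is allowed; the number of removed rows is
    logged, and removing every site emits a warning.
    """
    blacklist = set(blacklist)
    out = matrix.drop_sites(blacklist)
    removed = matrix.shape[0] - out.shape[0]
    logger.info("filter_probes removed %d of %d sites", removed, matrix.shape[0])
    if out.shape[0] == 0 and matrix.shape[0] > 0:
        logger.warning("probe blacklist removed every site in the matrix")
    return out


# ---------------------------------------------------------------------------
# probe manifest and BED export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeManifest:
    """Genomic placement of array probes: site_id -> (chrom, pos, strand).

    Positions are 0-based; export is 0-based half-open single-base
    intervals (BED convention).
    """

    table: pd.DataFrame  # index site_id; columns chrom, pos, strand
    assembly: str = "hg19"

    def __post_init__(self) -> None:
        for col in ("chrom", "pos", "strand"):
            if col not in self.table.columns:
                raise ValueError(f"probe manifest is missing column {col!r}")
        if (self.table["pos"] < 0).any():
            raise ValueError("probe manifest contains a negative position")

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.table.index


def read_probe_manifest(path: str | Path, assembly: str = "hg19") -> ProbeManifest:
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    if "site_id" in tab.columns:
        tab = tab.set_index("site_id")
    return ProbeManifest(tab, assembly=assembly)


def export_sites_bed(records: Sequence, manifest: ProbeManifest, path: str | Path) -> int:
    """Write unique-site records as a BED file; returns lines written.

    Score encodes direction: 0 = low (hypomethylated in the tissue),
    1000 = high.  Records absent from the manifest are skipped with a
    warning.
    """
    known = {"hg19", "hg38", "GRCh37", "GRCh38"}
    if manifest.assembly not in known:
        raise ValueError(f"unmapped assembly label: {manifest.assembly!r}")
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if rec.site_id not in manifest:
                logger.warning("site %s not in probe manifest; skipped", rec.site_id)
                continue
            row = manifest.table.loc[rec.site_id]
            score = 0 if rec.direction == "low" else 1000
            start = int(row["pos"])
            fh.write(
                f"{row['chrom']}\t{start}\t{start + 1}\t{rec.site_id}\t{score}\t{row['strand']}\n"
            )
            n += 1
    return n
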
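"""TSV readers/writers for every artifact the pipeline emits.

Matrices are analyte x sample TSVs: first column = analyte id, header row =
sample ids; empty cells or a configurable sentinel (default "NA") denote
missing values. TSV is used throughout because metabolite feature ids can
contain commas in adduct annotations.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth
from .types import (
    DatasetTag,
    EigengeneTable,
    FilterReport,
    ModulePartition,
    OmicsMatrix,
    SampleMetadata,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_partition",
    "write_partition",
    "read_ground_truth",
    "write_ground_truth",
    "read_gmt",
    "sha256_file",
]

MISSING_SENTINELS = ("", "NA")


def read_matrix(
    path, dataset_tag: DatasetTag | str, missing_sentinel: str = "NA"
) -> OmicsMatrix:
    """Read an analyte x sample TSV into an OmicsMatrix.

    Duplicate analyte/sample ids, ragged rows and negative values raise;
    empty cells and ``missing_sentinel`` both parse to missing.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_header = header[1:]
    if len(set(sample_header)) != len(sample_header):
        dups = sorted({s for s in sample_header if sample_header.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    na_values = sorted({missing_sentinel, ""})
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=na_values,
        keep_default_na=False,
        dtype=str,
    )
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate analyte ids {dups}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    values.index.name = "analyte_id"
    return OmicsMatrix(DatasetTag(dataset_tag), values)


def write_matrix(matrix: OmicsMatrix, path, missing_sentinel: str = "NA") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.values.copy()
    out.index.name = "analyte_id"
    out.to_csv(path, sep="\t", na_rep=missing_sentinel, float_format="%.10g")
    return path


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(Path(path), sep="\t", index_col=0, dtype={"is_qc": str})
    df["is_qc"] = df["is_qc"].str.lower().isin(("true", "1", "yes"))
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = metadata.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    return path


def read_partition(path) -> ModulePartition:
    df = pd.read_csv(Path(path), sep="\t", index_col=0, dtype=str)
    return ModulePartition(df)


def write_partition(partition: ModulePartition, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = partition.table.copy()
    out.index.name = "analyte_id"
    out.to_csv(path, sep="\t")
    return path


def write_ground_truth(truth: GroundTruth, path) -> Path:
    """Sidecar TSV: analyte_id, dataset, module_id, module_trait."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = truth.partition.copy()
    out.index.name = "analyte_id"
    out.to_csv(path, sep="\t")
    lat = path.with_suffix(".activities.tsv")
    truth.latent_activities.rename_axis("module_id").to_csv(
        lat, sep="\t", float_format="%.10g"
    )
    return path


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    part = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    traits = (
        part.loc[part["module_id"] != "background"]
        .drop_duplicates("module_id")
        .set_index("module_id")["module_trait"]
        .to_dict()
    )
    lat_path = path.with_suffix(".activities.tsv")
    latent = (
        pd.read_csv(lat_path, sep="\t", index_col=0)
        if lat_path.exists()
        else pd.DataFrame()
    )
    return GroundTruth(part, traits, latent)


def write_filter_report(report: FilterReport, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = report.table.copy()
    out.index.name = "analyte_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")
    return path


def write_eigengenes(eigengenes: EigengeneTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = eigengenes.values.copy()
    out["variance_explained"] = eigengenes.variance_explained
    out.index.name = "module_colour"
    out.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: name <tab> description <tab> member ids...; one per line."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line[:80]!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name: {name}")
        sets[name] = set(f for f in fields[2:] if f)
    return sets


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
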
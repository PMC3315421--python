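"""Table I/O with schema validation, truth records, Newick export, manifests.

All tables are UTF-8 delimited text with one header row: CSV for narrow
observation tables, TSV for matrices. Extra columns are tolerated and
logged; missing required columns raise a schema error naming the column.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .microarray import ClusterOrdering

log = logging.getLogger("regenkit")

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "write_truth_record",
    "read_truth_record",
    "cluster_to_newick",
    "write_manifest",
]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


#: schema name -> (required columns, numeric columns, delimiter)
SCHEMAS: dict[str, tuple[list[str], list[str], str]] = {
    "ct": (
        ["sample_id", "condition", "time_hr", "gene_role", "gene_name", "replicate", "ct", "dilution"],
        ["time_hr", "ct", "dilution"],
        ",",
    ),
    "neurite": (
        ["cell_id", "neurite_class", "treatment", "time_hr", "length_um"],
        ["time_hr", "length_um"],
        ",",
    ),
    "locomotion": (
        ["snail_id", "group", "day", "distance_cm"],
        ["day", "distance_cm"],
        ",",
    ),
    "group_summary": (
        ["group", "mean", "sem", "n"],
        ["mean", "sem", "n"],
        ",",
    ),
    "expression_matrix": (
        ["probe_id", "gene_id", "replicate_group"],
        [],
        "\t",
    ),
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited table against a named schema.

    Extra columns are kept but logged; for the ``expression_matrix`` schema
    every non-annotation column is an array column and must be numeric.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    required, numeric, sep = SCHEMAS[schema]
    path = Path(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if schema == "expression_matrix":
        numeric = extra
        extra = []
    if extra:
        log.info("%s: ignoring %d extra column(s): %s", path.name, len(extra), extra)
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise SchemaError(f"{path.name}: unparsable numeric value in column {col!r} near line {line}") from exc
    log.info("%s: read %d rows (%s schema)", path.name, len(df), schema)
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> Path:
    """Write a table in the schema's dialect (TSV for matrices, CSV otherwise)."""
    sep = SCHEMAS[schema][2] if schema else ","
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
    return path


def write_truth_record(truth: dict, path: str | Path, dataset_id: str = "dataset") -> Path:
    """Persist a generator's ground-truth record as YAML, keyed by dataset id.

    Truth lives in its own file so analysis pipelines reading the data table
    cannot see it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({dataset_id: _plain(truth)}, fh, sort_keys=True)
    return path


def read_truth_record(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def cluster_to_newick(ordering: ClusterOrdering) -> str:
    """Serialize an agglomerative merge tree as a Newick string with branch
    lengths derived from merge heights."""
    tree = TreeNode.from_linkage_matrix(ordering.linkage, ordering.labels)
    return str(tree).strip()


def write_manifest(out_dir: str | Path, files: list[Path], *, name: str = "MANIFEST.txt") -> Path:
    """Write a manifest of artifacts with SHA-256 content hashes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    for f in files:
        digest = hashlib.sha256(Path(f).read_bytes()).hexdigest()
        lines.append(f"{digest}  {Path(f).name}")
    manifest = out_dir / name
    manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest
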
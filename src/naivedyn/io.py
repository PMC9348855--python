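"""Dataset readers, schema validation, configuration and manifests.

CSV is the single tabular interchange format.  Each schema declares its
required columns and row-level validation rules; violations are collected
into a report and reading fails hard unless invalid rows are explicitly
dropped.  Run manifests (JSON) record input hashes, the seed and the
package version so every output is reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

PACKAGE_VERSION = "0.1.0"

SCHEMAS = {
    "sp": {
        "columns": ["mouse_age_days", "subset", "sp_count", "sp_ki67_frac"],
        "rules": {
            "mouse_age_days": lambda v: v > 0,
            "sp_count": lambda v: v >= 0,
            "sp_ki67_frac": lambda v: 0 <= v <= 1,
        },
    },
    "chimera": {
        "columns": ["mouse_id", "host_age", "age_at_bmt", "subset",
                    "total_count", "fd", "ki67_host", "ki67_donor"],
        "rules": {
            "host_age": lambda v: v > 0,
            "age_at_bmt": lambda v: v >= 0,
            "total_count": lambda v: v > 0,
            "fd": lambda v: 0 <= v <= 1,
            "ki67_host": lambda v: 0 <= v <= 1,
            "ki67_donor": lambda v: 0 <= v <= 1,
        },
        "row_rules": {
            "host_age>age_at_bmt": lambda r: r["host_age"] > r["age_at_bmt"],
        },
    },
    "cohort": {
        "columns": ["mouse_id", "group_age_days", "time_since_label_days",
                    "labelled_count"],
        "rules": {
            "group_age_days": lambda v: v > 0,
            "time_since_label_days": lambda v: v >= 0,
            "labelled_count": lambda v: v >= 0,
        },
    },
    "reporter": {
        "columns": ["t_days", "gfp_count", "pct_gfp_ki67pos", "pct_gfp_ki67neg"],
        "rules": {
            "t_days": lambda v: v > 0,
            "gfp_count": lambda v: v >= 0,
            "pct_gfp_ki67pos": lambda v: 0 <= v <= 100,
            "pct_gfp_ki67neg": lambda v: 0 <= v <= 100,
        },
    },
}

__all__ = ["read_dataset", "ValidationReport", "SCHEMAS", "write_manifest",
           "load_config"]


@dataclass
class ValidationReport:
    schema: str
    n_rows: int
    violations: list = field(default_factory=list)

    @property
    def ok(self):
        return not self.violations

    def __str__(self):
        head = f"schema={self.schema} rows={self.n_rows}"
        if self.ok:
            return head + " OK"
        lines = [f"  row {r}: {rule}" for r, rule in self.violations[:20]]
        return head + f" {len(self.violations)} violation(s)\n" + "\n".join(lines)


class SchemaError(ValueError):
    def __init__(self, message, report: ValidationReport = None):
        super().__init__(message)
        self.report = report


def read_dataset(path, schema_id: str, drop_invalid: bool = False):
    """Read and validate a CSV dataset against a named schema.

    Returns ``(frame, report)``.  Any row-level violation is a hard
    failure unless ``drop_invalid`` is set, in which case offending rows
    are removed and listed in the report.  Tolerates UTF-8 BOMs and
    Windows line endings.
    """
    if schema_id not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_id!r}; one of {list(SCHEMAS)}")
    schema = SCHEMAS[schema_id]
    df = pd.read_csv(path, encoding="utf-8-sig")
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    report = ValidationReport(schema=schema_id, n_rows=len(df))
    bad_rows = set()
    for col, rule in schema.get("rules", {}).items():
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[~vals.apply(lambda v: bool(np.isfinite(v)) and rule(v))]:
            report.violations.append((int(i), f"{col} fails range rule"))
            bad_rows.add(i)
    for name, rule in schema.get("row_rules", {}).items():
        for i in df.index:
            try:
                ok = bool(rule(df.loc[i]))
            except Exception:
                ok = False
            if not ok:
                report.violations.append((int(i), name))
                bad_rows.add(i)
    if report.violations and not drop_invalid:
        raise SchemaError(
            f"{path}: {len(report.violations)} invalid row(s); "
            "pass drop_invalid to discard them", report
        )
    if bad_rows:
        df = df.drop(index=sorted(bad_rows)).reset_index(drop=True)
    return df, report


def _hash_file(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, seed, inputs=(), params=None):
    """Write a machine-readable run manifest next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": PACKAGE_VERSION,
        "inputs": {str(p): _hash_file(p) for p in inputs if Path(p).exists()},
        "params": params or {},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path


def load_config(path):
    """Load a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    return yaml.safe_load(text)
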
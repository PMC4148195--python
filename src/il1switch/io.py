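"""Tabular I/O with schema validation and provenance headers.

All artifacts are plain text: TSV by default (CSV on request), numbers at
12 significant digits, with ``#``-prefixed provenance header lines carrying
the package version, the seed and the configuration used.  Readers skip
header lines, check required columns and preserve extra ones.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["SCHEMAS", "FormatError", "write_table", "read_table"]

SCHEMAS: dict[str, list[str]] = {
    "trajectory": ["t_days", "G_mM", "I_pM", "B_mg", "L_pg_ml", "A_pg_ml", "F"],
    "events": ["t_days", "event"],
    "diagram": ["G_mM", "branch_id", "L_pg_ml", "A_pg_ml", "stable"],
    "nullcline": ["L_pg_ml", "A_pg_ml"],
    "dose_response": ["dose_pg_ml", "G_treated_end_mM", "G_control_end_mM",
                      "improvement_mM"],
    "sensitivity": ["t_days", "S_H_percent"],
    "glucose_history": ["t_days", "G_mM"],
    "scan": ["Lb_rel", "Ab_rel", "label", "fold_change_L"],
    "invitro": ["x", "replicate", "y"],
}


class FormatError(ValueError):
    """A table does not match its declared schema."""


def config_hash(config: dict) -> str:
    blob = repr(sorted(config.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, schema: str,
                seed: int | None = None, config: dict | None = None,
                fmt: str = "tsv") -> None:
    """Write a validated table with a provenance header."""
    required = SCHEMAS.get(schema)
    if required is None:
        raise ValueError(f"unknown schema {schema!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} for schema {schema!r}")
    sep = "\t" if fmt == "tsv" else ","
    path = Path(path)
    lines = [f"# il1switch v{__version__} schema={schema}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config:
        lines.append(f"# config_hash={config_hash(config)}")
        for key in sorted(config):
            lines.append(f"# config.{key}={config[key]}")
    header = "\n".join(lines) + "\n"
    body = df.to_csv(sep=sep, index=False, float_format="%.12g")
    path.write_text(header + body)


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a table, skipping provenance lines and validating the schema.

    Extra columns are preserved; a missing required column raises
    :class:`FormatError` naming it.
    """
    required = SCHEMAS.get(schema)
    if required is None:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    with path.open() as fh:
        first_data = ""
        for line in fh:
            if not line.startswith("#"):
                first_data = line
                break
    sep = "\t" if "\t" in first_data else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing} for schema {schema!r}")
    return df
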
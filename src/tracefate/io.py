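"""Validated CSV round-tripping and run manifests.

All tables are long/tidy UTF-8 CSV with a header row.  Readers are
tolerant: extra columns are accepted with a warning; missing required
columns raise a :class:`SchemaError` listing the missing names.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

SCHEMAS: dict[str, tuple[str, ...]] = {
    "integrals": ("sample_id", "metabolite", "integral"),
    "mix": ("metabolite", "nmol", "integral"),
    "mid_timecourse": ("metabolite", "turn", "pool_nmol"),
    "profile": ("key", "fraction"),
    "quant": ("sample_id", "metabolite", "nmol", "flag"),
    "growth": ("time_h", "od595", "glucose_pct"),
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise SchemaError(f"{path}: malformed CSV: {e}") from e
    required = set(SCHEMAS[schema])
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required columns {sorted(missing)} "
            f"for schema {schema!r}"
        )
    extra = set(df.columns) - required
    if schema == "mid_timecourse":
        extra -= {c for c in df.columns if len(c) == 2 and c.startswith("m")}
    if extra:
        logger.warning("%s: ignoring extra columns %s", path, sorted(extra))
    return df


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a CSV after checking it satisfies the named schema."""
    missing = set(SCHEMAS[schema]) - set(df.columns)
    if missing:
        raise SchemaError(
            f"refusing to write {path}: missing columns {sorted(missing)}"
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_manifest(out_dir, command: str, config: dict,
                   inputs: dict | None = None, seed: int | None = None) -> Path:
    """Record everything needed to reproduce a run next to its outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "inputs": inputs or {},
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
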
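"""Tabular I/O with embedded run metadata.

CSV convention: UTF-8, comma-separated, '.' decimal, one header row,
preceded by '#'-prefixed metadata lines (``# key: value``) recording the
resolved configuration (package version, seed, thresholds) so every
output is self-describing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_csv(df: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    """Write a table with '#'-prefixed metadata lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path) -> pd.DataFrame:
    """Read a metadata-CSV; '#' lines are skipped (see :func:`read_metadata`)."""
    return pd.read_csv(path, comment="#")


def read_metadata(path) -> dict[str, str]:
    """Parse the '# key: value' header lines of a metadata-CSV."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta
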
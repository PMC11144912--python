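"""Tabular result output: one CSV per table plus a JSON summary manifest."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_report(tables: dict[str, pd.DataFrame], path,
                 extra: dict | None = None) -> dict:
    """Write every table as ``<name>.csv`` under ``path`` plus ``summary.json``.

    Column order is preserved as given, so repeated runs are byte-identical.
    Returns the manifest that was written to the summary file.
    """
    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {outdir}: {exc}") from exc
    manifest: dict = {"tables": {}, "files": []}
    for name, table in tables.items():
        if not isinstance(table, pd.DataFrame):
            table = pd.DataFrame(table)
        fname = f"{name}.csv"
        table.to_csv(outdir / fname, index=False, float_format="%.9g")
        manifest["tables"][name] = {
            "file": fname, "rows": int(table.shape[0]),
            "columns": list(map(str, table.columns)),
        }
        manifest["files"].append(fname)
    if extra:
        manifest.update(extra)
    manifest["files"].append("summary.json")
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
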
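"""BED-like result tables and the run manifest.

One tab-delimited file per analyzed mismatch class, named by the class
(``AG.tsv``, ``GA.tsv``, ...). Columns, all coordinates 0-based half-open::

    chrom start end window_id delta strand q_value n_sites
    mean_signal_set1 mean_signal_set2

q values are present only in the focal class's file; decoy-class files
carry ``NA`` in that column. Rows are sorted by chromosome then start and
floats are serialized with six significant digits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import RunConfig

__all__ = ["write_result_table", "read_result_table", "write_manifest"]

RESULT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "window_id",
    "delta",
    "strand",
    "q_value",
    "n_sites",
    "mean_signal_set1",
    "mean_signal_set2",
]


def _as_result_frame(records: pd.DataFrame) -> pd.DataFrame:
    frame = records.copy()
    if "q_value" not in frame.columns:
        frame["q_value"] = frame["q_final"] if "q_final" in frame.columns else pd.NA
    frame = frame.rename(
        columns={"z_set1": "mean_signal_set1", "z_set2": "mean_signal_set2"}
    )
    if "strand" not in frame.columns:
        frame["strand"] = "."
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns and c != "q_value"]
    if missing:
        raise ValueError(f"result records lack required columns: {missing}")
    frame = frame[RESULT_COLUMNS]
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_result_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write one class's window records as a BED-like table (see module doc).

    ``records`` is a window-signal frame, optionally carrying ``q_final``
    (focal class); an empty frame yields a header-only file.
    """
    frame = _as_result_frame(records) if len(records) else pd.DataFrame(
        columns=RESULT_COLUMNS
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_result_table(path: str | Path) -> pd.DataFrame:
    """Re-parse a written result table (inverse of :func:`write_result_table`)."""
    return pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        dtype={"chrom": str, "strand": str, "window_id": str},
    )


def _checksum(path: str | Path) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def write_manifest(
    path: str | Path,
    cfg: RunConfig,
    input_paths: Mapping[str, list[str]],
    class_window_counts: Mapping[str, int],
    focal_records: pd.DataFrame,
    q_threshold: float = 0.1,
) -> dict:
    """Write a JSON manifest that fully determines the run.

    Records the configuration, md5 checksums of every input file, per-class
    window counts, and the number of focal windows at ``q_final <= 0.1``
    split by the sign of delta.
    """
    from . import __version__

    significant = focal_records[focal_records.get("q_final", pd.Series(dtype=float)) <= q_threshold] if len(focal_records) else focal_records
    manifest = {
        "tool": "diffedit",
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {
            role: {str(p): _checksum(p) for p in paths}
            for role, paths in input_paths.items()
        },
        "windows_per_class": dict(class_window_counts),
        "q_threshold": q_threshold,
        "significant_windows": {
            "positive_delta": int((significant["delta"] > 0).sum()) if len(significant) else 0,
            "negative_delta": int((significant["delta"] < 0).sum()) if len(significant) else 0,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
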
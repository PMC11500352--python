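"""End-to-end orchestration: counts -> window signals -> q values -> files."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import MISMATCH_CLASSES, RunConfig
from .counts import CountTable
from .pileup import pileup_sample_sets, reference_lengths
from .qvalue import qvalues_for_focal
from .regions import Region, read_regions, validate_regions
from .tables import write_manifest, write_result_table
from .windows import WindowSpec, build_delta_sets, tile_windows

logger = logging.getLogger("diffedit")

__all__ = ["AnalysisResult", "run_analysis", "run_from_alignments"]


@dataclass
class AnalysisResult:
    """Per-class window tables plus the q-scored focal table."""

    class_tables: dict[str, pd.DataFrame]
    focal_records: pd.DataFrame
    windows: list[WindowSpec]
    cfg: RunConfig

    def significant(self, q_threshold: float = 0.1) -> pd.DataFrame:
        if len(self.focal_records) == 0:
            return self.focal_records
        return self.focal_records[self.focal_records["q_final"] <= q_threshold]


def run_analysis(
    table: CountTable,
    regions: Sequence[Region],
    cfg: RunConfig,
    windows: Sequence[WindowSpec] | None = None,
) -> AnalysisResult:
    """Score differential editing on an in-memory count table.

    Tiles the regions (unless ``windows`` is given), builds the per-class
    delta sets, and estimates q values for the focal class from the
    remaining classes.
    """
    if windows is None:
        windows = tile_windows(regions, cfg.window_size)
    windows = list(windows)
    if not windows:
        raise ValueError("no windows to analyze: empty region set")
    delta_sets = build_delta_sets(table, windows, cfg)
    for mismatch_class in MISMATCH_CLASSES:
        logger.info(
            "class %s: %d windows", mismatch_class, len(delta_sets[mismatch_class])
        )
    focal = qvalues_for_focal(delta_sets, cfg) if len(
        delta_sets[cfg.focal_mismatch]
    ) else delta_sets[cfg.focal_mismatch].assign(q_raw=pd.NA, q_final=pd.NA)
    if len(focal) == 0:
        logger.warning("focal class %s has no eligible window", cfg.focal_mismatch)
    return AnalysisResult(delta_sets, focal, windows, cfg)


def run_from_alignments(
    set1_paths: Mapping[str, str] | Sequence[str],
    set2_paths: Mapping[str, str] | Sequence[str],
    fasta_path: str | Path,
    regions_path: str | Path,
    out_dir: str | Path,
    cfg: RunConfig,
    regions_format: str | None = None,
    feature_types: Sequence[str] | None = None,
    manifest_q_threshold: float = 0.1,
) -> AnalysisResult:
    """Full file-based run: BAMs + FASTA + BED/GFF -> result tables + manifest.

    Writes one BED-like table per mismatch class into ``out_dir`` (q values
    only in the focal class's file) plus ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    regions = read_regions(regions_path, format=regions_format, feature_types=feature_types)
    if not regions:
        raise ValueError(f"no regions parsed from {regions_path}")
    validate_regions(regions, reference_lengths(fasta_path))
    logger.info("loaded %d merged regions", len(regions))

    table = pileup_sample_sets(set1_paths, set2_paths, regions, fasta_path, cfg)
    logger.info(
        "pileup complete: %d positions, %d samples", table.n_sites(), len(table.samples)
    )
    result = run_analysis(table, regions, cfg)
    if len(result.focal_records) == 0:
        raise ValueError("zero eligible windows for the focal class")

    for mismatch_class, frame in result.class_tables.items():
        records = (
            result.focal_records if mismatch_class == cfg.focal_mismatch else frame
        )
        write_result_table(records, out_dir / f"{mismatch_class}.tsv")

    def paths_of(p):
        return list(p.values()) if isinstance(p, Mapping) else list(p)

    write_manifest(
        out_dir / "manifest.json",
        cfg,
        {
            "set1": [str(x) for x in paths_of(set1_paths)],
            "set2": [str(x) for x in paths_of(set2_paths)],
            "reference": [str(fasta_path)],
            "regions": [str(regions_path)],
        },
        {c: len(t) for c, t in result.class_tables.items()},
        result.focal_records,
        q_threshold=manifest_q_threshold,
    )
    return result
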
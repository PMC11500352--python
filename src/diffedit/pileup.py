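"""BAM -> per-position base counts over the target regions.

Counting contract: a base contributes when it is an aligned match/mismatch
(CIGAR M/=/X) from a primary, mapped, non-QC-fail read with mapping quality
at or above ``min_mapping_quality`` and base quality at or above
``min_base_quality``. Deletions, reference skips (introns) and N base calls
contribute nothing; each read contributes at most once per position
(overlapping mate pairs count independently). Duplicate-flagged reads are
counted unless ``exclude_duplicates`` is set. Positions whose reference
base is not A/C/G/T are dropped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .config import RunConfig
from .counts import ChromCounts, CountTable, SampleSet
from .regions import Region

__all__ = ["pileup_counts", "pileup_sample_sets", "reference_lengths"]

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def reference_lengths(fasta_path: str | Path) -> dict[str, int]:
    with pysam.FastaFile(str(fasta_path)) as fa:
        return dict(zip(fa.references, fa.lengths))


def _read_filter(cfg: RunConfig):
    def keep(read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            return False
        if read.is_qcfail:
            return False
        if cfg.exclude_duplicates and read.is_duplicate:
            return False
        return read.mapping_quality >= cfg.min_mapping_quality

    return keep


def pileup_counts(
    alignment_path: str | Path,
    regions: Sequence[Region],
    fasta_path: str | Path,
    cfg: RunConfig,
) -> dict[str, ChromCounts]:
    """Count observed A/C/G/T per position of one sample's alignments.

    Returns a mapping chromosome -> :class:`ChromCounts` with a single
    sample axis, covering every region position with an A/C/G/T reference
    base (zero counts where no read passes the filters).
    """
    alignment_path = Path(alignment_path)
    if not (
        alignment_path.with_suffix(alignment_path.suffix + ".bai").exists()
        or alignment_path.with_suffix(".bai").exists()
        or alignment_path.with_suffix(alignment_path.suffix + ".csi").exists()
    ):
        raise FileNotFoundError(
            f"missing BAM index for {alignment_path}; run samtools index"
        )
    keep = _read_filter(cfg)
    per_chrom_pos: dict[str, list[np.ndarray]] = {}
    per_chrom_ref: dict[str, list[np.ndarray]] = {}
    per_chrom_counts: dict[str, list[np.ndarray]] = {}
    with pysam.AlignmentFile(str(alignment_path)) as bam, pysam.FastaFile(
        str(fasta_path)
    ) as fa:
        header_chroms = set(bam.references)
        for region in regions:
            if region.chrom not in header_chroms:
                raise ValueError(
                    f"region chromosome {region.chrom!r} absent from "
                    f"{alignment_path.name} header"
                )
            acgt = bam.count_coverage(
                region.chrom,
                region.start,
                region.end,
                quality_threshold=cfg.min_base_quality,
                read_callback=keep,
            )
            counts = np.stack(
                [np.asarray(a, dtype=np.int64) for a in acgt], axis=1
            )  # (L, 4)
            seq = fa.fetch(region.chrom, region.start, region.end)
            ref = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            valid = ref >= 0  # drop N / ambiguous reference bases
            per_chrom_pos.setdefault(region.chrom, []).append(
                np.arange(region.start, region.end, dtype=np.int64)[valid]
            )
            per_chrom_ref.setdefault(region.chrom, []).append(ref[valid])
            per_chrom_counts.setdefault(region.chrom, []).append(counts[valid])
    out: dict[str, ChromCounts] = {}
    for chrom in per_chrom_pos:
        positions = np.concatenate(per_chrom_pos[chrom])
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        if len(positions) > 1 and np.any(np.diff(positions) <= 0):
            raise ValueError(
                f"{chrom}: overlapping regions passed to pileup; merge first"
            )
        ref = np.concatenate(per_chrom_ref[chrom])[order]
        counts = np.concatenate(per_chrom_counts[chrom])[order][None, :, :]
        out[chrom] = ChromCounts(positions, ref, counts)
    return out


def pileup_sample_sets(
    set1_paths: Mapping[str, str | Path] | Sequence[str | Path],
    set2_paths: Mapping[str, str | Path] | Sequence[str | Path],
    regions: Sequence[Region],
    fasta_path: str | Path,
    cfg: RunConfig,
) -> CountTable:
    """Pile up both sample sets and merge into one :class:`CountTable`.

    Sample identifiers default to alignment file stems when plain path
    sequences are given.
    """

    def as_mapping(paths, label) -> dict[str, Path]:
        if isinstance(paths, Mapping):
            return {str(k): Path(v) for k, v in paths.items()}
        mapping: dict[str, Path] = {}
        for p in paths:
            p = Path(p)
            stem = p.stem
            name = stem
            k = 1
            while name in mapping:
                k += 1
                name = f"{stem}.{k}"
            mapping[name] = p
        if not mapping:
            raise ValueError(f"sample set {label} has no alignment files")
        return mapping

    map1 = as_mapping(set1_paths, "set1")
    map2 = as_mapping(set2_paths, "set2")
    # a self-comparison (same files in both sets) is legitimate; disambiguate
    map2 = {(f"{n}_set2" if n in map1 else n): p for n, p in map2.items()}
    set1 = SampleSet("set1", tuple(map1))
    set2 = SampleSet("set2", tuple(map2))
    per_sample = {
        sample: pileup_counts(path, regions, fasta_path, cfg)
        for sample, path in {**map1, **map2}.items()
    }
    return CountTable.from_per_sample(per_sample, set1, set2)
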
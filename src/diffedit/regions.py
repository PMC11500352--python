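"""Target-region handling: BED/GFF reading, merging, validation.

All coordinates are 0-based half-open internally; GFF/GTF input (1-based
closed) is converted at parse time and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = ["Region", "read_regions", "merge_regions", "validate_regions"]


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class RegionParseError(ValueError):
    """A malformed annotation line; the message names the line number."""


def read_regions(
    path: str | Path,
    format: str | None = None,
    feature_types: Sequence[str] | None = None,
    merge: bool = True,
) -> list[Region]:
    """Read target regions from a BED or GFF3/GTF file.

    Overlapping records are merged per chromosome (strand collapsed to
    ``"."`` on conflict) so no genomic base is tiled twice, and the result
    is coordinate-sorted.

    Parameters
    ----------
    format
        ``"bed"`` or ``"gff"``; inferred from the file suffix when omitted.
    feature_types
        For GFF input, keep only these feature types (e.g. ``["gene"]``);
        all features are kept by default.
    """
    path = Path(path)
    fmt = (format or _infer_format(path)).lower()
    if fmt == "bed":
        regions = list(_parse_bed(path))
    elif fmt in {"gff", "gff3", "gtf"}:
        regions = list(_parse_gff(path, feature_types))
    else:
        raise ValueError(f"unknown region format {fmt!r}")
    return merge_regions(regions) if merge else sorted(
        regions, key=lambda r: (r.chrom, r.start, r.end)
    )


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return "bed"
    if suffix in {".gff", ".gff3", ".gtf"}:
        return "gff"
    raise ValueError(f"cannot infer region format from {path.name!r}")


def _parse_bed(path: Path) -> Iterable[Region]:
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise RegionParseError(f"{path}:{lineno}: BED line has <3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise RegionParseError(
                f"{path}:{lineno}: non-integer coordinates"
            ) from exc
        name = parts[3] if len(parts) > 3 and parts[3] else "."
        strand = parts[5] if len(parts) > 5 and parts[5] in {"+", "-"} else "."
        try:
            yield Region(parts[0], start, end, strand, name)
        except ValueError as exc:
            raise RegionParseError(f"{path}:{lineno}: {exc}") from exc


_GFF_NAME_KEYS = ("ID", "Name", "gene_id", "gene_name", "transcript_id")


def _parse_gff(path: Path, feature_types: Sequence[str] | None) -> Iterable[Region]:
    wanted = set(feature_types) if feature_types else None
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 8:
            raise RegionParseError(f"{path}:{lineno}: GFF line has <8 columns")
        if wanted is not None and parts[2] not in wanted:
            continue
        try:
            start1, end1 = int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise RegionParseError(
                f"{path}:{lineno}: non-integer coordinates"
            ) from exc
        strand = parts[6] if parts[6] in {"+", "-"} else "."
        name = _gff_name(parts[8]) if len(parts) > 8 else "."
        try:
            # GFF is 1-based closed: [start1, end1] -> [start1-1, end1)
            yield Region(parts[0], start1 - 1, end1, strand, name)
        except ValueError as exc:
            raise RegionParseError(f"{path}:{lineno}: {exc}") from exc


def _gff_name(attributes: str) -> str:
    for field in attributes.replace("; ", ";").split(";"):
        field = field.strip()
        for key in _GFF_NAME_KEYS:
            if field.startswith(key + "=") or field.startswith(key + " "):
                return field[len(key) + 1 :].strip().strip('"')
    return "."


def merge_regions(regions: Iterable[Region]) -> list[Region]:
    """Union of intervals per chromosome; sorted by (chrom, start).

    Abutting intervals ([a,b) and [b,c)) are merged as well, so the result
    tiles each covered stretch exactly once. Strands are kept when all
    merged records agree and collapsed to ``"."`` otherwise.
    """
    out: list[Region] = []
    for region in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and out[-1].chrom == region.chrom and region.start <= out[-1].end:
            prev = out[-1]
            out[-1] = replace(
                prev,
                end=max(prev.end, region.end),
                strand=prev.strand if prev.strand == region.strand else ".",
                name=prev.name if prev.name == region.name else ".",
            )
        else:
            out.append(region)
    return out


def validate_regions(
    regions: Sequence[Region], reference_lengths: Mapping[str, int]
) -> None:
    """Check every region against reference chromosome names and lengths."""
    for region in regions:
        if region.chrom not in reference_lengths:
            raise ValueError(
                f"region chromosome {region.chrom!r} absent from reference"
            )
        if region.end > reference_lengths[region.chrom]:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"reference length {reference_lengths[region.chrom]}"
            )
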
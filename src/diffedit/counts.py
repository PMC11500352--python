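"""Per-position, per-sample base-count containers.

The central object is :class:`CountTable`: for every position inside the
target regions it stores the reference base and, for every sample of both
sets, the filtered counts of observed A/C/G/T. Coverage at a position is
the sum of the four observed-base counts ("all matches and mismatches");
the mismatch count for class x->y at a reference-x position is simply the
count of observed y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import BASE_INDEX, BASES

__all__ = ["SampleSet", "ChromCounts", "CountTable", "mismatch_count"]


@dataclass(frozen=True)
class SampleSet:
    """One of the two compared groups: a label and its sample identifiers."""

    label: str
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"sample set {self.label!r} is empty")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError(f"duplicate sample ids in set {self.label!r}")


@dataclass
class ChromCounts:
    """Counts for one chromosome.

    positions : sorted unique 0-based positions, shape (P,)
    ref       : base codes (0..3 over ACGT) aligned with positions
    counts    : int array, shape (n_samples, P, 4) in ACGT order
    """

    positions: np.ndarray
    ref: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=np.int8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must have shape (n_samples, P, 4)")
        if not (
            len(self.positions) == len(self.ref) == self.counts.shape[1]
        ):
            raise ValueError("positions, ref and counts are misaligned")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("negative base counts")

    @property
    def coverage(self) -> np.ndarray:
        """Per sample x position coverage: sum of the four base counts."""
        return self.counts.sum(axis=2)


class CountTable:
    """Merged base counts for all samples of both sets over shared positions."""

    def __init__(
        self,
        set1: SampleSet,
        set2: SampleSet,
        chroms: Mapping[str, ChromCounts],
    ) -> None:
        overlap = set(set1.samples) & set(set2.samples)
        if overlap:
            raise ValueError(f"samples present in both sets: {sorted(overlap)}")
        self.set1 = set1
        self.set2 = set2
        self.samples: tuple[str, ...] = set1.samples + set2.samples
        self.chroms = dict(chroms)
        n = len(self.samples)
        for chrom, cc in self.chroms.items():
            if cc.counts.shape[0] != n:
                raise ValueError(
                    f"{chrom}: counts carry {cc.counts.shape[0]} samples, "
                    f"expected {n}"
                )

    @property
    def set1_indices(self) -> np.ndarray:
        return np.arange(len(self.set1.samples))

    @property
    def set2_indices(self) -> np.ndarray:
        return len(self.set1.samples) + np.arange(len(self.set2.samples))

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def n_sites(self) -> int:
        return sum(len(cc.positions) for cc in self.chroms.values())

    @classmethod
    def from_per_sample(
        cls,
        per_sample: Mapping[str, Mapping[str, ChromCounts]],
        set1: SampleSet,
        set2: SampleSet,
    ) -> "CountTable":
        """Merge single-sample pileups into one table.

        Positions are keyed identically across samples (the pileup runs over
        the same regions and reference); a sample without reads at a
        position carries explicit zero counts rather than a missing entry.
        Inconsistent reference bases across samples at one position are an
        internal error (impossible when the same reference is used).
        """
        samples = set1.samples + set2.samples
        missing = [s for s in samples if s not in per_sample]
        if missing:
            raise ValueError(f"no counts provided for samples {missing}")
        chrom_names = sorted({c for m in per_sample.values() for c in m})
        chroms: dict[str, ChromCounts] = {}
        for chrom in chrom_names:
            pieces = [per_sample[s][chrom] for s in samples if chrom in per_sample[s]]
            positions = np.unique(np.concatenate([p.positions for p in pieces]))
            ref = np.zeros(len(positions), dtype=np.int8)
            ref_set = np.zeros(len(positions), dtype=bool)
            counts = np.zeros((len(samples), len(positions), 4), dtype=np.int64)
            for si, sample in enumerate(samples):
                if chrom not in per_sample[sample]:
                    continue
                piece = per_sample[sample][chrom]
                idx = np.searchsorted(positions, piece.positions)
                counts[si, idx] = piece.counts[0]
                clash = ref_set[idx] & (ref[idx] != piece.ref)
                if np.any(clash):
                    raise RuntimeError(
                        f"{chrom}: inconsistent reference bases across samples"
                    )
                ref[idx] = piece.ref
                ref_set[idx] = True
            chroms[chrom] = ChromCounts(positions, ref, counts)
        return cls(set1, set2, chroms)

    @classmethod
    def from_site_records(
        cls,
        records: Iterable[tuple[str, int, str, Mapping[str, Sequence[int]]]],
        set1: SampleSet,
        set2: SampleSet,
    ) -> "CountTable":
        """Build a table from explicit site records.

        Each record is ``(chrom, pos, ref_base, {sample: (nA, nC, nG, nT)})``;
        samples absent from a record get zero counts. Convenient for small
        hand-constructed tables.
        """
        samples = set1.samples + set2.samples
        by_chrom: dict[str, list] = {}
        for chrom, pos, ref_base, sample_counts in records:
            by_chrom.setdefault(chrom, []).append((pos, ref_base, sample_counts))
        chroms: dict[str, ChromCounts] = {}
        for chrom, rows in by_chrom.items():
            rows.sort(key=lambda r: r[0])
            positions = np.array([r[0] for r in rows], dtype=np.int64)
            ref = np.array([BASE_INDEX[r[1].upper()] for r in rows], dtype=np.int8)
            counts = np.zeros((len(samples), len(rows), 4), dtype=np.int64)
            for pi, (_, _, sample_counts) in enumerate(rows):
                for sample, quad in sample_counts.items():
                    counts[samples.index(sample), pi] = np.asarray(quad)
            chroms[chrom] = ChromCounts(positions, ref, counts)
        return cls(set1, set2, chroms)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (chrom, pos, sample) with ACGT counts."""
        frames = []
        for chrom in sorted(self.chroms):
            cc = self.chroms[chrom]
            for si, sample in enumerate(self.samples):
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": cc.positions,
                            "ref": [BASES[b] for b in cc.ref],
                            "sample": sample,
                            "A": cc.counts[si, :, 0],
                            "C": cc.counts[si, :, 1],
                            "G": cc.counts[si, :, 2],
                            "T": cc.counts[si, :, 3],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def mismatch_count(
    table: CountTable, chrom: str, pos: int, sample: str, x: str, y: str
) -> int | None:
    """Observed count of base ``y`` at a reference-``x`` position.

    Returns ``None`` (site ineligible for class x->y, distinct from a zero
    count) when the reference base at the position is not ``x``.
    """
    if x == y:
        raise ValueError("mismatch class requires two distinct bases")
    cc = table.chroms[chrom]
    idx = int(np.searchsorted(cc.positions, pos))
    if idx >= len(cc.positions) or cc.positions[idx] != pos:
        raise KeyError(f"position {chrom}:{pos} not in table")
    if cc.ref[idx] != BASE_INDEX[x.upper()]:
        return None
    return int(cc.counts[table.sample_index(sample), idx, BASE_INDEX[y.upper()]])
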
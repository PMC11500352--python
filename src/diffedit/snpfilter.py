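"""Heuristic SNP exclusion.

A homozygous (or high-frequency heterozygous) genomic variant looks like a
near-fixed mismatch in every read, unlike A-to-I editing which is almost
always partial. The ad-hoc filter drops a position for a mismatch class
when any single sufficiently covered sample of either set shows a mismatch
frequency at or above the threshold (default 0.80, inclusive). Only samples
meeting ``min_coverage`` are consulted so a 1-read "100%" cannot remove a
site. The exclusion applies to all samples of both sets at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BASE_INDEX, RunConfig
from .counts import ChromCounts, CountTable

__all__ = ["SnpVerdict", "snp_filter", "snp_exclusion_mask"]


@dataclass(frozen=True)
class SnpVerdict:
    chrom: str
    pos: int
    excluded: bool
    triggering_sample: str | None
    observed_freq: float


def snp_exclusion_mask(
    cc: ChromCounts, y_index: int, cfg: RunConfig
) -> np.ndarray:
    """Boolean mask over positions: True where the site is SNP-excluded
    for the mismatch class whose observed base has ACGT index ``y_index``.

    Reference-base agreement is checked by the caller (a site only enters a
    class when ref matches), so the mask is computed purely from observed-y
    frequencies.
    """
    coverage = cc.coverage  # (S, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(coverage > 0, cc.counts[:, :, y_index] / coverage, 0.0)
    considered = coverage >= cfg.min_coverage
    return np.any(considered & (freq >= cfg.snp_freq_threshold), axis=0)


def snp_filter(
    table: CountTable, chrom: str, pos: int, mismatch_class: str, cfg: RunConfig
) -> SnpVerdict:
    """Verdict for a single site and class; see module docstring for the rule."""
    cc = table.chroms[chrom]
    idx = int(np.searchsorted(cc.positions, pos))
    if idx >= len(cc.positions) or cc.positions[idx] != pos:
        raise KeyError(f"position {chrom}:{pos} not in table")
    y_index = BASE_INDEX[mismatch_class[1]]
    coverage = cc.coverage[:, idx]
    counts_y = cc.counts[:, idx, y_index]
    best_sample = None
    best_freq = 0.0
    excluded = False
    for si, sample in enumerate(table.samples):
        if coverage[si] < cfg.min_coverage or coverage[si] == 0:
            continue
        freq = counts_y[si] / coverage[si]
        if freq > best_freq:
            best_freq = float(freq)
            best_sample = sample
        if freq >= cfg.snp_freq_threshold:
            excluded = True
    return SnpVerdict(chrom, pos, excluded, best_sample if excluded else None, best_freq)
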
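"""Window tiling and editing-signal computation.

For a sample *s* and window *w*, the editing signal for mismatch class
x->y is the sum over eligible positions *i* in the window of the editing
ratio

    r_i,s = m_i,s / c_i,s,

the fraction of reads showing the observed base y at the reference-x
position. The per-set estimate z is the arithmetic mean of the signals of
the set's samples, and the window's differential-editing score is

    delta = z(set2) - z(set1),

positive when editing is higher in set2. A position is eligible for a
class when its reference base matches, every sample of both sets reaches
the minimum coverage there, and (when enabled) it survives the SNP filter.
The all-sample coverage rule keeps each sample's signal a sum over the
identical site set, so coverage imbalances cannot masquerade as editing
differences.

Windows are non-overlapping tiles of the merged target regions, anchored
at each region's start; a shorter remainder window is kept at region ends
so short exons are not silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import BASE_INDEX, MISMATCH_CLASSES, RunConfig
from .counts import CountTable
from .regions import Region
from .snpfilter import snp_exclusion_mask

__all__ = [
    "WindowSpec",
    "tile_windows",
    "editing_ratio",
    "build_delta_sets",
    "window_signal_frame",
]


@dataclass(frozen=True)
class WindowSpec:
    chrom: str
    start: int
    end: int
    strand: str = "."

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def tile_windows(regions: Sequence[Region], window_size: int) -> list[WindowSpec]:
    """Tile merged regions left-to-right into consecutive windows.

    Every window has exactly ``window_size`` bases except a final remainder
    window of length ``len(region) % window_size`` when nonzero; windows
    never span region boundaries.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    windows: list[WindowSpec] = []
    for region in regions:
        for start in range(region.start, region.end, window_size):
            windows.append(
                WindowSpec(
                    region.chrom,
                    start,
                    min(start + window_size, region.end),
                    region.strand,
                )
            )
    return windows


def editing_ratio(m: int, c: int) -> float:
    """Editing ratio m/c at one position; the caller guarantees c > 0."""
    if not 0 <= m <= c:
        raise ValueError(f"require 0 <= m <= c, got m={m}, c={c}")
    return m / c


def window_signal_frame(
    table: CountTable,
    windows: Sequence[WindowSpec],
    cfg: RunConfig,
    mismatch_class: str,
) -> pd.DataFrame:
    """Per-window signals for one mismatch class.

    Returns a DataFrame with one row per window that retains at least
    ``min_sites_per_window`` eligible positions, columns::

        chrom start end window_id strand n_sites e_<sample>... z_set1 z_set2 delta
    """
    x_index = BASE_INDEX[mismatch_class[0]]
    y_index = BASE_INDEX[mismatch_class[1]]
    samples = table.samples
    n_samples = len(samples)

    by_chrom: dict[str, list[WindowSpec]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    rows: list[dict] = []
    for chrom, chrom_windows in by_chrom.items():
        cc = table.chroms.get(chrom)
        if cc is None or len(cc.positions) == 0:
            continue
        chrom_windows = sorted(chrom_windows, key=lambda w: w.start)
        coverage = cc.coverage  # (S, P)
        eligible = (coverage >= cfg.min_coverage).all(axis=0) & (cc.ref == x_index)
        if cfg.snp_filter_enabled:
            eligible &= ~snp_exclusion_mask(cc, y_index, cfg)
        safe_cov = np.maximum(coverage, 1)
        ratios = np.where(eligible, cc.counts[:, :, y_index] / safe_cov, 0.0)
        # per-window sums via reduceat (padded so an end index of P is valid);
        # summing within the window keeps rounding independent of the
        # chromosome-wide signal, unlike a prefix-sum difference
        padded = np.concatenate([ratios, np.zeros((n_samples, 1))], axis=1)
        elig_csum = np.concatenate([[0], np.cumsum(eligible)])
        bounds = np.array([[w.start, w.end] for w in chrom_windows])
        idx = np.searchsorted(cc.positions, bounds)  # (W, 2)
        window_sums = np.add.reduceat(padded, idx.ravel(), axis=1)[:, 0::2]
        window_sums[:, idx[:, 0] == idx[:, 1]] = 0.0
        for wi, w in enumerate(chrom_windows):
            i0, i1 = idx[wi]
            n_sites = int(elig_csum[i1] - elig_csum[i0])
            if n_sites < cfg.min_sites_per_window:
                continue
            signals = window_sums[:, wi]
            z1 = float(signals[table.set1_indices].mean())
            z2 = float(signals[table.set2_indices].mean())
            row = {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "window_id": w.window_id,
                "strand": w.strand,
                "n_sites": n_sites,
            }
            row.update({f"e_{s}": float(signals[si]) for si, s in enumerate(samples)})
            row.update({"z_set1": z1, "z_set2": z2, "delta": z2 - z1})
            rows.append(row)

    columns = (
        ["chrom", "start", "end", "window_id", "strand", "n_sites"]
        + [f"e_{s}" for s in samples]
        + ["z_set1", "z_set2", "delta"]
    )
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def build_delta_sets(
    table: CountTable,
    windows: Sequence[WindowSpec],
    cfg: RunConfig,
    classes: Sequence[str] = MISMATCH_CLASSES,
) -> dict[str, pd.DataFrame]:
    """Window-signal tables for every mismatch class.

    The returned mapping covers all requested classes; a class with no
    surviving window maps to an empty frame (handled downstream by the
    q-value estimation, which skips empty decoys).
    """
    return {
        mismatch_class: window_signal_frame(table, windows, cfg, mismatch_class)
        for mismatch_class in classes
    }
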
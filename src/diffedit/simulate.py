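"""Seeded synthetic data with known ground truth.

The generator emulates the data model the detector assumes: every base is
mis-read as each of the three other bases with probability ``error_rate/3``
(symmetric across all twelve mismatch classes, so the non-focal classes are
a valid null for the focal one), while A-to-I editing adds an excess of
observed G at edited reference-A positions. Editing levels are shared by
all samples of a set; planted windows shift the level of the second set so
the true per-window delta is known exactly. Optional SNP sites mix in a
fixed alternative-allele fraction for one or both sets, and an optional
per-class error-skew factor deliberately violates the noise-symmetry
assumption for robustness checks.

By default edited sites exist only inside planted windows. Background
editing that is identical in both sets would still contribute sampling
variance p(1-p)/c to focal-class windows only, making the focal null
heavier-tailed than every decoy and thereby violating the exchangeability
the decoy-based q estimation relies on; ``background_editing=True`` enables
it explicitly to probe that failure mode.

Counts can be materialized as micro-BAM + FASTA fixtures whose pileup
reproduces the generated count table integer-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .config import BASE_INDEX, BASES, MISMATCH_CLASSES
from .counts import ChromCounts, CountTable, SampleSet
from .regions import Region
from .windows import WindowSpec, tile_windows

__all__ = ["SimParams", "SnpSite", "GroundTruth", "SimResult", "simulate_counts", "emit_micro_bam"]

_CHROM = "sim1"
_GAP = 25  # unannotated spacer between simulated regions


@dataclass(frozen=True)
class SnpSite:
    """A genomic-variant site: ``scope`` is ``both``, ``set1`` or ``set2``."""

    pos: int
    alt_base: str
    alt_fraction: float
    scope: str = "both"

    def __post_init__(self) -> None:
        if self.alt_base.upper() not in BASES:
            raise ValueError(f"invalid alt base {self.alt_base!r}")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction must be in [0, 1]")
        if self.scope not in {"both", "set1", "set2"}:
            raise ValueError(f"invalid scope {self.scope!r}")


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults define the standard simulation regime.

    Defaults give 2 vs 2 samples over 40 regions of 2550 nt (2000 windows
    of 51 nt), negative-binomial coverage with mean 50, a symmetric
    per-base error rate of 0.002 (typical Illumina substitution-error
    scale), edited sites at density 0.25 of reference-A positions inside
    planted windows with Beta(2, 8) baseline levels (mean 0.2, the typical
    range of repeat-region editing levels).
    """

    n_samples_set1: int = 2
    n_samples_set2: int = 2
    n_regions: int = 40
    region_length: int = 2550
    window_size: int = 51
    coverage_mean: float = 50.0
    coverage_dispersion: float = 10.0
    error_rate: float = 0.002
    editing_site_density: float = 0.25
    editing_level_alpha: float = 2.0
    editing_level_beta: float = 8.0
    background_editing: bool = False
    planted_windows: tuple[tuple[int, float], ...] = ()
    snp_sites: tuple[SnpSite, ...] = ()
    error_skew: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        for rate in (self.error_rate, self.editing_site_density):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_samples_set1 < 1 or self.n_samples_set2 < 1:
            raise ValueError("each set needs at least one sample")
        if self.window_size < 1 or self.n_regions < 1 or self.region_length < 1:
            raise ValueError("geometry parameters must be positive")
        for cls, factor in self.error_skew:
            if cls not in MISMATCH_CLASSES or factor < 0:
                raise ValueError(f"invalid error skew entry ({cls!r}, {factor})")


@dataclass
class GroundTruth:
    """Everything needed to score a detection run without re-derivation."""

    positions: np.ndarray  # all region positions on the simulated chromosome
    ref: np.ndarray  # base codes aligned with positions
    level_set1: np.ndarray  # true editing level per position, set 1
    level_set2: np.ndarray  # true editing level per position, set 2
    windows: pd.DataFrame  # window_id, planted, delta_level, expected_delta

    @property
    def planted_window_ids(self) -> list[str]:
        return self.windows.loc[self.windows["planted"], "window_id"].tolist()


@dataclass
class SimResult:
    table: CountTable
    regions: list[Region]
    windows: list[WindowSpec]
    truth: GroundTruth
    ref_seqs: dict[str, str]
    params: SimParams


def simulate_counts(params: SimParams) -> SimResult:
    """Generate a seeded count table with ground truth (see module doc).

    Deterministic: identical params (including seed) give identical output.
    """
    rng = np.random.default_rng(params.seed)
    span = params.region_length + _GAP
    total_length = params.n_regions * span
    seq_codes = rng.integers(0, 4, size=total_length, dtype=np.int8)
    regions = [
        Region(_CHROM, i * span, i * span + params.region_length, "+", f"reg{i:03d}")
        for i in range(params.n_regions)
    ]
    windows = tile_windows(regions, params.window_size)

    positions = np.concatenate(
        [np.arange(r.start, r.end, dtype=np.int64) for r in regions]
    )
    ref = seq_codes[positions]
    n_pos = len(positions)

    planted = dict(params.planted_windows)
    bad = [wi for wi in planted if not 0 <= wi < len(windows)]
    if bad:
        raise ValueError(f"planted window indices out of range: {bad}")

    # membership of each position in its window (regions tile contiguously)
    window_of = np.full(n_pos, -1, dtype=np.int64)
    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    idx0 = np.searchsorted(positions, starts)
    idx1 = np.searchsorted(positions, ends)
    for wi in range(len(windows)):
        window_of[idx0[wi]:idx1[wi]] = wi

    is_a = ref == BASE_INDEX["A"]
    in_planted = np.isin(window_of, list(planted)) if planted else np.zeros(n_pos, bool)
    candidate = is_a & (in_planted | params.background_editing)
    edited = candidate & (rng.random(n_pos) < params.editing_site_density)

    level1 = np.zeros(n_pos)
    level1[edited] = rng.beta(
        params.editing_level_alpha, params.editing_level_beta, size=int(edited.sum())
    )
    shift = np.zeros(n_pos)
    for wi, delta_level in planted.items():
        shift[(window_of == wi) & edited] = delta_level
    level2 = np.clip(level1 + shift, 0.0, 1.0)

    # per-class error probabilities (per target base: error_rate/3, skewed)
    skew = dict(params.error_skew)
    err = np.zeros((4, 4))
    for x in BASES:
        for y in BASES:
            if x != y:
                err[BASE_INDEX[x], BASE_INDEX[y]] = (
                    params.error_rate * skew.get(x + y, 1.0) / 3.0
                )

    def build_probs(level: np.ndarray) -> np.ndarray:
        p = err[ref].copy()  # (P, 4) mismatch probabilities
        g = BASE_INDEX["G"]
        # cap levels so the reference probability stays non-negative
        eff = np.minimum(level, 1.0 - p.sum(axis=1))
        p[:, g] = p[:, g] + np.where(is_a, eff, 0.0)
        p[np.arange(n_pos), ref] = 0.0
        p[np.arange(n_pos), ref] = 1.0 - p.sum(axis=1)
        return p

    probs = {"set1": build_probs(level1), "set2": build_probs(level2)}
    for snp in params.snp_sites:
        pi = int(np.searchsorted(positions, snp.pos))
        if pi >= n_pos or positions[pi] != snp.pos:
            raise ValueError(f"SNP position {snp.pos} is outside the regions")
        onehot = np.zeros(4)
        onehot[BASE_INDEX[snp.alt_base.upper()]] = 1.0
        targets = ("set1", "set2") if snp.scope == "both" else (snp.scope,)
        for label in targets:
            probs[label][pi] = (
                (1.0 - snp.alt_fraction) * probs[label][pi] + snp.alt_fraction * onehot
            )

    set1 = SampleSet("set1", tuple(f"s1_{i}" for i in range(params.n_samples_set1)))
    set2 = SampleSet("set2", tuple(f"s2_{i}" for i in range(params.n_samples_set2)))
    n_samples = len(set1.samples) + len(set2.samples)
    nb_n = params.coverage_dispersion
    nb_p = nb_n / (nb_n + params.coverage_mean)
    coverage = rng.negative_binomial(nb_n, nb_p, size=(n_samples, n_pos))

    counts = np.zeros((n_samples, n_pos, 4), dtype=np.int64)
    for si in range(n_samples):
        label = "set1" if si < len(set1.samples) else "set2"
        counts[si] = rng.multinomial(coverage[si], probs[label])

    table = CountTable(set1, set2, {_CHROM: ChromCounts(positions, ref, counts)})

    per_site_diff = np.where(edited, level2 - level1, 0.0)
    window_rows = []
    for wi, w in enumerate(windows):
        sel = window_of == wi
        window_rows.append(
            {
                "window_id": w.window_id,
                "planted": wi in planted,
                "delta_level": planted.get(wi, 0.0),
                "n_edited_sites": int((edited & sel).sum()),
                "expected_delta": float(per_site_diff[sel].sum()),
            }
        )
    truth = GroundTruth(
        positions=positions,
        ref=ref,
        level_set1=level1,
        level_set2=level2,
        windows=pd.DataFrame(window_rows),
    )
    ref_seq = "".join(BASES[b] for b in seq_codes)
    return SimResult(table, regions, windows, truth, {_CHROM: ref_seq}, params)


def emit_micro_bam(
    table: CountTable,
    ref_seqs: Mapping[str, str],
    outdir: str | Path,
    base_quality: int = 30,
    mapping_quality: int = 60,
    extra_reads: Sequence[tuple[str, str, int, str, int]] = (),
) -> tuple[Path, dict[str, Path]]:
    """Materialize a count table as FASTA + per-sample indexed micro-BAMs.

    Every counted base becomes one single-base read (CIGAR ``1M``) at the
    site, emitted at ``base_quality``; running the pileup on the emitted
    files reproduces the table exactly. ``extra_reads`` entries
    ``(sample, chrom, pos, base, quality)`` add reads at arbitrary base
    qualities, e.g. straddling a filter threshold. Returns the FASTA path
    and a mapping sample -> BAM path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / "ref.fa"
    with open(fasta_path, "w") as handle:
        for chrom in sorted(ref_seqs):
            handle.write(f">{chrom}\n")
            seq = ref_seqs[chrom]
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(fasta_path))

    chrom_order = sorted(ref_seqs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(ref_seqs[c])} for c in chrom_order],
        }
    )
    reads_by_sample: dict[str, list[tuple[int, int, str, int]]] = {
        s: [] for s in table.samples
    }
    for chrom, cc in table.chroms.items():
        cid = chrom_order.index(chrom)
        for si, sample in enumerate(table.samples):
            nz_pos, nz_base = np.nonzero(cc.counts[si])
            for pi, bi in zip(nz_pos, nz_base):
                n = int(cc.counts[si, pi, bi])
                reads_by_sample[sample].extend(
                    [(cid, int(cc.positions[pi]), BASES[bi], base_quality)] * n
                )
    for sample, chrom, pos, base, quality in extra_reads:
        reads_by_sample[sample].append(
            (chrom_order.index(chrom), pos, base.upper(), quality)
        )

    bam_paths: dict[str, Path] = {}
    for sample, reads in reads_by_sample.items():
        path = outdir / f"{sample}.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for ri, (cid, pos, base, quality) in enumerate(sorted(reads)):
                aln = pysam.AlignedSegment(header)
                aln.query_name = f"{sample}_r{ri}"
                aln.flag = 0
                aln.reference_id = cid
                aln.reference_start = pos
                aln.mapping_quality = mapping_quality
                aln.cigarstring = "1M"
                aln.query_sequence = base
                aln.query_qualities = pysam.qualitystring_to_array(chr(quality + 33))
                bam.write(aln)
        pysam.index(str(path))
        bam_paths[sample] = path
    return fasta_path, bam_paths
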
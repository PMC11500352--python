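"""Run configuration and mismatch-class vocabulary.

A mismatch class is an ordered pair of distinct reference/observed bases,
written ``"AG"`` for reference A observed as G. A-to-I editing surfaces in
RNA-seq as the ``AG`` class (inosine is sequenced as guanosine); the other
eleven classes carry no editing signal and serve as decoy null sets for the
empirical q-value estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: the 12 ordered reference->observed substitution classes
MISMATCH_CLASSES = tuple(x + y for x in BASES for y in BASES if x != y)


def validate_mismatch_class(cls: str) -> str:
    cls = cls.upper().replace(">", "").replace("-", "")
    if cls not in MISMATCH_CLASSES:
        raise ValueError(
            f"invalid mismatch class {cls!r}; expected one of {MISMATCH_CLASSES}"
        )
    return cls


@dataclass(frozen=True)
class RunConfig:
    """All thresholds and conventions of one analysis run.

    Parameters
    ----------
    window_size
        Width in nucleotides of the non-overlapping windows regions are
        tiled into (default 51).
    min_coverage
        Minimum read coverage a position must reach *in every sample of
        both sets* to contribute to any window signal (default 10).
    snp_filter_enabled
        Apply the heuristic SNP exclusion (default off).
    snp_freq_threshold
        A position is excluded for a mismatch class when any sufficiently
        covered sample shows a mismatch frequency at or above this fraction
        (default 0.80); likely a genomic variant rather than editing.
    focal_mismatch
        The class scored with q values; ``"AG"`` for A-to-I editing.
    min_base_quality
        Phred score a base call must reach to be counted in the pileup.
    min_mapping_quality
        Minimum read mapping quality.
    min_sites_per_window
        Windows with fewer eligible positions are dropped for that class.
    exclude_duplicates
        Skip duplicate-flagged reads in the pileup (default: counted).
    normalize_decoy_size
        Scale each decoy tail count by |focal set| / |decoy set| before
        forming the q estimate, for runs comparing classes with very
        different window counts (default: raw count ratio).
    """

    window_size: int = 51
    min_coverage: int = 10
    snp_filter_enabled: bool = False
    snp_freq_threshold: float = 0.80
    focal_mismatch: str = "AG"
    q_cap: float = 1.0
    min_base_quality: int = 20
    min_mapping_quality: int = 0
    min_sites_per_window: int = 1
    exclude_duplicates: bool = False
    normalize_decoy_size: bool = False
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")
        if not 0.0 < self.snp_freq_threshold <= 1.0:
            raise ValueError("snp_freq_threshold must be in (0, 1]")
        if self.min_sites_per_window < 1:
            raise ValueError("min_sites_per_window must be >= 1")
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.q_cap != 1.0:
            raise ValueError("q_cap is fixed at 1.0")
        object.__setattr__(
            self, "focal_mismatch", validate_mismatch_class(self.focal_mismatch)
        )

    @property
    def decoy_classes(self) -> tuple[str, ...]:
        """The eleven classes used as null sets for the focal class."""
        return tuple(c for c in MISMATCH_CLASSES if c != self.focal_mismatch)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a ``key = value`` configuration file mirroring the fields."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            kwargs[key] = _coerce(key, value)
        return cls(**kwargs)


def _coerce(key: str, value: str):
    if key in {"snp_filter_enabled", "exclude_duplicates", "normalize_decoy_size"}:
        lowered = value.lower()
        if lowered in {"true", "1", "yes", "on"}:
            return True
        if lowered in {"false", "0", "no", "off"}:
            return False
        raise ValueError(f"cannot interpret {value!r} as a boolean for {key}")
    if key in {"snp_freq_threshold", "q_cap"}:
        return float(value)
    if key == "focal_mismatch":
        return value
    if key == "random_seed":
        return None if value.lower() in {"none", ""} else int(value)
    return int(value)
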
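"""Empirical q values from decoy mismatch classes.

Most differences observed for non-focal mismatch classes (e.g. G->A when
the focal class is A->G) arise from sequencing/PCR errors and unfiltered
variants rather than editing, so each of the eleven non-focal delta sets
approximates the null distribution of window deltas. For an observed focal
delta d the per-decoy estimate is the tail-count ratio

    q_hat(d) = #{v in D_decoy : v as or more extreme than d}
             / #{v in D_focal : v as or more extreme than d},

where "as or more extreme" means <= d for d < 0 and >= d for d > 0. The
median of the available per-decoy estimates is the raw q, capped at 1
(a decoy tail can exceed the focal tail), and a running minimum within
each sign tail enforces that q never increases as |delta| grows. Windows
with delta exactly 0 are maximally non-significant (q = 1).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "tail_count",
    "empirical_q",
    "aggregate_decoys",
    "monotonize",
    "qvalues_for_focal",
]


def tail_count(values: Sequence[float] | np.ndarray, threshold: float) -> int:
    """Number of values as or more extreme than ``threshold``.

    For a negative threshold this is #{v <= threshold}; for a positive one
    #{v >= threshold}; a threshold of exactly 0 is the degenerate
    maximally-non-extreme case and returns the full list length.
    """
    arr = np.asarray(values, dtype=float)
    if threshold < 0:
        return int(np.count_nonzero(arr <= threshold))
    if threshold > 0:
        return int(np.count_nonzero(arr >= threshold))
    return arr.size


def empirical_q(
    delta0: float,
    focal: Sequence[float] | np.ndarray,
    decoy: Sequence[float] | np.ndarray,
    normalize_decoy_size: bool = False,
) -> float | None:
    """Single-decoy q estimate for one focal delta.

    ``delta0`` must belong to the focal set so the denominator is >= 1.
    Returns ``None`` when the decoy set is empty (no estimate available).
    """
    decoy = np.asarray(decoy, dtype=float)
    if decoy.size == 0:
        return None
    if delta0 == 0:
        return 1.0
    denominator = tail_count(focal, delta0)
    if denominator == 0:
        raise ValueError("delta0 must be a member of the focal set")
    numerator = tail_count(decoy, delta0)
    if normalize_decoy_size:
        numerator = numerator * len(np.asarray(focal)) / decoy.size
    return min(1.0, numerator / denominator)


def aggregate_decoys(estimates: Sequence[float | None]) -> float:
    """Median of the available per-decoy estimates.

    Even counts take the midpoint of the two central values. Raises when
    no decoy produced an estimate: without a single non-focal delta set no
    empirical null can be formed.
    """
    available = [e for e in estimates if e is not None]
    if not available:
        raise ValueError(
            "no decoy class has any window: cannot form an empirical null; "
            "check coverage thresholds and target regions"
        )
    return float(np.median(available))


def monotonize(records: pd.DataFrame) -> pd.DataFrame:
    """Enforce tail monotonicity of q over |delta|.

    Within each sign tail, q_final(i) = min{ q_raw(j) : |delta_j| <= |delta_i| },
    a running minimum, so significance never decreases for more extreme
    deltas; tied deltas receive identical q_final. Zero deltas keep
    q_final = min(1, q_raw). Requires columns ``delta`` and ``q_raw``;
    returns a copy with ``q_final`` added.
    """
    out = records.copy()
    out["q_final"] = np.minimum(1.0, out["q_raw"].to_numpy(dtype=float))
    for sign in (-1, 1):
        mask = np.sign(out["delta"].to_numpy(dtype=float)) == sign
        if not mask.any():
            continue
        sub = out.loc[mask, ["delta", "q_raw"]].copy()
        sub["absdelta"] = sub["delta"].abs()
        sub = sub.sort_values("absdelta", kind="stable")
        cummin = np.minimum(1.0, sub["q_raw"].to_numpy(dtype=float))
        cummin = np.minimum.accumulate(cummin)
        sub["q_final"] = cummin
        # ties at identical |delta| share the tie group's final (smallest) value
        sub["q_final"] = sub.groupby("absdelta")["q_final"].transform("min")
        out.loc[sub.index, "q_final"] = sub["q_final"]
    return out


def qvalues_for_focal(
    delta_sets: Mapping[str, pd.DataFrame], cfg: RunConfig
) -> pd.DataFrame:
    """q values for every window of the configured focal class.

    ``delta_sets`` maps mismatch classes to window tables carrying at least
    ``window_id`` and ``delta`` columns (as produced by
    :func:`diffedit.windows.build_delta_sets`). Decoy classes without any
    window are skipped; the remaining per-decoy estimates are aggregated by
    median and monotonized. Returns the focal table extended with one
    ``qhat_<class>`` column per available decoy plus ``q_raw`` and
    ``q_final``. An empty focal set returns an empty frame.
    """
    focal_frame = delta_sets[cfg.focal_mismatch]
    out = focal_frame.copy()
    if len(focal_frame) == 0:
        out["q_raw"] = pd.Series(dtype=float)
        out["q_final"] = pd.Series(dtype=float)
        return out

    focal = focal_frame["delta"].to_numpy(dtype=float)
    n_focal = focal.size
    focal_sorted = np.sort(focal)
    negative = focal < 0
    positive = focal > 0
    # focal tail counts (denominators), vectorized over windows
    denom = np.full(n_focal, n_focal, dtype=float)  # delta == 0 placeholder
    denom[negative] = np.searchsorted(focal_sorted, focal[negative], side="right")
    denom[positive] = n_focal - np.searchsorted(
        focal_sorted, focal[positive], side="left"
    )

    decoy_columns: list[str] = []
    estimates: list[np.ndarray] = []
    for decoy_class in cfg.decoy_classes:
        decoy_frame = delta_sets.get(decoy_class)
        if decoy_frame is None or len(decoy_frame) == 0:
            continue
        decoy_sorted = np.sort(decoy_frame["delta"].to_numpy(dtype=float))
        numer = np.zeros(n_focal, dtype=float)
        numer[negative] = np.searchsorted(decoy_sorted, focal[negative], side="right")
        numer[positive] = decoy_sorted.size - np.searchsorted(
            decoy_sorted, focal[positive], side="left"
        )
        if cfg.normalize_decoy_size:
            numer = numer * n_focal / decoy_sorted.size
        qhat = np.minimum(1.0, numer / denom)
        qhat[~(negative | positive)] = 1.0  # delta == 0 convention
        decoy_columns.append(f"qhat_{decoy_class}")
        estimates.append(qhat)

    if not estimates:
        raise ValueError(
            "no decoy class has any window: cannot form an empirical null; "
            "check coverage thresholds and target regions"
        )
    stacked = np.stack(estimates, axis=1)
    for column, values in zip(decoy_columns, estimates):
        out[column] = values
    out["q_raw"] = np.median(stacked, axis=1)
    return monotonize(out)
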
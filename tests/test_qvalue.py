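"""Empirical q estimation: tail counts, decoy aggregation, monotonization."""

import numpy as np
import pandas as pd
import pytest

from oracle import ALL_CLASSES, oracle_qvalues, oracle_tail_count

from diffedit import (
    RunConfig,
    aggregate_decoys,
    empirical_q,
    monotonize,
    qvalues_for_focal,
    tail_count,
)


def frame_from_deltas(deltas):
    return pd.DataFrame(
        {"window_id": [f"w{i}" for i in range(len(deltas))], "delta": deltas}
    )


class TestTailCount:
    @pytest.mark.parametrize(
        "threshold,expected",
        [(-2.0, 2), (1.5, 1), (-10.0, 0), (10.0, 0), (0.0, 5)],
    )
    def test_matches_brute_force(self, threshold, expected):
        values = [-3, -2, -1, 1, 2]
        assert tail_count(values, threshold) == expected
        assert oracle_tail_count(values, threshold) == expected


class TestEmpiricalQ:
    def test_decoy_identical_to_focal_gives_one(self):
        focal = [-3.0, -2.0, -1.0, 1.0, 2.0]
        for d0 in focal:
            assert empirical_q(d0, focal, list(focal)) == 1.0

    def test_no_decoy_value_as_extreme_gives_zero(self):
        assert empirical_q(-2.0, [-3.0, -2.0, 1.0], [-0.5, 0.3]) == 0.0

    def test_hand_computed_ratios(self):
        focal = [-3.0, -2.0, -1.0, 1.0, 2.0]
        decoy = [-1.0, -0.5, 0.5]
        assert empirical_q(-2.0, focal, decoy) == 0.0  # 0/2
        assert empirical_q(-1.0, focal, decoy) == pytest.approx(1 / 3)
        assert empirical_q(1.0, focal, decoy) == 0.0  # no decoy >= 1
        assert empirical_q(1.0, focal, [-1.0, 0.5, 1.5]) == pytest.approx(0.5)  # 1/2

    def test_empty_decoy_is_unavailable(self):
        assert empirical_q(-1.0, [-1.0], []) is None

    def test_size_normalization_scales_numerator(self):
        focal = [-2.0, -1.0, 1.0]
        decoy = [-2.5]  # a third of the focal size
        raw = empirical_q(-2.0, focal, decoy)
        scaled = empirical_q(-2.0, focal, decoy, normalize_decoy_size=True)
        assert raw == 1.0
        assert scaled == 1.0  # capped: 1 * 3/1 / 1


class TestAggregate:
    def test_median_conventions(self):
        assert aggregate_decoys([0.0] * 11) == 0.0
        assert aggregate_decoys([0.0, 0.5, 1.0]) == 0.5
        assert aggregate_decoys([0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.25)
        assert aggregate_decoys([0.3, None, 0.7]) == pytest.approx(0.5)

    def test_no_available_decoy_is_an_error(self):
        with pytest.raises(ValueError, match="no decoy"):
            aggregate_decoys([None, None])


class TestMonotonize:
    def test_running_minimum_within_tail(self):
        records = pd.DataFrame(
            {"delta": [0.1, 0.2, 0.3, 0.4], "q_raw": [0.5, 0.3, 0.4, 0.1]}
        )
        out = monotonize(records)
        assert list(out["q_final"]) == [0.5, 0.3, 0.3, 0.1]

    def test_non_increasing_sequence_is_fixed_point(self):
        records = pd.DataFrame(
            {"delta": [-0.1, -0.2, -0.3], "q_raw": [0.9, 0.5, 0.2]}
        )
        assert list(monotonize(records)["q_final"]) == [0.9, 0.5, 0.2]

    def test_single_record_and_zero_delta(self):
        out = monotonize(pd.DataFrame({"delta": [0.5, 0.0], "q_raw": [0.7, 0.2]}))
        assert out.loc[0, "q_final"] == 0.7
        assert out.loc[1, "q_final"] == 0.2  # zero delta: min(1, q_raw)

    def test_tails_are_independent_and_ties_share_q(self):
        records = pd.DataFrame(
            {
                "delta": [-0.5, -0.1, 0.1, 0.5, 0.5],
                "q_raw": [0.05, 0.8, 0.9, 0.6, 0.3],
            }
        )
        out = monotonize(records)
        assert out.loc[0, "q_final"] == 0.05
        assert out.loc[1, "q_final"] == 0.8  # unaffected by positive tail
        assert out.loc[3, "q_final"] == out.loc[4, "q_final"] == 0.3


class TestFocalQValues:
    def cfg(self, **kw):
        return RunConfig(**kw)

    def test_identical_delta_sets_give_q_one_everywhere(self, rng):
        deltas = rng.normal(size=30)
        sets = {cls: frame_from_deltas(deltas) for cls in ALL_CLASSES}
        out = qvalues_for_focal(sets, self.cfg())
        assert (out["q_raw"] == 1.0).all()
        assert (out["q_final"] == 1.0).all()

    def test_separated_focal_tail_reaches_zero(self, rng):
        focal = np.concatenate([rng.normal(0, 0.01, 50), [-5.0, -4.0, -4.5]])
        sets = {
            cls: frame_from_deltas(rng.normal(0, 0.01, 50))
            for cls in ALL_CLASSES
            if cls != "AG"
        }
        sets["AG"] = frame_from_deltas(focal)
        out = qvalues_for_focal(sets, self.cfg())
        extreme = out[out["delta"] <= -4.0]
        assert (extreme["q_final"] == 0.0).all()

    def test_decoy_order_is_irrelevant(self, rng):
        sets = {cls: frame_from_deltas(rng.normal(size=20)) for cls in ALL_CLASSES}
        out1 = qvalues_for_focal(sets, self.cfg())
        reordered = dict(reversed(list(sets.items())))
        out2 = qvalues_for_focal(reordered, self.cfg())
        assert np.array_equal(out1["q_final"], out2["q_final"])

    def test_empty_decoys_are_skipped(self, rng):
        sets = {cls: frame_from_deltas([]) for cls in ALL_CLASSES}
        sets["AG"] = frame_from_deltas(rng.normal(size=10))
        sets["GA"] = frame_from_deltas(rng.normal(size=10))
        out = qvalues_for_focal(sets, self.cfg())
        assert [c for c in out.columns if c.startswith("qhat_")] == ["qhat_GA"]

    def test_empty_focal_returns_empty(self, rng):
        sets = {cls: frame_from_deltas(rng.normal(size=10)) for cls in ALL_CLASSES}
        sets["AG"] = frame_from_deltas([])
        out = qvalues_for_focal(sets, self.cfg())
        assert len(out) == 0 and "q_final" in out.columns

    def test_q_in_unit_interval_and_tail_monotone(self, rng):
        for _ in range(10):
            sets = {
                cls: frame_from_deltas(rng.normal(size=int(rng.integers(1, 40))))
                for cls in ALL_CLASSES
            }
            out = qvalues_for_focal(sets, self.cfg())
            assert out["q_final"].between(0, 1).all()
            for sign in (-1, 1):
                tail = out[np.sign(out["delta"]) == sign].copy()
                tail = tail.sort_values("delta", key=abs)
                assert (tail["q_final"].diff().dropna() <= 1e-15).all()

    @pytest.mark.parametrize("normalize", [False, True])
    def test_matches_brute_force_exactly(self, rng, normalize):
        for _ in range(20):
            sets = {}
            for cls in ALL_CLASSES:
                n = int(rng.integers(0, 30)) if cls != "AG" else int(rng.integers(1, 30))
                deltas = np.round(rng.normal(size=n), 3)  # rounding forces ties
                sets[cls] = frame_from_deltas(deltas)
            cfg = self.cfg(normalize_decoy_size=normalize)
            out = qvalues_for_focal(sets, cfg)
            expected = oracle_qvalues(
                {
                    cls: dict(zip(f["window_id"], f["delta"]))
                    for cls, f in sets.items()
                },
                "AG",
                normalize=normalize,
            )
            for _, row in out.iterrows():
                q_raw, q_final = expected[row["window_id"]]
                assert row["q_raw"] == q_raw
                assert row["q_final"] == q_final
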
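"""Window tiling and editing-signal computation (ratios, set means, deltas)."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_table, random_case
from oracle import oracle_delta_sets

from diffedit import (
    Region,
    RunConfig,
    build_delta_sets,
    editing_ratio,
    tile_windows,
    window_signal_frame,
)


class TestTiling:
    @pytest.mark.parametrize(
        "region,size,expected",
        [
            ((0, 153), 51, [(0, 51), (51, 102), (102, 153)]),
            ((0, 60), 51, [(0, 51), (51, 60)]),
            ((10, 40), 51, [(10, 40)]),
        ],
        ids=["exact-tiling", "remainder-window", "short-region"],
    )
    def test_tiles(self, region, size, expected):
        windows = tile_windows([Region("c", *region)], size)
        assert [(w.start, w.end) for w in windows] == expected

    def test_windows_never_span_region_boundaries(self):
        regions = [Region("c", 0, 60), Region("c", 100, 130)]
        windows = tile_windows(regions, 51)
        assert [(w.start, w.end) for w in windows] == [(0, 51), (51, 60), (100, 130)]

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            tile_windows([Region("c", 0, 10)], 0)


def test_editing_ratio_bounds():
    assert editing_ratio(3, 10) == 0.3
    assert editing_ratio(0, 10) == 0.0
    assert editing_ratio(10, 10) == 1.0
    with pytest.raises(ValueError):
        editing_ratio(11, 10)


def simple_sites(ratios_by_sample, cov=20, pos0=0):
    """Ref-A sites where sample s shows ratios_by_sample[s][i] G fraction."""
    samples = list(ratios_by_sample)
    n = len(next(iter(ratios_by_sample.values())))
    sites = []
    for i in range(n):
        quads = {}
        for s in samples:
            m = int(round(ratios_by_sample[s][i] * cov))
            quads[s] = (cov - m, 0, m, 0)
        sites.append(("c", pos0 + i, "A", quads))
    return sites


class TestEligibility:
    def test_low_coverage_in_one_sample_drops_site_for_all(self):
        sites = [
            ("c", 0, "A", {"a": (10, 0, 2, 0), "b": (5, 0, 4, 0)}),  # b has c=9
            ("c", 1, "A", {"a": (8, 0, 2, 0), "b": (12, 0, 3, 0)}),
        ]
        table = make_table(sites, ["a"], ["b"])
        frame = window_signal_frame(
            table, tile_windows([Region("c", 0, 10)], 10), RunConfig(), "AG"
        )
        assert frame.loc[0, "n_sites"] == 1
        assert frame.loc[0, "e_a"] == pytest.approx(0.2)

    def test_wrong_ref_base_ineligible(self):
        sites = [("c", 0, "C", {"a": (0, 18, 2, 0), "b": (0, 15, 5, 0)})]
        table = make_table(sites, ["a"], ["b"])
        frame = window_signal_frame(
            table, tile_windows([Region("c", 0, 5)], 5), RunConfig(), "AG"
        )
        assert len(frame) == 0  # no eligible site -> window dropped

    def test_min_sites_per_window(self):
        sites = simple_sites({"a": [0.1], "b": [0.2]})
        table = make_table(sites, ["a"], ["b"])
        windows = tile_windows([Region("c", 0, 5)], 5)
        assert len(window_signal_frame(table, windows, RunConfig(), "AG")) == 1
        cfg2 = RunConfig(min_sites_per_window=2)
        assert len(window_signal_frame(table, windows, cfg2, "AG")) == 0


class TestSignals:
    def test_signal_is_sum_of_ratios_and_delta_is_mean_difference(self):
        sites = simple_sites({"a": [0.1, 0.2, 0.0], "b": [0.3, 0.3, 0.2]}, cov=20)
        table = make_table(sites, ["a"], ["b"])
        frame = window_signal_frame(
            table, tile_windows([Region("c", 0, 3)], 51), RunConfig(), "AG"
        )
        row = frame.iloc[0]
        assert row["e_a"] == pytest.approx(0.3)
        assert row["e_b"] == pytest.approx(0.8)
        assert row["delta"] == pytest.approx(0.5)
        assert row["n_sites"] == 3

    def test_self_comparison_yields_zero_deltas_everywhere(self, rng):
        sites, samples1, _, regions, cfg_kwargs = random_case(rng)
        mirrored = []
        for chrom, pos, ref, quads in sites:
            quads2 = {s: quads.get(s, (0, 0, 0, 0)) for s in samples1}
            quads2.update(
                {f"m_{s}": quads.get(s, (0, 0, 0, 0)) for s in samples1}
            )
            mirrored.append((chrom, pos, ref, quads2))
        table = make_table(mirrored, samples1, [f"m_{s}" for s in samples1])
        cfg = RunConfig(**cfg_kwargs)
        windows = tile_windows(
            [Region(c, s, e) for c, s, e in regions], cfg.window_size
        )
        for frame in build_delta_sets(table, windows, cfg).values():
            assert (frame["delta"] == 0).all()

    def test_swapping_sets_negates_delta(self, rng):
        for _ in range(5):
            sites, samples1, samples2, regions, cfg_kwargs = random_case(rng)
            cfg = RunConfig(**cfg_kwargs)
            windows = tile_windows(
                [Region(c, s, e) for c, s, e in regions], cfg.window_size
            )
            forward = make_table(sites, samples1, samples2)
            backward = make_table(sites, samples2, samples1)
            for cls in ("AG", "CT", "GA"):
                f = window_signal_frame(forward, windows, cfg, cls)
                b = window_signal_frame(backward, windows, cfg, cls)
                assert np.array_equal(f["window_id"], b["window_id"])
                assert np.array_equal(
                    f["delta"].to_numpy(float), -b["delta"].to_numpy(float)
                )

    def test_constant_variant_fraction_leaves_delta_unchanged(self):
        """A homozygous-like mismatch fraction added identically in every
        sample of both sets shifts both set means equally: delta invariant."""
        base = {"a": [0.1, 0.2], "b": [0.4, 0.1], "x": [0.2, 0.2], "y": [0.0, 0.5]}
        plain = simple_sites(base, cov=100)
        shifted = simple_sites(
            {s: [r + 0.3 for r in rs] for s, rs in base.items()}, cov=100
        )
        windows = tile_windows([Region("c", 0, 2)], 51)
        cfg = RunConfig()
        d_plain = window_signal_frame(
            make_table(plain, ["a", "x"], ["b", "y"]), windows, cfg, "AG"
        )["delta"]
        d_shift = window_signal_frame(
            make_table(shifted, ["a", "x"], ["b", "y"]), windows, cfg, "AG"
        )["delta"]
        assert abs(d_plain.iloc[0] - d_shift.iloc[0]) < 1e-12


class TestOracleEquivalence:
    def test_deltas_match_brute_force_bitwise_on_dyadic_tables(self, rng):
        """Power-of-two coverages make every ratio and sum an exact binary
        fraction, so the vectorized pipeline must agree bitwise with a
        plain-loop evaluation of the ratio/signal/mean/delta chain."""
        for _ in range(25):
            sites, s1, s2, regions, cfg_kwargs = random_case(rng, dyadic=True)
            cfg = RunConfig(**cfg_kwargs)
            expected = oracle_delta_sets(
                sites, s1, s2, regions, cfg.window_size, cfg.min_coverage,
                cfg.snp_filter_enabled, cfg.snp_freq_threshold,
                cfg.min_sites_per_window,
            )
            table = make_table(sites, s1, s2)
            windows = tile_windows(
                [Region(c, s, e) for c, s, e in regions], cfg.window_size
            )
            got = build_delta_sets(table, windows, cfg)
            for cls, frame in got.items():
                exp = expected[cls]
                assert set(frame["window_id"]) == set(exp)
                for _, row in frame.iterrows():
                    n_sites, e, z1, z2, delta = exp[row["window_id"]]
                    assert row["n_sites"] == n_sites
                    assert row["delta"] == delta  # bitwise
                    assert row["z_set1"] == z1 and row["z_set2"] == z2
                    for s in s1 + s2:
                        assert row[f"e_{s}"] == e[s]

    def test_deltas_match_brute_force_closely_on_arbitrary_coverage(self, rng):
        for _ in range(10):
            sites, s1, s2, regions, cfg_kwargs = random_case(rng, dyadic=False)
            cfg = RunConfig(**cfg_kwargs)
            expected = oracle_delta_sets(
                sites, s1, s2, regions, cfg.window_size, cfg.min_coverage,
                cfg.snp_filter_enabled, cfg.snp_freq_threshold,
                cfg.min_sites_per_window,
            )
            table = make_table(sites, s1, s2)
            windows = tile_windows(
                [Region(c, s, e) for c, s, e in regions], cfg.window_size
            )
            got = build_delta_sets(table, windows, cfg)
            for cls, frame in got.items():
                assert set(frame["window_id"]) == set(expected[cls])
                for _, row in frame.iterrows():
                    delta = expected[cls][row["window_id"]][4]
                    assert row["delta"] == pytest.approx(delta, abs=1e-12)
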
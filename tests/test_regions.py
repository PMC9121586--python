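"""Candidate-region calling, interval arithmetic and the marker scan."""

import numpy as np
import pandas as pd
import pytest

from bsascan.index import WindowConfig, compute_indices, sliding_window
from bsascan.nullband import NullCITable, NullSimConfig, build_ci_table
from bsascan.regions import (CandidateRegion, MarkerInterval,
                             call_candidate_regions, interval_length,
                             regions_to_frame, single_marker_scan)
from bsascan.simulate import simulate_experiment


def window_frame(rows):
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "midpoint", "n_snps",
        "mean_index_high", "mean_index_low", "mean_delta", "mean_depth"])


def constant_table(lo, up, levels=(0.95, 0.99), depths=(20,)):
    cfg = NullSimConfig(depths=depths, ci_levels=levels)
    bands = {(d, lv): (lo, up) for d in depths for lv in levels}
    return NullCITable(config=cfg, bands=bands)


class TestCallCandidateRegions:
    def test_all_windows_inside_band_give_no_region(self):
        win = window_frame([
            ("chr1", 1, 100, 50, 3, 0.5, 0.4, 0.1, 20.0),
            ("chr1", 51, 150, 100, 3, 0.5, 0.6, -0.1, 20.0)])
        table = constant_table(-0.3, 0.3)
        assert call_candidate_regions(win, table, 0.99) == []

    def test_degenerate_zero_band_calls_every_nonzero_window(self):
        win = window_frame([
            ("chr1", 1, 100, 50, 3, 0.5, 0.4, 0.1, 20.0),
            ("chr1", 101, 200, 150, 3, 0.6, 0.4, 0.2, 20.0),
            ("chr2", 1, 100, 50, 3, 0.4, 0.6, -0.2, 20.0)])
        table = constant_table(0.0, 0.0)
        regions = call_candidate_regions(win, table, 0.99)
        assert [(r.chrom, r.start, r.end, r.sign) for r in regions] == [
            ("chr1", 1, 200, 1), ("chr2", 1, 100, -1)]

    def test_opposite_signs_never_merge(self):
        win = window_frame([
            ("chr1", 1, 100, 50, 3, 0.9, 0.1, 0.8, 20.0),
            ("chr1", 51, 150, 100, 3, 0.1, 0.9, -0.8, 20.0)])
        table = constant_table(-0.3, 0.3)
        regions = call_candidate_regions(win, table, 0.99)
        assert len(regions) == 2
        assert {r.sign for r in regions} == {1, -1}

    def test_gap_splits_runs(self):
        win = window_frame([
            ("chr1", 1, 100, 50, 3, 0.9, 0.1, 0.8, 20.0),
            ("chr1", 500, 600, 550, 3, 0.9, 0.1, 0.8, 20.0)])
        table = constant_table(-0.3, 0.3)
        assert len(call_candidate_regions(win, table, 0.99)) == 2

    def test_peak_delta_and_window_count(self):
        win = window_frame([
            ("chr1", 1, 100, 50, 3, 0.9, 0.1, 0.5, 20.0),
            ("chr1", 51, 150, 100, 3, 0.9, 0.1, 0.8, 20.0),
            ("chr1", 101, 200, 150, 3, 0.9, 0.1, 0.6, 20.0)])
        table = constant_table(-0.3, 0.3)
        (region,) = call_candidate_regions(win, table, 0.99)
        assert region.peak_delta == pytest.approx(0.8)
        assert region.n_windows == 3

    def test_min_windows_drops_isolated_hits(self):
        win = window_frame([
            ("chr1", 1, 100, 50, 3, 0.9, 0.1, 0.8, 20.0)])
        table = constant_table(-0.3, 0.3)
        assert call_candidate_regions(win, table, 0.99, min_windows=2) == []

    def test_planted_qtl_recovered_in_synthetic_scan(self):
        # full-length chromosomes so linkage to the QTL decays within the
        # chromosome and the signal is one contiguous region
        from bsascan.simulate import F2SimParams
        sim = F2SimParams(
            chrom_lengths={"chr1": 30_000_000, "chr2": 30_000_000,
                           "chr3": 30_000_000},
            snp_spacing=20_000, qtl_chrom="chr2", qtl_pos=15_000_000,
            n_f2=278, pool_size=20, seed=7)
        exp = simulate_experiment(sim)
        records = compute_indices(exp.sites)
        windows = sliding_window(records, WindowConfig(),
                                 sim.chrom_lengths)
        table = build_ci_table(NullSimConfig(
            pool_size=sim.pool_size, n_iterations=2_000,
            depths=tuple(range(10, 41)), seed=1))
        regions = call_candidate_regions(windows, table, 0.99)
        assert {r.chrom for r in regions} == {"chr2"}
        containing = [r for r in regions
                      if r.contains(exp.truth.qtl_chrom, exp.truth.qtl_pos)]
        assert len(containing) == 1
        # and the QTL region carries the genome-wide peak signal
        assert containing[0].peak_delta == max(
            r.peak_delta for r in regions)

    def test_stricter_level_regions_nest_in_looser(self, small_params):
        exp = simulate_experiment(small_params)
        records = compute_indices(exp.sites)
        windows = sliding_window(records, WindowConfig(),
                                 small_params.chrom_lengths)
        table = build_ci_table(NullSimConfig(
            pool_size=small_params.pool_size, n_iterations=2_000,
            depths=tuple(range(10, 41)), seed=1))
        strict = call_candidate_regions(windows, table, 0.99)
        loose = call_candidate_regions(windows, table, 0.95)
        for r in strict:
            assert any(q.chrom == r.chrom and q.start <= r.start
                       and q.end >= r.end for q in loose)

    def test_empty_windows_give_empty_frame(self):
        table = constant_table(-0.3, 0.3)
        assert call_candidate_regions(window_frame([]), table, 0.99) == []
        assert regions_to_frame([]).empty


class TestIntervalLength:
    def test_fine_map_flanking_markers(self):
        # the two flanking SNP markers of the fine-mapped locus
        interval = MarkerInterval("chr3", 39_531_980, 39_626_163)
        bp, kb = interval_length(interval)
        assert bp == 94_183
        assert kb == 94

    def test_round_kb(self):
        bp, kb = interval_length(MarkerInterval("chr1", 1000, 2000))
        assert (bp, kb) == (1000, 1)

    def test_region_endpoint_arithmetic(self):
        bp, _ = interval_length(
            MarkerInterval("chr3", 36_620_000, 39_770_000))
        assert bp == 3_150_000

    def test_translation_invariance(self):
        for shift in (0, 10, 12_345):
            bp, _ = interval_length(
                MarkerInterval("chr1", 100 + shift, 700 + shift))
            assert bp == 600

    def test_swapped_markers_are_an_error(self):
        with pytest.raises(ValueError):
            MarkerInterval("chr1", 2000, 1000)
        with pytest.raises(ValueError):
            MarkerInterval("chr1", 1000, 1000)


class TestSingleMarkerScan:
    def test_phenotype_equal_to_dosage_is_perfect_fit(self, rng):
        G = rng.integers(0, 3, size=(60, 5))
        y = G[:, 2].astype(float)
        res = single_marker_scan(G, y)
        assert res["pve"].iloc[2] == pytest.approx(1.0)
        assert np.isinf(res["lod"].iloc[2])

    def test_constant_phenotype_gives_zero_everywhere(self, rng):
        G = rng.integers(0, 3, size=(40, 4))
        res = single_marker_scan(G, np.full(40, 3.3))
        assert (res["lod"] == 0).all() and (res["pve"] == 0).all()

    def test_pure_noise_has_small_pve(self):
        rng = np.random.default_rng(42)
        G = rng.binomial(2, 0.5, size=(278, 50))
        y = rng.normal(size=278)
        res = single_marker_scan(G, y)
        assert res["pve"].max() < 0.06

    def test_pve_matches_variance_decomposition_oracle(self):
        # brute-force oracle: fit the class means on the sample itself and
        # recompute PVE from the resulting residuals
        rng = np.random.default_rng(7)
        n, a, d, sigma = 278, 1.0, 0.6, 1.0
        G = rng.binomial(2, 0.5, size=(n, 1))
        dos = G[:, 0].astype(float)
        y = a * (dos - 1) + d * (dos == 1) + rng.normal(0, sigma, n)
        res = single_marker_scan(G, y)

        fitted = np.empty(n)
        for c in (0, 1, 2):
            mask = dos == c
            if mask.any():
                fitted[mask] = y[mask].mean()
        pve_oracle = 1 - np.sum((y - fitted) ** 2) / \
            np.sum((y - y.mean()) ** 2)
        assert res["pve"].iloc[0] == pytest.approx(pve_oracle, abs=1e-12)
        # and the oracle itself sits near the theoretical decomposition
        var_g = np.var(fitted)
        theory = var_g / (var_g + sigma ** 2)
        assert res["pve"].iloc[0] == pytest.approx(theory, abs=0.05)

    def test_lod_is_nonnegative(self, rng):
        G = rng.integers(0, 3, size=(100, 20))
        y = rng.normal(size=100)
        assert (single_marker_scan(G, y)["lod"] >= 0).all()

    def test_shape_and_missing_validation(self):
        with pytest.raises(ValueError):
            single_marker_scan(np.zeros((5, 2)), np.zeros(4))
        with pytest.raises(ValueError):
            single_marker_scan(np.zeros((3, 2)),
                               np.array([1.0, np.nan, 2.0]))


class TestCandidateRegionType:
    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            CandidateRegion("chr1", 100, 50, 0.99, 0.5, 1, 1)

    def test_contains(self):
        r = CandidateRegion("chr1", 100, 200, 0.99, 0.5, 1, 1)
        assert r.contains("chr1", 100) and r.contains("chr1", 200)
        assert not r.contains("chr1", 99) and not r.contains("chr2", 150)
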
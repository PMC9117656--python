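import numpy as np
import pytest

from plastcomp.hotspots import merge_hotspots, scan_windows, screen_markers
from plastcomp.simulate import hotspot_demo_config, simulate
from plastcomp.variants import call_variants


def brute_force_counts(ind, window, circular=True):
    n = len(ind)
    ext = np.concatenate([ind, ind]) if circular else ind
    out = {}
    starts = range(n) if circular else range(n - window + 1)
    for s in starts:
        out[s] = int(ext[s:s + window].sum())
    return out


class TestScanWindows:
    def test_uniform_low_density_yields_nothing(self):
        rng = np.random.default_rng(60)
        ind = (rng.random(20_000) < 0.005).astype(int)   # ~5 SNPs per kb
        assert scan_windows(ind, window=1000, min_snps=11) == []

    def test_planted_segment_matches_brute_force(self):
        rng = np.random.default_rng(61)
        ind = np.zeros(10_000, dtype=int)
        pos = rng.choice(np.arange(4_000, 5_000), size=20, replace=False)
        ind[pos] = 1
        wins = scan_windows(ind, window=1000, min_snps=11)
        oracle = brute_force_counts(ind, 1000)
        expect = {s for s, c in oracle.items() if c >= 11}
        assert {w.start for w in wins} == expect
        assert all(oracle[w.start] == w.snp_count for w in wins)

    def test_wraparound_windows_counted(self):
        ind = np.zeros(3_000, dtype=int)
        ind[:6] = 1
        ind[-6:] = 1                      # 12 SNPs across the origin
        wins = scan_windows(ind, window=1000, min_snps=11)
        assert any(w.start >= 2_000 for w in wins)
        linear = scan_windows(ind, window=1000, min_snps=11, circular=False)
        assert linear == []

    def test_window_larger_than_genome_raises(self):
        with pytest.raises(ValueError, match="larger"):
            scan_windows(np.zeros(500, dtype=int), window=1000)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            scan_windows(np.zeros(2000, dtype=int), window=0)
        with pytest.raises(ValueError):
            scan_windows(np.zeros(2000, dtype=int), min_snps=0)


class TestMergeHotspots:
    def test_overlapping_windows_union(self):
        ind = np.zeros(5_000, dtype=int)
        ind[100:1400:50] = 1
        wins = scan_windows(ind, window=1000, min_snps=11)
        if not wins:                       # construct explicit overlap instead
            pytest.skip("construction produced no qualifying windows")
        regions = merge_hotspots(wins, window=1000, variants=ind)
        assert len(regions) >= 1
        # maximality: no two output regions overlap
        spans = sorted((r.start, r.end) for r in regions)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_explicit_merge_and_disjoint(self):
        from plastcomp.hotspots import Window
        regions = merge_hotspots([Window(0, 12), Window(500, 12)],
                                 window=1000, genome_length=50_000)
        assert len(regions) == 1 and (regions[0].start, regions[0].end) == (0, 1500)
        regions = merge_hotspots([Window(0, 12), Window(5_000, 12)],
                                 window=1000, genome_length=50_000)
        assert [(r.start, r.end) for r in regions] == [(0, 1000), (5_000, 6_000)]

    def test_empty_input(self):
        assert merge_hotspots([], window=1000) == []

    def test_counts_recomputed_on_merged_interval(self):
        ind = np.zeros(8_000, dtype=int)
        ind[1000:1200] = 1                 # dense block: 200 SNPs
        wins = scan_windows(ind, window=1000, min_snps=11)
        regions = merge_hotspots(wins, window=1000, variants=ind)
        assert len(regions) == 1
        assert regions[0].snp_count == 200
        assert regions[0].end - regions[0].start == regions[0].length


@pytest.fixture(scope="module")
def demo():
    res = simulate(hotspot_demo_config(seed=62))
    ref = res.genomes[res.reference_id]
    vt = call_variants(res.msa, ref, ingroup=res.ingroup)
    return res, vt


class TestSimulatedHotspots:
    def test_two_planted_segments_two_regions(self, demo):
        res, vt = demo
        wins = scan_windows(vt)
        regions = merge_hotspots(wins, variants=vt)
        assert len(regions) == 2
        for (ws, we, _), reg in zip(sorted(res.truth.rate_windows),
                                    sorted(regions, key=lambda r: r.start)):
            assert reg.start <= ws + 200 and reg.end >= we - 200

    def test_scan_agrees_with_brute_force_on_simulated_data(self, demo):
        _, vt = demo
        ind = np.zeros(len(vt.consensus.sequence), dtype=int)
        ind[vt.snp_positions_on_consensus()] = 1
        wins = scan_windows(vt)
        oracle = brute_force_counts(ind, 1000)
        assert {w.start for w in wins} == {s for s, c in oracle.items() if c >= 11}

    def test_screen_markers_concordance(self, demo):
        res, vt = demo
        wins = scan_windows(vt)
        regions = merge_hotspots(wins, variants=vt)
        clades = {
            "Acnida": ["Acnida_1", "Acnida_2"],
            "Amaranthus": ["Amaranthus_1", "Amaranthus_2"],
        }
        df = screen_markers(res.msa, regions, clades, vt,
                            outgroup="outgroup_1", n_replicates=30, seed=3)
        assert len(df) == 2
        # hotspot windows carry strong clade signal at 30x rate boost
        assert (df.recovery_fraction > 0.5).all()

    def test_zero_variation_region_not_concordant(self, demo):
        res, vt = demo
        from plastcomp.hotspots import HotspotRegion
        # rRNA block in the IR is essentially invariant at demo rates
        quiet = HotspotRegion(start=20_500, end=21_000, snp_count=0, n_windows=1)
        clades = {"Acnida": ["Acnida_1", "Acnida_2"],
                  "Amaranthus": ["Amaranthus_1", "Amaranthus_2"]}
        df = screen_markers(res.msa, [quiet], clades, vt,
                            outgroup="outgroup_1", n_replicates=10, seed=4)
        if len(df):                       # not skipped for length
            assert not df.iloc[0].concordant

    def test_short_region_skipped_with_warning(self, demo):
        res, vt = demo
        from plastcomp.hotspots import HotspotRegion
        tiny = HotspotRegion(start=0, end=50, snp_count=0, n_windows=1)
        clades = {"Acnida": ["Acnida_1", "Acnida_2"],
                  "Amaranthus": ["Amaranthus_1", "Amaranthus_2"]}
        with pytest.warns(UserWarning, match="skipped"):
            df = screen_markers(res.msa, [tiny], clades, vt,
                                outgroup="outgroup_1", n_replicates=5, seed=5)
        assert len(df) == 0
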
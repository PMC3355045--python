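"""Tiling-signal analytics: binding values, peak calling, distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mslseq.chip import (
    PeakRegion,
    ProbeTrack,
    binned_colocalization,
    call_regions,
    coverage_fraction,
    gene_binding_value,
    genomic_stats,
    intersect_regions,
    read_bedgraph,
    tss_peak_distance,
    write_peaks_bed,
)
from mslseq.errors import InputError, ParameterError
from mslseq.features import GeneModel


class TestGeneBindingValue:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4], 3.5),  # top 2 of 4
            ([1, 2, 3], 2.5),  # ceil(3/2) = 2 values
            ([5], 5.0),
            ([2, 2, 2, 2], 2.0),
        ],
    )
    def test_examples(self, values, expected):
        assert gene_binding_value(values) == pytest.approx(expected)

    def test_empty_list_gives_missing_marker(self):
        assert np.isnan(gene_binding_value([]))

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=15),
        st.integers(0, 14),
        st.floats(0.01, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_every_probe(self, values, idx, bump):
        # raising any probe value never lowers the binding value
        if idx >= len(values):
            idx = idx % len(values)
        raised = list(values)
        raised[idx] += bump
        assert gene_binding_value(raised) >= gene_binding_value(values) - 1e-12


def _track(values, chrom="chr1", spacing=100):
    positions = np.arange(len(values)) * spacing + 50
    return ProbeTrack(chrom=chrom, positions=positions, values=np.asarray(values, float))


class TestCallRegions:
    def test_flat_peak_with_leftmost_tie_break(self):
        vals = [0.0] * 200 + [10.0] * 8 + [0.0] * 200
        track = _track(vals)
        regions = call_regions(track)
        assert len(regions) == 1
        r = regions[0]
        first = 200 * 100 + 50
        assert r.end - r.start == 700
        assert r.value == pytest.approx(10.0)
        # center = midpoint of the leftmost six qualifying probes
        assert r.center == pytest.approx((first + (first + 500)) / 2)
        assert r.n_probes == 8

    def test_four_probes_insufficient(self):
        vals = [0.0] * 200 + [10.0] * 4 + [0.0] * 200
        assert call_regions(_track(vals)) == []

    def test_short_span_insufficient(self):
        vals = [0.0] * 300
        vals[100] = vals[101] = vals[102] = 10.0  # span 200 < 360
        assert call_regions(_track(vals)) == []

    def test_gap_splits_regions(self):
        vals = [0.0] * 100 + [10.0] * 6 + [0.0] * 5 + [10.0] * 6 + [0.0] * 100
        # 5 low probes = 500 bp gap > 360: two chains
        regions = call_regions(_track(vals))
        assert len(regions) == 2

    def test_five_probe_region_uses_all_five(self):
        vals = [0.0] * 300 + [8.0, 9.0, 10.0, 9.0, 8.0] + [0.0] * 300
        (r,) = call_regions(_track(vals))
        assert r.n_probes == 5
        assert r.value == pytest.approx(np.mean([8, 9, 10, 9, 8]))

    def test_empty_track_rejected(self):
        with pytest.raises(InputError):
            call_regions([])

    def test_planted_peaks_recovered_and_noise_clean(self):
        # 20 planted peaks at SNR >= 5: at least 19 recovered with center
        # error <= 180 bp; pure-noise tracks yield zero calls over 10 seeds
        rng = np.random.default_rng(42)
        n_probes = 20_000
        noise_sd = 0.2
        centers = (np.arange(20) + 1) * 90_000 + 50
        vals = rng.normal(0, noise_sd, size=n_probes)
        positions = np.arange(n_probes) * 100 + 50
        for c in centers:
            sel = np.abs(positions - c) <= 300
            vals[sel] += 1.0  # SNR 5
        track = ProbeTrack("chr1", positions, vals)
        regions = call_regions(track)
        recovered = 0
        for c in centers:
            if any(abs(r.center - c) <= 180 for r in regions):
                recovered += 1
        assert recovered >= 19

        for seed in range(10):
            noise = np.random.default_rng(seed).normal(0, noise_sd, size=n_probes)
            assert call_regions(ProbeTrack("chr1", positions, noise)) == []

    def test_region_invariants_asserted(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.1, size=5000)
        positions = np.arange(5000) * 100 + 50
        vals[1000:1010] += 3.0
        vals[3000:3007] += 2.5
        regions = call_regions(ProbeTrack("chr1", positions, vals))
        assert regions == sorted(regions, key=lambda r: (r.chrom, r.start))
        for r in regions:
            assert r.end - r.start >= 360
            assert r.n_probes >= 5
            assert r.start <= r.center <= r.end
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start  # disjoint


class TestIntersectRegions:
    def _r(self, start, end, value=1.0, center=None):
        return PeakRegion("chr1", start, end, value,
                          (start + end) / 2 if center is None else center, 6)

    def test_identical_lists_idempotent(self):
        regions = [self._r(100, 600), self._r(1000, 1500)]
        out = intersect_regions(regions, regions)
        assert [(r.start, r.end) for r in out] == [(100, 600), (1000, 1500)]

    def test_disjoint_lists_empty(self):
        assert intersect_regions([self._r(0, 100)], [self._r(200, 300)]) == []

    def test_union_span_emitted(self):
        (r,) = intersect_regions([self._r(100, 600, 2.0)], [self._r(500, 900, 3.0)])
        assert (r.start, r.end) == (100, 900)
        assert r.value == 3.0
        assert r.center == pytest.approx((350 + 700) / 2)


class TestTssPeakDistance:
    def _genes(self):
        def g(gid, chrom, tss):
            return GeneModel(gid, chrom, "+", tss, [(tss, tss + 100)], [], [], [], [])

        return [g("a", "chr1", 1000), g("b", "chr1", 800), g("c", "chr2", 50)]

    def test_nearest_center(self):
        peaks = [PeakRegion("chr1", 700, 1200, 1.0, 800.0, 6),
                 PeakRegion("chr1", 1300, 1800, 1.0, 1500.0, 6)]
        d = tss_peak_distance(self._genes(), peaks)
        assert d["a"] == 200.0
        assert d["b"] == 0.0  # TSS exactly at a center
        assert np.isnan(d["c"])  # no peak on chr2


class TestBinnedColocalization:
    def test_probe_bin_assignment(self):
        track = ProbeTrack("chr1", np.array([850, 1050]), np.array([2.0, 4.0]))
        prof = binned_colocalization([track], [("chr1", 1000.0, True)],
                                     bin_bp=100, span=400)
        assert prof[-200] == pytest.approx(2.0)  # probe at signed -150
        assert prof[0] == pytest.approx(4.0)  # probe at signed +50
        assert np.isnan(prof[100])

    def test_mirroring_flips_sign(self):
        track = ProbeTrack("chr1", np.array([1050]), np.array([4.0]))
        prof = binned_colocalization([track], [("chr1", 1000.0, False)],
                                     bin_bp=100, span=400)
        assert prof[-100] == pytest.approx(4.0)  # +50 mirrored to -50

    def test_span_must_be_multiple_of_bin(self):
        track = ProbeTrack("chr1", np.array([100]), np.array([1.0]))
        with pytest.raises(ParameterError):
            binned_colocalization([track], [("chr1", 100.0, True)], 100, 450)

    def test_no_probes_near_anchor_rejected(self):
        track = ProbeTrack("chr1", np.array([10_000]), np.array([1.0]))
        with pytest.raises(InputError):
            binned_colocalization([track], [("chr1", 100.0, True)], 100, 400)

    def test_coplanted_peaks_maximum_at_center(self):
        # a second protein planted at the anchor centers peaks in the 0 bin
        rng = np.random.default_rng(0)
        positions = np.arange(5000) * 100 + 50
        vals = rng.normal(0, 0.1, size=5000)
        anchors = []
        for c in (50_050, 150_050, 250_050, 350_050):
            d = np.abs(positions - c)
            vals += 2.0 * np.exp(-(d / 200.0) ** 2)
            anchors.append(("chr1", float(c), True))
        track = ProbeTrack("chr1", positions, vals)
        prof = binned_colocalization([track], anchors, 100, 2000)
        assert prof.idxmax() == 0


class TestCoverageFraction:
    def test_simple_fraction(self):
        regions = [PeakRegion("chr1", 100, 300, 1.0, 200.0, 6)]
        cov = coverage_fraction(regions, {"chr1": 10_000, "chr2": 5000})
        assert cov["chr1"] == pytest.approx(0.02)
        assert cov["chr2"] == 0.0

    def test_region_beyond_chromosome_rejected(self):
        regions = [PeakRegion("chr1", 100, 30_000, 1.0, 200.0, 6)]
        with pytest.raises(InputError):
            coverage_fraction(regions, {"chr1": 10_000})

    def test_planted_coverage_recovered(self):
        # plant peaks covering ~1.9% of a 2-Mb chromosome, recover +/-0.3%
        rng = np.random.default_rng(3)
        n = 20_000
        positions = np.arange(n) * 100 + 50
        vals = rng.normal(0, 0.1, size=n)
        target = 0.019
        n_peaks = int(target * n * 100 / 700)  # each region spans ~700 bp
        for i in range(n_peaks):
            start = 400 + i * (n // n_peaks) * 100
            sel = (positions >= start) & (positions < start + 800)
            vals[sel] += 2.0
        regions = call_regions(ProbeTrack("chr1", positions, vals))
        cov = coverage_fraction(regions, {"chr1": n * 100})
        assert abs(cov["chr1"] - target) < 0.003


def test_bedgraph_round_trip(tmp_path, small_dataset):
    _, ds = small_dataset
    from mslseq.synth import write_dataset

    write_dataset(ds, tmp_path)
    tracks = read_bedgraph(tmp_path / "tracks" / "MOF.bedGraph")
    orig = {t.chrom: t for t in ds.probe_tracks["MOF"]}
    assert {t.chrom for t in tracks} == set(orig)
    for t in tracks:
        assert np.array_equal(t.positions, orig[t.chrom].positions)
        assert np.allclose(t.values, orig[t.chrom].values, atol=1e-5)


def test_peaks_bed_export(tmp_path):
    regions = [PeakRegion("chr1", 100, 600, 1.234, 350.0, 6)]
    path = tmp_path / "peaks.bed"
    write_peaks_bed(regions, path)
    chrom, start, end, name, score, strand = path.read_text().strip().split("\t")
    assert (chrom, start, end, score) == ("chr1", "100", "600", "123")
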
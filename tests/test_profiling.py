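"""Positional statistics: densities, metagenes, forming probability, trend."""

import numpy as np
import pytest

from rg4scope.profiling import (
    TranscriptAnnotation,
    annotate_region,
    distance_to_ends,
    forming_probability,
    mann_kendall,
    metagene_profile,
    region_counts_density,
    relative_density_5p,
)
from rg4scope.scan import G4Motif


def _motif(tid="t", start=20, end=35, region="NA"):
    return G4Motif(
        tid, start, end, "G" * (end - start), (3, 3, 3, 3),
        _loops_for(end - start), region=region,
    )


def _loops_for(length):
    # any loop triple consistent with 4x3 tracts and the given length
    rest = length - 12
    a = min(rest - 2, 7)
    rest -= a
    b = min(rest - 1, 7)
    return (a, b, rest - b)


class TestAnnotateRegion:
    ann = TranscriptAnnotation("t", 50, 200, 300)

    def test_by_start_position(self):
        assert annotate_region(_motif(start=10, end=25), self.ann) == ("UTR5", False)
        assert annotate_region(_motif(start=60, end=75), self.ann) == ("CDS", False)
        assert annotate_region(_motif(start=250, end=265), self.ann) == ("UTR3", False)

    def test_boundary_spanning_flagged(self):
        label, spans = annotate_region(_motif(start=45, end=66), self.ann)
        assert label == "UTR5" and spans

    def test_start_past_transcript_fails(self):
        with pytest.raises(ValueError, match="outside transcript"):
            annotate_region(_motif(start=290, end=305), self.ann)

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            TranscriptAnnotation("t", 100, 50, 300)

    def test_planted_regions_recovered(self, small_dataset):
        _, _, annotations, truth, _, _ = small_dataset
        for m in truth.motifs:
            ann = annotations[m.transcript_id]
            label, spans = annotate_region(
                _motif(m.transcript_id, m.start, m.end), ann
            )
            if not spans:
                assert label == m.region


class TestRegionCountsDensity:
    def test_proportions_and_density(self):
        anns = {"t": TranscriptAnnotation("t", 1000, 2000, 3000)}
        motifs = [
            _motif(start=10, end=25),
            _motif(start=100, end=115),
            _motif(start=2500, end=2515),
        ]
        out = region_counts_density(motifs, anns)
        assert out["UTR5"]["count"] == 2
        assert out["UTR5"]["proportion"] == pytest.approx(2 / 3)
        assert out["UTR5"]["density_per_kb"] == pytest.approx(2.0)
        assert out["UTR3"]["density_per_kb"] == pytest.approx(1.0)
        assert sum(r["proportion"] for r in out.values()) == pytest.approx(1.0)

    def test_empty_motifs_give_zeros(self):
        anns = {"t": TranscriptAnnotation("t", 100, 200, 300)}
        out = region_counts_density([], anns)
        assert all(r["count"] == 0 for r in out.values())


class TestRelativeDensity5p:
    def test_single_transcript_single_motif(self):
        anns = {"t": TranscriptAnnotation("t", 300, 300, 300)}
        prof = relative_density_5p([_motif(start=20, end=35)], anns, window=300)
        # 1-based positions 21..35 are covered -> density 1000, else 0
        assert np.allclose(prof.d[20:35], 1000.0)
        assert np.allclose(np.delete(prof.d, np.s_[20:35]), 0.0)
        assert np.all(prof.T == 1)

    def test_eq1_arithmetic(self):
        # G_i = 2, T_i = 1000 -> d_i = 2.0 per kb
        assert 2 / 1000 * 1e3 == pytest.approx(2.0)
        anns = {
            f"t{k}": TranscriptAnnotation(f"t{k}", 300, 300, 300)
            for k in range(10)
        }
        motifs = [_motif(tid="t0", start=0, end=15), _motif(tid="t1", start=0, end=15)]
        prof = relative_density_5p(motifs, anns, window=20)
        assert prof.G[5] == 2 and prof.T[5] == 10
        assert prof.d[5] == pytest.approx(2 / 10 * 1e3)

    def test_eq2_background_arithmetic(self):
        # l = 500 motif nt over L = 100,000 region nt -> 5.0 per kb
        anns = {
            f"t{k}": TranscriptAnnotation(f"t{k}", 1000, 1000, 1000)
            for k in range(100)
        }
        motifs = [
            _motif(tid=f"t{k}", start=100, end=125) for k in range(20)
        ]  # 20 * 25 nt = 500 nt
        prof = relative_density_5p(motifs, anns, window=10)
        assert prof.background == pytest.approx(500 / 100_000 * 1e3)

    def test_t_non_increasing_when_5p_aligned(self, small_dataset):
        _, _, annotations, _, _, _ = small_dataset
        prof = relative_density_5p([], annotations, window=500)
        assert np.all(np.diff(prof.T) <= 0)

    def test_eq1_eq2_mean_consistency(self):
        # transcripts all exactly window long and pure 5'-UTR: the mean of
        # d_i over the window equals the region-wide background
        rng = np.random.default_rng(4)
        anns = {}
        motifs = []
        W = 120
        for k in range(30):
            tid = f"t{k}"
            anns[tid] = TranscriptAnnotation(tid, W, W, W)
            if k % 2 == 0:
                s = int(rng.integers(0, W - 20))
                motifs.append(_motif(tid=tid, start=s, end=s + 18))
        prof = relative_density_5p(motifs, anns, window=W)
        assert np.nanmean(prof.d) == pytest.approx(prof.background)

    def test_start_codon_alignment_counts_upstream(self):
        anns = {"t": TranscriptAnnotation("t", 100, 200, 300)}
        # motif at [80, 95): 5 to 20 nt upstream of the start codon
        prof = relative_density_5p(
            [_motif(start=80, end=95)],
            anns,
            window=50,
            alignment="start_codon",
        )
        covered = np.where(prof.G > 0)[0] + 1
        assert covered.min() == 6 and covered.max() == 20
        assert np.all(prof.T == 1)  # the 100-nt 5'-UTR reaches every offset


class TestDistanceToEnds:
    anns = {"t": TranscriptAnnotation("t", 100, 200, 300)}

    def test_distances(self):
        [(m, d5, d3)] = distance_to_ends(
            [_motif(start=20, end=35)], self.anns, region="UTR5"
        )
        assert (d5, d3) == (20, 65)

    def test_flush_motif_distance_zero(self):
        [(m, d5, d3)] = distance_to_ends(
            [_motif(start=0, end=15)], self.anns, region="UTR5"
        )
        assert d5 == 0

    def test_conservation_identity(self, small_dataset):
        _, sequences, annotations, truth, _, _ = small_dataset
        motifs = [
            _motif(m.transcript_id, m.start, m.end)
            for m in truth.motifs
            if m.region == "UTR3"
        ]
        for m, d5, d3 in distance_to_ends(motifs, annotations, region="UTR3"):
            a, b = annotations[m.transcript_id].region_interval("UTR3")
            assert d5 + d3 + m.length == b - a

    def test_motif_outside_region_skipped(self):
        assert distance_to_ends([_motif(start=150, end=165)], self.anns, "UTR5") == []


class TestMetageneProfile:
    def test_full_coverage_around_anchors(self):
        lengths = {"t": 1000}
        anchors = [("t", 500)]
        features = {"t": [(490, 511)]}  # anchor +/- 10 covered
        prof = metagene_profile(anchors, features, lengths, flank=20)
        for o, dens in zip(prof.offsets, prof.density):
            assert dens == pytest.approx(1.0 if abs(o) <= 10 else 0.0)

    def test_zero_anchors_fails(self):
        with pytest.raises(ValueError, match="no anchor"):
            metagene_profile([], {}, {}, flank=10)

    def test_independent_features_give_flat_profile(self):
        rng = np.random.default_rng(9)
        lengths = {f"t{k}": 2000 for k in range(60)}
        anchors = [(f"t{k}", int(rng.integers(500, 1500))) for k in range(60)]
        features = {
            f"t{k}": [(int(s), int(s) + 20)]
            for k in range(60)
            for s in [rng.integers(0, 1980)]
        }
        prof = metagene_profile(anchors, features, lengths, flank=100)
        # expected coverage ~ 20/2000 = 0.01; binomial null over 60 anchors
        p0 = 20 / 2000
        sd = np.sqrt(p0 * (1 - p0) / 60)
        assert np.all(np.abs(prof.density - p0) < 5 * sd)

    def test_control_profile_reproducible_and_matched(self):
        lengths = {"t": 1000}
        anchors = [("t", 300), ("t", 700)]
        features = {"t": [(100, 130)]}
        kwargs = dict(
            flank=50, control_regions={"t": (200, 900)}, seed=123
        )
        p1 = metagene_profile(anchors, features, lengths, **kwargs)
        p2 = metagene_profile(anchors, features, lengths, **kwargs)
        assert np.allclose(p1.control_density, p2.control_density, equal_nan=True)
        assert p1.n_anchors == 2

    def test_binned_aggregation(self):
        lengths = {"t": 400}
        prof = metagene_profile(
            [("t", 200)], {"t": [(180, 221)]}, lengths, flank=40
        )
        edges, means = prof.binned(20)
        assert len(edges) == len(prof.offsets) // 20
        assert means.max() == pytest.approx(1.0)


class TestFormingProbability:
    lengths = {"t": 1000}
    anchors = [("t", 100)]

    def _put(self):
        return [_motif(start=150, end=170), _motif(start=250, end=270)]

    def test_identity_when_all_observed(self):
        put = self._put()
        fp = forming_probability(put, put, self.anchors, self.lengths)
        defined = fp.p[~np.isnan(fp.p)]
        assert np.allclose(defined, 1.0)

    def test_zero_when_none_observed(self):
        put = self._put()
        fp = forming_probability([], put, self.anchors, self.lengths)
        defined = fp.p[~np.isnan(fp.p)]
        assert np.allclose(defined, 0.0)

    def test_eq3_ratio(self):
        # bin 1 spans positions 121..140 downstream of the anchor at 100;
        # putative coverage there is 15 + 5 nt, observed coverage 5 nt
        m1 = _motif(start=121, end=136)
        m2 = _motif(start=136, end=156)
        fp = forming_probability([m2], [m1, m2], self.anchors, self.lengths)
        assert fp.p[1] == pytest.approx(5 / 20)

    def test_subset_violation_fails(self):
        with pytest.raises(ValueError, match="subset"):
            forming_probability(
                [_motif(start=500, end=520)], self._put(), self.anchors, self.lengths
            )


class TestMannKendall:
    def test_strictly_increasing_series(self):
        mk = mann_kendall(np.arange(10))
        assert mk.S == 45
        assert mk.p < 1e-4

    def test_printed_value_for_s41(self):
        mk = mann_kendall([0, 1, 2, 3, 4, 5, 6, 9, 7, 8])
        assert mk.S == 41.0
        assert float(f"{mk.p:.4g}") == 0.0003466

    def test_reversal_negates_s_preserves_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        fwd, rev = mann_kendall(x), mann_kendall(x[::-1])
        assert fwd.S == -rev.S
        assert fwd.p == pytest.approx(rev.p)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 2, size=15)
        a = mann_kendall(x)
        b = mann_kendall(np.exp(x))
        c = mann_kendall(np.log(x))
        assert a.S == b.S == c.S
        assert a.p == pytest.approx(b.p) == pytest.approx(c.p)

    def test_constant_series(self):
        mk = mann_kendall([2.0] * 8)
        assert mk.S == 0 and mk.p == 1.0

    def test_tie_correction_reduces_variance(self):
        tied = mann_kendall([1, 2, 2, 3, 4, 5, 6, 7])
        free = mann_kendall([1, 2, 2.5, 3, 4, 5, 6, 7])
        assert tied.varS < free.varS

    def test_short_series_fails(self):
        with pytest.raises(ValueError, match="at least 4"):
            mann_kendall([1, 2, 3])
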
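"""Event classification, motif tracks, window Fisher tests, CLIP proximity."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import gradpath as gp
from gradpath.motifmap import RegionSequenceSet


def exact_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by exact rational enumeration over the margins."""
    N = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x):
        return Fraction(comb(col1, x) * comb(N - col1, row1 - x),
                        comb(N, row1))

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, row1 - (N - col1)), min(row1, col1) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(total)


def region_set(seqs, region="downstream_intron"):
    return RegionSequenceSet({region: {f"e{i}": s for i, s in enumerate(seqs)}})


class TestClassifyEvents:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["event", "junction", "dpsi_percent", "role"])

    def test_bidirectional_junctions_regulated_by_inclusion_sign(self):
        t = self.make_table([
            ("ev1", "j1", 15.0, "inclusion"), ("ev1", "j2", -15.0, "exclusion"),
            ("ev2", "j1", -12.0, "inclusion"), ("ev2", "j2", 12.0, "exclusion"),
        ])
        es = gp.classify_events(t)
        assert es.regulated_included == {"ev1"}
        assert es.regulated_excluded == {"ev2"}

    def test_quiet_junctions_non_regulated(self):
        t = self.make_table([("ev1", "j1", 2.0, "inclusion"),
                             ("ev1", "j2", -2.0, "exclusion")])
        es = gp.classify_events(t)
        assert es.non_regulated == {"ev1"}

    def test_intermediate_events_unassigned(self):
        t = self.make_table([("ev1", "j1", 7.0, "inclusion"),
                             ("ev1", "j2", -7.0, "exclusion")])
        es = gp.classify_events(t)
        assert "ev1" not in es.regulated | es.non_regulated

    def test_malformed_role_rejected(self):
        t = self.make_table([("ev1", "j1", 7.0, "inclusive")])
        with pytest.raises(ValueError, match="role"):
            gp.classify_events(t)

    def test_sets_are_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            gp.EventSets({"a"}, {"a"}, set())


class TestMotifFrequency:
    def test_single_sequence_single_hit(self):
        tracks = gp.motif_frequency(region_set(["AAUG"]), motifs=["AAU"])
        freq = tracks["downstream_intron"].frequency
        assert freq[0] == 1.0
        assert np.nansum(freq) == 1.0

    def test_overlapping_motif_starts_enumerated(self):
        tracks = gp.motif_frequency(region_set(["UAAUU"]),
                                    motifs=["AAU", "UAA", "AUU"])
        freq = tracks["downstream_intron"].frequency
        assert list(freq[:3]) == [1.0, 1.0, 1.0]

    def test_partial_presence_gives_fractional_frequency(self):
        seqs = ["CCCCAAUCCC", "CCCCCCCCCC"]
        tracks = gp.motif_frequency(region_set(seqs), motifs=["AAU"])
        assert tracks["downstream_intron"].frequency[4] == 0.5

    def test_dna_input_mapped_to_rna(self):
        tracks = gp.motif_frequency(region_set(["AATG"]), motifs=["AAU"])
        assert tracks["downstream_intron"].frequency[0] == 1.0

    def test_union_over_motifs_dominates_single_motif(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGU"), 60)) for _ in range(30)]
        rs = region_set(seqs)
        union = gp.motif_frequency(rs, motifs=["AAU", "UAA", "AUU"])
        single = gp.motif_frequency(rs, motifs=["AAU"])
        u = union["downstream_intron"].frequency
        s = single["downstream_intron"].frequency
        assert np.all(u[~np.isnan(u)] >= s[~np.isnan(s)] - 1e-12)

    def test_upstream_region_right_aligned(self):
        # shorter sequence anchors at the right (3' splice site)
        rs = RegionSequenceSet({"upstream_intron": {"a": "CCAAU", "b": "AAU"}})
        tracks = gp.motif_frequency(rs, motifs=["AAU"])
        freq = tracks["upstream_intron"].frequency
        # both sequences end with AAU at the anchor: start offset -3
        assert freq[2] == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            gp.motif_frequency(RegionSequenceSet({"exon": {}}))


class TestSmooth:
    def test_constant_track_unchanged(self):
        x = np.full(50, 0.3)
        assert np.allclose(gp.smooth(x, 20), 0.3)

    def test_interior_impulse_spreads_uniformly(self):
        x = np.zeros(100)
        x[50] = 1.0
        sm = gp.smooth(x, 20)
        covered = sm[sm > 0]
        assert len(covered) == 20
        assert np.allclose(covered, 1 / 20)

    def test_matches_naive_windowed_mean(self):
        rng = np.random.default_rng(1)
        x = rng.random(73)
        sm = gp.smooth(x, 20)
        for i in [0, 5, 36, 72]:
            lo, hi = max(0, i - 9), min(73, i + 11)
            assert sm[i] == pytest.approx(x[lo:hi].mean())

    def test_wide_window_collapses_to_global_mean(self):
        x = np.arange(10.0)
        assert np.allclose(gp.smooth(x, 25), x.mean())


class TestWindowFisher:
    def test_identical_sets_all_null(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGU"), 60)) for _ in range(20)]
        rs = region_set(seqs)
        out = gp.window_fisher(rs, region_set(seqs), window=20)
        assert np.allclose(out["downstream_intron"]["p"], 1.0)

    def test_extreme_table_matches_combinatorial_value(self):
        # 10/10 vs 0/10 presence: p = 2/C(20,10)
        withm = ["AAU" + "C" * 27 for _ in range(10)]
        without = ["C" * 30 for _ in range(10)]
        out = gp.window_fisher(region_set(withm), region_set(without),
                               motifs=["AAU"], window=20)
        p = out["downstream_intron"]["p"].iloc[0]
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    @pytest.mark.parametrize("trial", range(40))
    def test_scipy_fisher_matches_rational_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
        if (a + b) == 0 or (c + d) == 0:
            a, b = a + 1, b + 1
        from scipy.stats import fisher_exact

        p = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert p == pytest.approx(exact_fisher_two_sided(a, b, c, d), abs=1e-12)

    def test_swapping_sets_preserves_p_values(self):
        rng = np.random.default_rng(3)
        A = region_set(["".join(rng.choice(list("ACGU"), 50)) for _ in range(15)])
        B = region_set(["".join(rng.choice(list("ACGU"), 50)) for _ in range(15)])
        pa = gp.window_fisher(A, B)["downstream_intron"]["p"]
        pb = gp.window_fisher(B, A)["downstream_intron"]["p"]
        assert np.allclose(pa, pb)

    def test_planted_enrichment_localizes_to_window(self):
        data = gp.synth_sequences(n_events_per_set=200, planted_rate=0.5,
                                  planted_window=(180, 220), seed=4)
        out = gp.window_fisher(data.enriched, data.background, window=20)
        sig = out["downstream_intron"].query("significant")
        lo, hi = 180, 220
        in_span = sig[(sig["center"] >= lo - 10) & (sig["center"] <= hi + 12)]
        assert len(in_span) >= 5

    def test_null_rate_of_significant_windows_bounded(self):
        data = gp.synth_sequences(n_events_per_set=200, planted_rate=0.0, seed=5)
        out = gp.window_fisher(data.enriched, data.background, window=20)
        assert out["downstream_intron"]["significant"].mean() <= 0.10


class TestClipProximity:
    def make_inputs(self):
        events = pd.DataFrame(
            {
                "event": ["e1", "e2"],
                "chrom": ["chr1", "chr1"],
                "exon_start": [1000, 5000],
                "exon_end": [1100, 5150],
            }
        )
        return events

    def test_single_tag_sites_filtered(self):
        events = self.make_inputs()
        tags = pd.DataFrame({"chrom": ["chr1"], "start": [1050], "end": [1051],
                             "tag_count": [1]})
        frac, _ = gp.clip_proximity(tags, events, {"s": {"e1", "e2"}})
        assert frac.loc["s", "frac_any"] == 0.0

    def test_site_at_exon_start_counts_as_exon_bound(self):
        events = self.make_inputs()
        tags = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1001],
                             "tag_count": [3]})
        frac, _ = gp.clip_proximity(tags, events, {"s": {"e1"}})
        assert frac.loc["s", "frac_exon"] == 1.0
        assert frac.loc["s", "frac_upstream"] == 0.0

    def test_upstream_and_downstream_windows_respected(self):
        events = self.make_inputs()
        tags = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [700, 1150, 5500],
                "end": [701, 1151, 5501],
                "tag_count": [2, 2, 2],
            }
        )
        frac, _ = gp.clip_proximity(tags, events, {"s": {"e1", "e2"}})
        # 700 is exactly 300 nt before exon start 1000: inside [700, 1000)
        assert frac.loc["s", "frac_upstream"] == 0.5
        assert frac.loc["s", "frac_downstream"] == 0.5

    def test_pairwise_fisher_matches_oracle(self):
        rng = np.random.default_rng(6)
        n = 100
        events = pd.DataFrame(
            {
                "event": [f"e{i}" for i in range(2 * n)],
                "chrom": "chr1",
                "exon_start": np.arange(2 * n) * 10_000 + 1000,
                "exon_end": np.arange(2 * n) * 10_000 + 1100,
            }
        )
        bound_a = rng.choice(n, 30, replace=False)
        bound_b = n + rng.choice(n, 10, replace=False)
        starts = [int(events.loc[i, "exon_start"]) + 50
                  for i in np.concatenate([bound_a, bound_b])]
        tags = pd.DataFrame({"chrom": "chr1", "start": starts,
                             "end": [s + 1 for s in starts], "tag_count": 2})
        sets = {"A": set(events["event"][:n]), "B": set(events["event"][n:])}
        frac, P = gp.clip_proximity(tags, events, sets)
        assert frac.loc["A", "frac_any"] == pytest.approx(0.30)
        assert P.loc["A", "B"] == pytest.approx(
            exact_fisher_two_sided(30, 70, 10, 90), abs=1e-12
        )

    def test_negative_width_interval_rejected(self):
        events = pd.DataFrame({"event": ["e1"], "chrom": ["c"],
                               "exon_start": [100], "exon_end": [50]})
        tags = pd.DataFrame({"chrom": ["c"], "start": [1], "end": [2],
                             "tag_count": [2]})
        with pytest.raises(ValueError, match="coordinate"):
            gp.clip_proximity(tags, events, {"s": {"e1"}})


class TestFastaIO:
    def test_round_trip_preserves_regions_and_rna(self, tmp_path):
        rs = RegionSequenceSet(
            {
                "exon": {"e1": "ACGUACGU", "e2": "GGGCCC"},
                "downstream_intron": {"e1": "AATTAA"},
            }
        )
        f = tmp_path / "regions.fa"
        rs.to_fasta(f)
        back = RegionSequenceSet.from_fasta(f)
        assert back.sequences["exon"] == rs.sequences["exon"]
        assert back.sequences["downstream_intron"]["e1"] == "AAUUAA"
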
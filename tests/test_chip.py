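"""Binding calls, clusters, coincidence, subtelomere and context labels."""

import numpy as np
import pandas as pd
import pytest

from nucorg import chip
from nucorg.io import read_gff3
from nucorg.simulate import TilingSimConfig, simulate_tiling


class TestCallLocus:
    def test_strong_uniform_signal_is_positive(self):
        med, p_up, p_down, status = chip.call_locus([1.0] * 11)
        assert status == "positive"
        assert p_up == pytest.approx(1 / 2048)
        assert med == pytest.approx(1.0)

    def test_all_zero_makes_no_call(self):
        med, p_up, p_down, status = chip.call_locus([0.0] * 11)
        assert status == "not_significant"
        assert (p_up, p_down) == (1.0, 1.0)

    def test_strong_depletion_is_negative(self):
        *_, status = chip.call_locus([-1.0] * 11)
        assert status == "negative"

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            chip.call_locus([1.0] * 4)

    def test_status_consistent_with_thresholds(self, rng):
        alpha = 0.025
        for _ in range(50):
            v = rng.normal(rng.uniform(-1, 1), 0.8, 11)
            _, p_up, p_down, status = chip.call_locus(v, alpha=alpha)
            if status == "positive":
                assert p_up < alpha
            elif status == "negative":
                assert p_down < alpha
            else:
                assert p_up >= alpha and p_down >= alpha


class TestCallTrack:
    def test_recovers_planted_positives(self):
        cfg = TilingSimConfig(
            chrom_sizes=(("c1", 1000 * 300),), bound_fraction_A=0.2,
            effect_log2=1.5, noise_sd=0.5, seed=5,
        )
        sim = simulate_tiling(cfg)
        track = chip.call_track(sim.probes["A"])
        called = track.positive_ids()
        sens = len(called & sim.truth["A"]) / len(sim.truth["A"])
        assert sens > 0.95

    def test_empty_table_gives_empty_track(self):
        empty = pd.DataFrame(columns=chip.PROBE_COLUMNS)
        assert len(chip.call_track(empty)) == 0

    def test_conflicting_duplicate_locus_ids_rejected(self):
        df = pd.DataFrame(
            {
                "chrom": ["c1"] * 12,
                "locus_start": [0] * 6 + [300] * 6,
                "locus_end": [300] * 6 + [600] * 6,
                "locus_id": ["L1"] * 12,  # same id, two intervals
                "probe_index": list(range(6)) * 2,
                "log2_ratio": 0.1,
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            chip.call_track(df)

    def test_resolution_metadata_passthrough(self):
        rows = []
        for start, size in [(0, 300), (300, 100)]:
            for j in range(11):
                rows.append(("c1", start, start + size, f"c1:{start}", j, 1.0))
        df = pd.DataFrame(rows, columns=chip.PROBE_COLUMNS)
        track = chip.call_track(df)
        assert sorted(track.calls["resolution"]) == [100, 300]


class TestClusters:
    def test_minimum_run_of_two(self, track_factory):
        statuses = ["not_significant"] * 15
        for i in (5, 6, 7, 12):
            statuses[i] = "positive"
        clusters = chip.find_clusters(track_factory(statuses))
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end, c.n_loci) == (5 * 300, 8 * 300, 3)

    def test_no_positives_no_clusters(self, track_factory):
        assert chip.find_clusters(track_factory(["not_significant"] * 5)) == []

    def test_runs_do_not_span_gaps_in_the_grid(self, track_factory):
        track = track_factory(["positive"] * 4)
        # remove the middle locus: two runs of two, separated by a gap
        track.calls = track.calls.drop(index=2).reset_index(drop=True)
        clusters = chip.find_clusters(chip.BindingTrack(calls=track.calls))
        assert [c.n_loci for c in clusters] == [2]  # run of 2 then isolated locus

    def test_top_peaks_rank_then_filter(self, track_factory):
        statuses = ["positive", "positive", "not_significant", "positive", "positive"]
        log2 = [0.9, 0.7, 0.0, 1.2, 0.6]
        track = track_factory(statuses, log2=log2)
        peaks = chip.top_peaks(track, k=1, min_log2=0.8)
        assert len(peaks) == 1
        assert peaks[0].peak_log2 == pytest.approx(1.2)
        # low filter keeps both, ranked by peak descending
        both = chip.top_peaks(track, k=10, min_log2=0.5)
        assert [p.peak_log2 for p in both] == [1.2, 0.9]


class TestCoincidence:
    def test_self_coincidence_is_complete(self, track_factory):
        t = track_factory(["positive", "not_significant", "positive", "negative"])
        table = chip.coincidence(t, t)
        total = table[table["chrom"] == "total"].iloc[0]
        assert total["coincident_pct"] == 100

    def test_disjoint_positives(self, track_factory):
        a = track_factory(["positive", "not_significant"] * 3)
        b = track_factory(["not_significant", "positive"] * 3)
        table = chip.coincidence(a, b)
        assert table.iloc[-1]["coincident_pct"] == 0

    def test_percentages_recompute_and_pool(self, rng, track_factory):
        frames = []
        for chrom in ("chr1", "chr2"):
            statuses = rng.choice(
                ["positive", "not_significant", "negative"], 50, p=[0.3, 0.5, 0.2]
            )
            frames.append(track_factory(list(statuses), chrom=chrom).calls)
        a = chip.BindingTrack(calls=pd.concat(frames, ignore_index=True))
        statuses_b = rng.choice(["positive", "not_significant"], 100, p=[0.4, 0.6])
        b = chip.BindingTrack(
            calls=pd.concat(
                [
                    track_factory(list(statuses_b[:50]), chrom="chr1").calls,
                    track_factory(list(statuses_b[50:]), chrom="chr2").calls,
                ],
                ignore_index=True,
            )
        )
        table = chip.coincidence(a, b)
        per_chrom = table[table["chrom"] != "total"]
        total = table[table["chrom"] == "total"].iloc[0]
        for col in ("detectable_loci", "a_positive", "coincident"):
            assert total[col] == per_chrom[col].sum()
        for _, row in table.iterrows():
            if row["a_positive"]:
                expect = chip.round_half_up(100 * row["coincident"] / row["a_positive"])
                assert row["coincident_pct"] == expect

    def test_grid_mismatch_rejected(self, track_factory):
        a = track_factory(["positive"] * 4)
        b = track_factory(["positive"] * 5)
        with pytest.raises(ValueError, match="grid"):
            chip.coincidence(a, b)

    def test_fine_loci_map_to_containing_coarse_locus(self, track_factory):
        coarse = track_factory(["positive", "not_significant"])
        fine_statuses = ["not_significant"] * 6
        fine_statuses[4] = "positive"  # locus [400,500) -> coarse bin [300,600)
        fine = track_factory(fine_statuses, locus_size=100)
        table = chip.coincidence(coarse, fine)
        mapped = chip.map_to_resolution(fine, 300)
        assert set(mapped.calls["start"]) == {0, 300}
        assert mapped.calls.set_index("start").loc[300, "status"] == "positive"
        # coarse locus [0,300) is A-positive but fine support there is negative
        assert table.iloc[-1]["coincident"] == 0


class TestCorrelation:
    def test_identical_tracks_correlate_perfectly(self, rng, track_factory):
        log2 = rng.normal(1.0, 0.3, 20)
        t = track_factory(["positive"] * 20, log2=list(log2))
        _, rho, _ = chip.correlate_tracks(t, t)
        assert rho == pytest.approx(1.0)

    def test_independent_tracks_near_zero(self, rng, track_factory):
        n = 400
        a = track_factory(["positive"] * n, log2=list(rng.normal(1, 0.5, n)))
        b = track_factory(["not_significant"] * n, log2=list(rng.normal(0, 0.5, n)))
        _, rho, _ = chip.correlate_tracks(a, b)
        assert abs(rho) < 3 / np.sqrt(n)

    def test_planted_overlap_gives_positive_correlation(self):
        # with a constant planted effect the association on the
        # A-positive subset is weak by construction (within-positive
        # signal variation is pure noise), so this is a direction check
        # at the full grid size, not a magnitude check
        cfg = TilingSimConfig(chrom_sizes=(("c1", 8000 * 300),), seed=7)
        sim = simulate_tiling(cfg)
        ta = chip.call_track(sim.probes["A"])
        tb = chip.call_track(sim.probes["B"])
        _, rho, p = chip.correlate_tracks(ta, tb, subset="a_positive")
        assert rho > 0
        assert p < 0.05

    def test_empty_subset_rejected(self, track_factory):
        t = track_factory(["not_significant"] * 3)
        with pytest.raises(ValueError):
            chip.correlate_tracks(t, t, subset="a_positive")


class TestSubtelomere:
    sizes = pd.DataFrame({"chrom": ["chr1"], "length": [200_000]})

    def test_terminal_locus_counted(self, track_factory):
        statuses = ["not_significant"] * 667  # 200 kb of 300-bp loci
        statuses[0] = "positive"
        table = chip.subtelomere_presence(track_factory(statuses), self.sizes)
        left = table[(table["arm"] == "L")].iloc[0]
        assert left["n_positive"] == 1
        assert table[table["arm"] == "R"].iloc[0]["n_positive"] == 0

    def test_central_locus_not_counted(self, track_factory):
        statuses = ["not_significant"] * 667
        statuses[333] = "positive"  # ~100 kb, centre
        table = chip.subtelomere_presence(track_factory(statuses), self.sizes)
        assert table["n_positive"].sum() == 0

    def test_planted_subtelomeric_positives_recovered(self):
        cfg = TilingSimConfig(chrom_sizes=(("c1", 500 * 300),), bound_fraction_A=0.1,
                              seed=9)
        sim = simulate_tiling(cfg)
        track = chip.call_track(sim.probes["A"])
        sizes = pd.DataFrame({"chrom": ["c1"], "length": [500 * 300]})
        table = chip.subtelomere_presence(track, sizes, zone_bp=10_000)
        # every planted positive in the terminal 10 kb must be reported
        truth_sub = [
            lid for lid in sim.truth["A"]
            if int(lid.split(":")[1].split("-")[0]) < 10_000
            or int(lid.split("-")[1]) > 500 * 300 - 10_000
        ]
        called_sub = table["n_positive"].sum()
        called = track.positive_ids()
        assert called_sub >= len([x for x in truth_sub if x in called])

    def test_unknown_chromosome_rejected(self, track_factory):
        with pytest.raises(ValueError, match="absent"):
            chip.subtelomere_presence(
                track_factory(["positive"] * 2, chrom="chrX"), self.sizes
            )


class TestContext:
    def make_track_at(self, spans, chrom="chr1"):
        calls = pd.DataFrame(
            {
                "locus_id": [f"{chrom}:{s}-{e}" for s, e in spans],
                "chrom": chrom,
                "start": [s for s, _ in spans],
                "end": [e for _, e in spans],
                "resolution": [e - s for s, e in spans],
                "log2_ratio": 1.0,
                "p_up": 0.001,
                "p_down": 0.9,
                "status": "positive",
            }
        )
        return chip.BindingTrack(calls=calls)

    def test_labels(self, gff_file):
        genes = read_gff3(gff_file)
        # geneL: [2000,3000) on '-' (start codon at 3000);
        # geneR: [3300,4300) on '+' (start at 3300): divergent pair, gap 300 bp
        track = self.make_track_at(
            [(3000, 3300), (7700, 8000), (8400, 8700), (15000, 15300)]
        )
        labels = chip.classify_context(track, genes)
        assert labels["chr1:3000-3300"] == "divergent_promoter"
        assert labels["chr1:7700-8000"] == "single_promoter"  # geneS flank
        assert labels["chr1:8400-8700"] == "ORF_internal"  # inside geneS
        assert labels["chr1:15000-15300"] == "intergenic_other"  # >1 kb from genes

    def test_wide_gap_centre_is_not_a_promoter(self, gff_file):
        # chr2: '-' gene ending at 2000 and '+' gene starting at 6000; the
        # centre of the 4-kb gap is beyond promoter distance of both starts
        genes = read_gff3(gff_file)
        track = self.make_track_at([(3800, 4100)], chrom="chr2")
        labels = chip.classify_context(track, genes)
        assert labels["chr2:3800-4100"] == "intergenic_other"

    def test_strandless_genes_rejected(self, track_factory):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "start": [0], "end": [300],
             "strand": ["."]}
        )
        with pytest.raises(ValueError, match="strand"):
            chip.classify_context(track_factory(["positive"]), genes)
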
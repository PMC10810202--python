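"""NSC normalization, copy-state calling, tract segmentation, aneuploidy."""

import numpy as np
import pandas as pd
import pytest

from cenrec import (
    CopyNumberCaller,
    GenomeModel,
    GenomeMetadata,
    PlantedEvent,
    call_aneuploidy,
    call_copy_states,
    compute_nsc,
    conversion_tract_stats,
    gen_coverage,
    segment_tracts,
)
from cenrec.coverage import LohTract, TractSegment


def balanced_table(n=200, depth=50):
    return pd.DataFrame({
        "chrom": "chrIII",
        "pos": np.arange(1, n + 1) * 400,
        "cov_w": depth // 2,
        "cov_y": depth // 2,
    })


class TestNsc:
    def test_balanced_single_copy_sites_are_half(self):
        nsc = compute_nsc(balanced_table())
        assert np.allclose(nsc["nsc_w"], 0.5)
        assert np.allclose(nsc["nsc_y"], 0.5)

    def test_zero_coverage_site_has_zero_nsc(self):
        tbl = balanced_table()
        tbl.loc[5, "cov_w"] = 0
        nsc = compute_nsc(tbl)
        assert nsc.loc[5, "nsc_w"] == 0.0

    def test_matches_direct_formula_on_simulated_table(self):
        tbl, _ = gen_coverage(seed=1)
        nsc = compute_nsc(tbl)
        denom = (tbl["cov_w"] + tbl["cov_y"]).mean()
        np.testing.assert_allclose(nsc["nsc_w"], tbl["cov_w"] / denom)
        np.testing.assert_allclose(nsc["nsc_y"], tbl["cov_y"] / denom)

    def test_scale_invariance(self):
        tbl, _ = gen_coverage(seed=2)
        doubled = tbl.assign(cov_w=tbl.cov_w * 3, cov_y=tbl.cov_y * 3)
        np.testing.assert_allclose(
            compute_nsc(tbl)["nsc_w"], compute_nsc(doubled)["nsc_w"]
        )

    def test_mean_total_nsc_is_one_by_construction(self):
        tbl, _ = gen_coverage(seed=3)
        nsc = compute_nsc(tbl)
        assert (nsc["nsc_w"] + nsc["nsc_y"]).mean() == pytest.approx(1.0)

    def test_empty_and_zero_tables_rejected(self):
        with pytest.raises(ValueError):
            compute_nsc(balanced_table(0))
        with pytest.raises(ValueError):
            compute_nsc(balanced_table(10, depth=0))


class TestCopyStates:
    def test_balanced_disome_is_one_one(self):
        states = call_copy_states(compute_nsc(balanced_table()))
        assert (states["copies_w"] == 1).all()
        assert (states["copies_y"] == 1).all()

    def test_homozygous_duplication_is_two_zero(self):
        tbl = balanced_table()
        tbl["cov_w"], tbl["cov_y"] = 50, 0
        nsc = compute_nsc(tbl)
        # normalizer adapts: total is unchanged at 50, so nsc_w = 1.0
        states = call_copy_states(nsc)
        assert (states["copies_w"] == 2).all()
        assert (states["copies_y"] == 0).all()

    def test_window_must_be_odd(self):
        with pytest.raises(ValueError):
            call_copy_states(compute_nsc(balanced_table()), window_k=4)

    def test_short_chromosome_window_shrinks(self):
        states = call_copy_states(compute_nsc(balanced_table(5)), window_k=11)
        assert (states["copies_w"] == 1).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_boundaries_within_one_snp(self, seed):
        ev = PlantedEvent("chrIII", 2, 0, start=114_000, end=119_000)
        tbl, truth = gen_coverage(planted_events=[ev], seed=seed)
        states = call_copy_states(compute_nsc(tbl))
        sub = states[states["chrom"] == "chrIII"].reset_index(drop=True)
        deviant = (sub["copies_w"] != 1) | (sub["copies_y"] != 1)
        idx = np.where(deviant)[0]
        truth_run = next(
            r for r in truth.data["segments"]["chrIII"] if r["copies_y"] == 0
        )
        assert abs(idx.min() - truth_run["start_idx"]) <= 1
        assert abs(idx.max() - truth_run["end_idx"]) <= 1


class TestSegmentation:
    def test_terminal_vs_interstitial(self):
        tbl = balanced_table(100)
        # terminal LOH reaching the last SNP; interstitial conversion inside
        tbl.loc[80:, "cov_w"] = 50
        tbl.loc[80:, "cov_y"] = 0
        tbl.loc[20:25, "cov_w"] = 0
        tbl.loc[20:25, "cov_y"] = 50
        tracts = segment_tracts(call_copy_states(compute_nsc(tbl)))
        kinds = {(t.kind, t.retained_parent) for t in tracts}
        assert ("terminal", "W") in kinds
        assert ("interstitial", "Y") in kinds

    def test_planted_event_counts_recovered(self):
        # six chromosomes allow 12 terminal events (both ends of each)
        lengths = {f"c{i}": 200_000 for i in range(6)}
        cens = {f"c{i}": 100_000 for i in range(6)}
        gm = GenomeModel(GenomeMetadata(lengths, cens), snp_spacing=400)
        events = []
        for i in range(6):
            events.append(PlantedEvent(f"c{i}", 2, 0, start=1, end=15_000))
            events.append(PlantedEvent(f"c{i}", 0, 2, start=185_000, end=200_000))
        for i, s in enumerate((40_000, 60_000, 80_000, 120_000)):
            events.append(PlantedEvent(f"c{i}", 2, 0, start=s, end=s + 8_000))
        tbl, _ = gen_coverage(gm, events, seed=12)
        tracts = segment_tracts(call_copy_states(compute_nsc(tbl)))
        kinds = [t.kind for t in tracts]
        assert kinds.count("terminal") == 12
        assert kinds.count("interstitial") == 4

    def test_patchy_tract_flagged(self):
        segs = (TractSegment(1000, 2000, 2, 0), TractSegment(2400, 3000, 0, 2))
        t = LohTract("chrIII", 1000, 3000, "interstitial", segs)
        assert t.patchy and t.retained_parent is None


class TestAneuploidy:
    def test_balanced_chromosome_disomic(self):
        assert call_aneuploidy(compute_nsc(balanced_table())) == {
            "chrIII": "disomic"
        }

    @pytest.mark.parametrize("copies,expected", [
        ((1, 0), "monosomic"), ((2, 1), "trisomic"), ((3, 2), "other"),
    ])
    def test_simulated_whole_chromosome_states(self, copies, expected):
        ev = PlantedEvent("chrI", copies[0], copies[1])
        tbl, _ = gen_coverage(planted_events=[ev], seed=4)
        calls = call_aneuploidy(compute_nsc(tbl))
        assert calls["chrI"] == expected
        assert calls["chrV"] == "disomic"


class TestConversionTractStats:
    def test_order_statistics(self):
        tracts = [
            LohTract("chrIII", 100_000, 102_000, "interstitial",
                     (TractSegment(100_000, 102_000, 2, 0),)),
            LohTract("chrIII", 105_000, 108_000, "interstitial",
                     (TractSegment(105_000, 108_000, 2, 0),)),
            LohTract("chrIII", 120_000, 149_000, "interstitial",
                     (TractSegment(120_000, 149_000, 0, 2),)),
        ]
        s = conversion_tract_stats(tracts, centromere_pos=114_000)
        assert s.median_kb == pytest.approx(3.0005, abs=1e-3)
        assert s.min_kb == pytest.approx(2.001, abs=1e-3)
        assert s.max_kb == pytest.approx(29.001, abs=1e-3)

    def test_tract_spanning_centromere_not_unidirectional(self):
        spanning = LohTract("chrIII", 110_000, 118_000, "interstitial",
                            (TractSegment(110_000, 118_000, 2, 0),))
        left_only = LohTract("chrIII", 100_000, 105_000, "interstitial",
                             (TractSegment(100_000, 105_000, 2, 0),))
        s = conversion_tract_stats([spanning, left_only], centromere_pos=114_000)
        assert s.n_unidirectional == 1

    def test_empty_summary(self):
        s = conversion_tract_stats([], centromere_pos=114_000)
        assert s.n_total == 0 and s.median_kb is None

    def test_planted_tracts_summary_matches_truth(self):
        events = [
            PlantedEvent("chrIII", 2, 0, start=114_400, end=119_200),
            PlantedEvent("chrIII", 0, 2, start=100_000, end=108_000),
        ]
        tbl, truth = gen_coverage(planted_events=events, seed=6)
        tracts = segment_tracts(call_copy_states(compute_nsc(tbl)))
        cen_tracts = [t for t in tracts if t.chrom == "chrIII"]
        s = conversion_tract_stats(cen_tracts, centromere_pos=114_000)
        assert s.n_total == 2
        # spans recovered within one 400-bp SNP spacing at each boundary
        spans = sorted(s.lengths_kb)
        assert spans[0] == pytest.approx(4.8, abs=0.8)
        assert spans[1] == pytest.approx(8.0, abs=0.8)


class TestCopyNumberCallerEstimator:
    def test_transform_adds_state_columns(self):
        tbl, _ = gen_coverage(seed=8)
        caller = CopyNumberCaller(window_k=11).fit(tbl)
        out = caller.transform(tbl)
        assert {"nsc_w", "nsc_y", "copies_w", "copies_y"} <= set(out.columns)
        assert caller.get_params() == {"window_k": 11}

    def test_unfitted_transform_raises(self):
        tbl, _ = gen_coverage(seed=8)
        with pytest.raises(RuntimeError):
            CopyNumberCaller().transform(tbl)
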
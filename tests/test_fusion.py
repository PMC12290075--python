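import numpy as np
import pandas as pd
import pytest

import imctc
from imctc.binmap import BinMap
from imctc.cnv import RatioProfile, SegmentSet, call_states, profile_cell, segment_cbs
from imctc.cnv import SegmentationConfig
from imctc.fusion import (
    FUSION,
    NON_FUSION,
    UNINFORMATIVE,
    attenuation_statistic,
    detect_clonal_events,
    expected_ratio,
    synthesize_fusion_profile,
)
from imctc.simulate import (
    CNAEvent,
    CellCountVector,
    SimulationConfig,
    make_truth_profile,
    simulate_counts,
)


class TestExpectedRatio:
    @pytest.mark.parametrize(
        "state,fused,ratio",
        [
            (3, False, 1.5),
            (1, False, 0.5),
            (3, True, 1.25),
            (1, True, 0.75),
            (2, False, 1.0),
            (2, True, 1.0),
            (4, False, 2.0),
            (4, True, 1.5),
        ],
    )
    def test_ratio_arithmetic(self, state, fused, ratio):
        assert expected_ratio(state, fused) == ratio

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            expected_ratio(-1, False)


def balanced_tumor(bm, depth=2_000_000, seed=0):
    """Tumor with one 40-bin gain and one 40-bin loss (mean ploidy exactly 2)."""
    truth = make_truth_profile(
        bm, [CNAEvent("chr2", 0, 40, 3), CNAEvent("chr3", 0, 40, 1)]
    )
    return truth, simulate_counts(
        truth, bm, SimulationConfig(depth, seed=seed), "tumor", "epi.CTC"
    )


class TestSynthesizeFusion:
    def test_fusion_compresses_gain_and_loss(self, flat_bin_map):
        bm = flat_bin_map
        _, tumor = balanced_tumor(bm, seed=31)
        wbc = simulate_counts(
            make_truth_profile(bm, []), bm, SimulationConfig(2_000_000, seed=32),
            "wbc", "WBC",
        )
        fused = synthesize_fusion_profile(tumor, wbc, bm)
        g = bm.chrom_slice("chr2").start
        l = bm.chrom_slice("chr3").start
        assert fused.ratios[g : g + 40].mean() == pytest.approx(1.25, abs=0.02)
        assert fused.ratios[l : l + 40].mean() == pytest.approx(0.75, abs=0.02)

    def test_fusion_with_empty_cell_is_identity(self, flat_bin_map):
        bm = flat_bin_map
        _, tumor = balanced_tumor(bm, seed=33)
        zero = CellCountVector(np.zeros(bm.n_bins, dtype=int), bm, "empty")
        fused = synthesize_fusion_profile(tumor, zero, bm)
        np.testing.assert_allclose(fused.ratios, profile_cell(tumor, bm).ratios)


def reference_segments(bm, gain_span, loss_span):
    rows = [
        {"chrom": gain_span[0], "start_bin": gain_span[1], "end_bin": gain_span[2],
         "n_bins": gain_span[2] - gain_span[1], "mean_ratio": 1.5, "state": 3},
        {"chrom": loss_span[0], "start_bin": loss_span[1], "end_bin": loss_span[2],
         "n_bins": loss_span[2] - loss_span[1], "mean_ratio": 0.5, "state": 1},
    ]
    return SegmentSet(pd.DataFrame(rows), cell_id="clonal_reference")


class TestAttenuation:
    @pytest.fixture()
    def setup(self, flat_bin_map):
        bm = flat_bin_map
        g = bm.chrom_slice("chr2").start
        l = bm.chrom_slice("chr3").start
        ref = reference_segments(bm, ("chr2", g, g + 40), ("chr3", l, l + 40))
        return bm, ref

    def test_self_comparison_near_one(self, setup):
        bm, ref = setup
        _, tumor = balanced_tumor(bm, seed=41)
        a = attenuation_statistic(profile_cell(tumor, bm), ref)
        assert a.attenuation == pytest.approx(1.0, abs=0.05)
        assert a.verdict == NON_FUSION
        assert a.n_informative_bins == 80

    def test_equal_depth_fusion_near_half(self, setup):
        bm, ref = setup
        _, tumor = balanced_tumor(bm, seed=42)
        wbc = simulate_counts(
            make_truth_profile(bm, []), bm, SimulationConfig(2_000_000, seed=43)
        )
        a = attenuation_statistic(synthesize_fusion_profile(tumor, wbc, bm), ref)
        assert a.attenuation == pytest.approx(0.5, abs=0.05)
        assert a.verdict == FUSION

    def test_diploid_wbc_near_zero(self, setup):
        bm, ref = setup
        wbc = simulate_counts(
            make_truth_profile(bm, []), bm, SimulationConfig(2_000_000, seed=44)
        )
        a = attenuation_statistic(profile_cell(wbc, bm), ref)
        assert a.attenuation == pytest.approx(0.0, abs=0.05)

    def test_uninformative_when_reference_neutral(self, setup):
        bm, _ = setup
        wbc_seg = SegmentSet(
            pd.DataFrame(
                [{"chrom": "chr1", "start_bin": 0, "end_bin": bm.n_bins,
                  "n_bins": bm.n_bins, "mean_ratio": 1.0, "state": 2}]
            )
        )
        _, tumor = balanced_tumor(bm, seed=45)
        a = attenuation_statistic(profile_cell(tumor, bm), wbc_seg)
        assert a.verdict == UNINFORMATIVE

    def test_x_chromosome_excluded_from_reference(self, flat_bin_map):
        bm = imctc.make_bin_map(400, 24, seed=5)
        slx = bm.chrom_slice("chrX")
        ref = SegmentSet(
            pd.DataFrame(
                [{"chrom": "chrX", "start_bin": slx.start, "end_bin": slx.stop,
                  "n_bins": slx.stop - slx.start, "mean_ratio": 0.5, "state": 1}]
            )
        )
        prof = RatioProfile(np.ones(bm.n_bins), bm)
        assert attenuation_statistic(prof, ref).verdict == UNINFORMATIVE

    def test_attenuation_decreases_with_diploid_read_fraction(self, setup):
        """Mixing in diploid reads at fraction w gives attenuation ~ 1 - w."""
        bm, ref = setup
        total = 2_000_000
        vals = []
        for w in (0.0, 0.25, 0.5):
            truth, _ = balanced_tumor(bm)
            tumor = simulate_counts(
                truth, bm, SimulationConfig(max(int((1 - w) * total), 1), seed=46)
            )
            if w == 0:
                prof = profile_cell(tumor, bm)
            else:
                wbc = simulate_counts(
                    make_truth_profile(bm, []), bm,
                    SimulationConfig(int(w * total), seed=47),
                )
                prof = synthesize_fusion_profile(tumor, wbc, bm)
            vals.append(attenuation_statistic(prof, ref).attenuation)
        assert vals[0] > vals[1] > vals[2]
        np.testing.assert_allclose(vals, [1.0, 0.75, 0.5], atol=0.05)

    def test_invariant_to_depth_rescaling(self, setup):
        bm, ref = setup
        _, tumor = balanced_tumor(bm, seed=48)
        from imctc.cnv import gc_correct, ratio_normalize

        corrected = gc_correct(tumor, bm)
        a1 = attenuation_statistic(ratio_normalize(corrected, bm), ref)
        a2 = attenuation_statistic(ratio_normalize(corrected * 7.3, bm), ref)
        assert a1.attenuation == pytest.approx(a2.attenuation, rel=1e-9)


def clone_segments(bm, cell_id, seed, depth=1_000_000):
    truth = make_truth_profile(bm, imctc.index_clone_events(bm), clone="index")
    cell = simulate_counts(truth, bm, SimulationConfig(depth, seed=seed), cell_id)
    prof = profile_cell(cell, bm)
    return call_states(
        segment_cbs(prof, SegmentationConfig(alpha=0.01, n_perm=100, seed=seed))
    )


def wbc_segments(bm, cell_id, seed, depth=1_000_000):
    cell = simulate_counts(
        make_truth_profile(bm, []), bm, SimulationConfig(depth, seed=seed), cell_id
    )
    return call_states(
        segment_cbs(profile_cell(cell, bm),
                    SegmentationConfig(alpha=0.01, n_perm=100, seed=seed))
    )


@pytest.fixture(scope="module")
def cohort(bin_map_5k):
    clones = [clone_segments(bin_map_5k, f"t{i}", 600 + i) for i in range(10)]
    wbcs = [wbc_segments(bin_map_5k, f"w{i}", 700 + i) for i in range(4)]
    return clones, wbcs


class TestClonality:

    def test_identical_clone_all_flagged(self, cohort):
        clones, _ = cohort
        rep = detect_clonal_events(clones)
        assert rep.n_clonal_events >= 5
        assert rep.per_cell["clonal"].all()

    def test_wbc_controls_not_flagged(self, cohort):
        clones, wbcs = cohort
        rep = detect_clonal_events(clones + wbcs)
        flags = rep.per_cell.set_index("cell_id")
        assert flags.loc[[f"t{i}" for i in range(10)], "clonal"].all()
        assert not flags.loc[[f"w{i}" for i in range(4)], "clonal"].any()
        assert (flags.loc[[f"w{i}" for i in range(4)],
                          "n_clonal_events_carried"] == 0).all()

    def test_order_invariant(self, cohort):
        clones, wbcs = cohort
        cells = clones + wbcs
        a = detect_clonal_events(cells)
        b = detect_clonal_events(cells[::-1])
        assert a.n_clonal_events == b.n_clonal_events
        merged = a.per_cell.merge(b.per_cell, on="cell_id")
        assert (merged["clonal_x"] == merged["clonal_y"]).all()

    def test_private_losses_are_not_clonal(self, bin_map_5k):
        """Nine cells carrying only private (non-shared) losses yield zero
        clonal events — the pattern of non-tumor CD45+/CK+ candidates."""
        bm = bin_map_5k
        cells = []
        chroms = [f"chr{c}" for c in range(1, 10)]
        for i, chrom in enumerate(chroms):
            sl = bm.chrom_slice(chrom)
            n = sl.stop - sl.start
            events = (
                [CNAEvent(chrom, 0, n // 3, 1)] if i % 3 == 0 else []
            )  # a third carry one private loss each, elsewhere diploid
            truth = make_truth_profile(bm, events)
            cell = simulate_counts(
                truth, bm, SimulationConfig(1_000_000, seed=800 + i), f"p3_{i}"
            )
            cells.append(
                call_states(
                    segment_cbs(
                        profile_cell(cell, bm),
                        SegmentationConfig(alpha=0.01, n_perm=100, seed=i),
                    )
                )
            )
        rep = detect_clonal_events(cells)
        assert rep.n_clonal_events == 0
        assert not rep.per_cell["clonal"].any()

    def test_requires_two_cells(self, bin_map_5k):
        with pytest.raises(ValueError):
            detect_clonal_events([])
        with pytest.raises(ValueError):
            detect_clonal_events([wbc_segments(bin_map_5k, "w", 1)])
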
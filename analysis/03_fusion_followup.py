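#!/usr/bin/env python
"""Fusion hypothesis and follow-up patient scenarios.

Part 1 quantifies compression directly: a simulated tumor cell is fused
with an equal-depth WBC (bin counts summed, GC-corrected, re-normalised)
and the attenuation statistic is computed for the tumor, the synthetic
fusion, and a plain WBC.

Part 2 replays the two follow-up scenarios: a patient whose im.CTCs share
the epi.CTC clone's alterations (everything clonal), and a patient whose
im.CTC candidates carry only private losses (nothing clonal; not tumor).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import imctc
from imctc.cnv import SegmentationConfig, call_states, profile_cell, segment_cbs
from imctc.simulate import CNAEvent, SimulationConfig, make_truth_profile, simulate_counts

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEG_CFG = dict(alpha=0.01, n_perm=100)


def segments_for(cell, bm, seed):
    return call_states(
        segment_cbs(profile_cell(cell, bm), SegmentationConfig(seed=seed, **SEG_CFG))
    )


def part1_compression(seed: int) -> None:
    from imctc import experiments as ex

    res = ex.ratio_compression_experiment(seed=seed)
    print("-- synthetic fusion compression --")
    print(f"tumor gain/loss segment ratios:  {res['tumor_gain_ratio']:.3f} / "
          f"{res['tumor_loss_ratio']:.3f}   (expected 1.5 / 0.5)")
    print(f"fusion gain/loss segment ratios: {res['fusion_gain_ratio']:.3f} / "
          f"{res['fusion_loss_ratio']:.3f}   (expected 1.25 / 0.75)")

    res2 = ex.attenuation_recovery_experiment(seed=seed)
    print(f"attenuation over {res2['n_runs']} noisy runs: "
          f"tumor {res2['mean_tumor_attenuation']:.3f}, "
          f"fusion {res2['mean_fusion_attenuation']:.3f}; "
          f"verdict accuracy {100 * res2['verdict_accuracy']:.0f}%")


def followup_cohort(bm, truth_events, n_im, n_epi, n_wbc, seed, private_loss_im=False):
    rng = np.random.default_rng(seed)
    truth = make_truth_profile(bm, truth_events, clone="followup")
    diploid = make_truth_profile(bm, [], clone="diploid")
    cells = []
    for i in range(n_im):
        if private_loss_im:
            # at most a private loss on a per-cell chromosome; mostly diploid
            if i % 3 == 0:
                chrom = f"chr{2 + i}"
                sl = bm.chrom_slice(chrom)
                n = sl.stop - sl.start
                t = make_truth_profile(bm, [CNAEvent(chrom, 0, n // 2, 1)])
            else:
                t = diploid
        else:
            t = truth
        cells.append(
            simulate_counts(t, bm, SimulationConfig(1_000_000, seed=int(rng.integers(2**31))),
                            f"im{i}", "im.CTC")
        )
    for i in range(n_epi):
        cells.append(
            simulate_counts(truth, bm, SimulationConfig(1_000_000, seed=int(rng.integers(2**31))),
                            f"epi{i}", "epi.CTC")
        )
    for i in range(n_wbc):
        cells.append(
            simulate_counts(diploid, bm, SimulationConfig(1_000_000, seed=int(rng.integers(2**31))),
                            f"wbc{i}", "WBC")
        )
    segs = [segments_for(c, bm, seed=int(rng.integers(2**31))) for c in cells]
    rep = imctc.detect_clonal_events(segs)
    types = pd.Series([c.cell_type for c in cells], name="cell_type")
    per_cell = rep.per_cell.assign(cell_type=types.values)
    return rep, per_cell


def part2_followup(seed: int) -> None:
    bm = imctc.make_bin_map(2000, 24, seed=seed)
    sl3 = bm.chrom_slice("chr3")
    sl5 = bm.chrom_slice("chr5")
    events = [
        CNAEvent("chr3", 0, (sl3.stop - sl3.start) // 2, 3),
        CNAEvent("chr5", 0, (sl5.stop - sl5.start) // 2, 1),
    ]

    print("-- follow-up patient with clonal im.CTCs (7 im, 6 epi, 2 WBC) --")
    rep, per_cell = followup_cohort(bm, events, 7, 6, 2, seed)
    im = per_cell[per_cell["cell_type"] == "im.CTC"]
    print(f"clonal events: {rep.n_clonal_events}; "
          f"im.CTCs flagged clonal: {im['clonal'].sum()}/{len(im)}")
    per_cell.to_csv(RESULTS / "followup_clonal_patient.tsv", sep="\t", index=False)

    print("-- follow-up patient without clonal im.CTCs (9 im, private losses only) --")
    rep3, per_cell3 = followup_cohort(bm, [], 9, 0, 3, seed + 1, private_loss_im=True)
    im3 = per_cell3[per_cell3["cell_type"] == "im.CTC"]
    print(f"clonal events: {rep3.n_clonal_events}; "
          f"im.CTC candidates flagged clonal: {im3['clonal'].sum()}/{len(im3)} "
          "(these candidates do not look like tumor cells)")
    per_cell3.to_csv(RESULTS / "followup_nonclonal_patient.tsv", sep="\t", index=False)


def main(seed: int) -> None:
    RESULTS.mkdir(exist_ok=True)
    part1_compression(seed)
    part2_followup(seed)


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    main(p.parse_args().seed)
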
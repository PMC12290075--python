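"""Tumor-WBC fusion assessment and clonality scoring.

A tumor cell fused with a diploid leukocyte carries the tumor's CNAs diluted
by a full extra diploid genome: in an initially diploid tumor a single-copy
gain reads out as a 3:2 ratio (1.5) and a loss as 2:1 (0.5), while after
adding a diploid genome those become 5:4 (1.25) and 4:3 (0.75) — a
"compressed" profile.  The attenuation statistic formalises this: regressing
a query cell's bin-ratio deviations on a clonal reference's segment-mean
deviations (slope through the origin) yields ~1 for a true tumor cell, ~0.5
for a 1:1 tumor-diploid fusion, and ~0 for a plain leukocyte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binmap import BinMap
from .cnv import RatioProfile, SegmentSet, gc_correct, ratio_normalize
from .simulate import CellCountVector, fuse_counts

__all__ = [
    "FusionAssessment",
    "ClonalityReport",
    "expected_ratio",
    "synthesize_fusion_profile",
    "attenuation_statistic",
    "detect_clonal_events",
]

NON_FUSION = "non-fusion-consistent"
FUSION = "fusion-consistent"
UNINFORMATIVE = "uninformative"


def expected_ratio(tumor_state: int, fused_with_diploid: bool) -> float:
    """Expected normalised bin ratio for a tumor copy state, optionally after
    fusion with a diploid genome at equal depth (near-diploid tumor, altered
    fraction small): state/2 unfused, (state + 2)/4 fused."""
    if tumor_state < 0:
        raise ValueError("tumor_state must be non-negative")
    if fused_with_diploid:
        return (tumor_state + 2) / 4.0
    return tumor_state / 2.0


def synthesize_fusion_profile(
    tumor: CellCountVector, wbc: CellCountVector, bin_map: BinMap
) -> RatioProfile:
    """Synthetic fusion profile: sum the two cells' bin read counts, correct
    for GC content, and re-normalise to the genome-wide mean."""
    fused = fuse_counts(tumor, wbc)
    corrected = gc_correct(fused, bin_map)
    return ratio_normalize(
        corrected, bin_map, cell_id=fused.cell_id, cell_type="synthetic_fusion"
    )


@dataclass(frozen=True)
class FusionAssessment:
    """Attenuation of CNA amplitudes in a query cell relative to the clonal
    reference, with the resulting verdict."""

    cell_id: str
    attenuation: float
    n_informative_bins: int
    verdict: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.attenuation):
            raise ValueError("attenuation must be finite")


def attenuation_statistic(
    query: RatioProfile,
    reference_segments: SegmentSet,
    min_informative: int = 50,
    fusion_threshold: float = 0.75,
    exclude_chromosomes: tuple[str, ...] = ("chrX",),
    baseline_state: int = 2,
) -> FusionAssessment:
    """Least-squares slope through the origin of (query bin ratio - 1)
    against (reference segment mean ratio - 1) over bins inside non-neutral
    reference segments.

    X-chromosome bins are excluded by default: partial or complete X loss is
    subclonal in these tumors and would contaminate the clonal reference.
    Cells with fewer than ``min_informative`` usable bins are reported
    uninformative (attenuation 0 by convention).
    """
    seg = reference_segments.non_neutral(baseline_state)
    seg = seg[~seg["chrom"].isin(exclude_chromosomes)]
    x_parts, y_parts = [], []
    for row in seg.itertuples():
        lo, hi = int(row.start_bin), int(row.end_bin)
        x_parts.append(np.full(hi - lo, row.mean_ratio - 1.0))
        y_parts.append(query.ratios[lo:hi] - 1.0)
    n_bins = int(sum(len(p) for p in x_parts))
    if n_bins < min_informative:
        return FusionAssessment(query.cell_id, 0.0, n_bins, UNINFORMATIVE)
    x = np.concatenate(x_parts)
    y = np.concatenate(y_parts)
    denom = float(np.dot(x, x))
    if denom == 0:
        return FusionAssessment(query.cell_id, 0.0, n_bins, UNINFORMATIVE)
    a = float(np.dot(x, y) / denom)
    verdict = FUSION if a < fusion_threshold else NON_FUSION
    return FusionAssessment(query.cell_id, a, n_bins, verdict)


@dataclass(frozen=True)
class ClonalityReport:
    """Shared (clonal) CNA events across cells and per-cell carrier status.

    ``events``: one row per clonal event (chrom, start_bin, end_bin median
    span across carriers, direction, n_cells).
    ``per_cell``: cell_id, n_clonal_events_carried, clonal flag.
    """

    events: pd.DataFrame
    per_cell: pd.DataFrame
    n_clonal_events: int


def _reciprocal_overlap(a_lo, a_hi, b_lo, b_hi) -> float:
    inter = min(a_hi, b_hi) - max(a_lo, b_lo)
    if inter <= 0:
        return 0.0
    return min(inter / (a_hi - a_lo), inter / (b_hi - b_lo))


def detect_clonal_events(
    cells: list[SegmentSet],
    min_cell_fraction: float = 0.5,
    min_overlap: float = 0.5,
    baseline_state: int = 2,
) -> ClonalityReport:
    """Identify CNAs shared across single cells and flag clonal cells.

    Non-neutral segments from all cells are linked when they sit on the same
    chromosome, deviate in the same direction (gain vs loss), and have
    reciprocal bin overlap >= ``min_overlap``; connected components of this
    link graph are candidate events.  An event is clonal when carried by at
    least ``min_cell_fraction`` of the input cells; a cell is flagged clonal
    when it carries at least half of the clonal events.  Order-invariant in
    the cell list.
    """
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to assess clonality")
    recs = []
    for ci, segset in enumerate(cells):
        for row in segset.non_neutral(baseline_state).itertuples():
            recs.append(
                {
                    "cell_idx": ci,
                    "cell_id": segset.cell_id,
                    "chrom": row.chrom,
                    "start_bin": int(row.start_bin),
                    "end_bin": int(row.end_bin),
                    "direction": "gain" if row.state > baseline_state else "loss",
                }
            )
    n_cells = len(cells)
    cell_ids = [c.cell_id for c in cells]
    if not recs:
        per_cell = pd.DataFrame(
            {"cell_id": cell_ids, "n_clonal_events_carried": 0, "clonal": False}
        )
        return ClonalityReport(pd.DataFrame(), per_cell, 0)

    ev = pd.DataFrame(recs)
    m = len(ev)
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for key, grp in ev.groupby(["chrom", "direction"]):
        idx = grp.index.to_numpy()
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                a, b = ev.loc[idx[ii]], ev.loc[idx[jj]]
                if (
                    _reciprocal_overlap(
                        a.start_bin, a.end_bin, b.start_bin, b.end_bin
                    )
                    >= min_overlap
                ):
                    union(int(idx[ii]), int(idx[jj]))

    ev["component"] = [find(i) for i in range(m)]
    event_rows = []
    carriers: dict[int, set[int]] = {}
    for comp, grp in ev.groupby("component"):
        cells_in = set(grp["cell_idx"])
        if len(cells_in) / n_cells >= min_cell_fraction:
            carriers[comp] = cells_in
            event_rows.append(
                {
                    "chrom": grp["chrom"].iloc[0],
                    "start_bin": int(grp["start_bin"].median()),
                    "end_bin": int(grp["end_bin"].median()),
                    "direction": grp["direction"].iloc[0],
                    "n_cells": len(cells_in),
                }
            )
    events = (
        pd.DataFrame(event_rows)
        .sort_values(["chrom", "start_bin"])
        .reset_index(drop=True)
        if event_rows
        else pd.DataFrame()
    )
    n_clonal = len(event_rows)
    carried = np.zeros(n_cells, dtype=int)
    for cells_in in carriers.values():
        for ci in cells_in:
            carried[ci] += 1
    clonal_flag = (carried >= 0.5 * n_clonal) & (n_clonal > 0)
    per_cell = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "n_clonal_events_carried": carried,
            "clonal": clonal_flag,
        }
    )
    return ClonalityReport(events, per_cell, n_clonal)
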
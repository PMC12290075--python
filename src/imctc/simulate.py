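"""Synthetic data generators with known ground truth.

Three kinds of input are emulated, each with the structure the downstream
analytics expect:

* per-cell bin read counts for near-diploid tumor cells carrying clonal copy
  number alterations, diploid white blood cells, and tumor-WBC fusion cells
  formed by summing two parents' counts;
* slide-level immunofluorescence feature tables (mean CK and CD45 intensity
  per cell) for rare-cell detection;
* imaging-mass-cytometry ion-count tables (cells x markers, with mask area
  and DNA-intercalator counts) for QC filtering, gating and clustering.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binmap import BinMap

__all__ = [
    "CNAEvent",
    "CopyStateVector",
    "SimulationConfig",
    "CellCountVector",
    "FeaturePopulation",
    "IonPopulation",
    "make_truth_profile",
    "simulate_counts",
    "fuse_counts",
    "simulate_feature_table",
    "simulate_ion_counts",
    "index_clone_events",
    "firestorm_events",
    "IMC_MARKERS",
    "default_imc_populations",
    "default_feature_populations",
]


@dataclass(frozen=True)
class CNAEvent:
    """A copy-number event: bins [start_bin, end_bin) of one chromosome set
    to ``state`` copies.  Bin indices are 0-based within the chromosome."""

    chromosome: str
    start_bin: int
    end_bin: int
    state: int

    def __post_init__(self) -> None:
        if self.state < 0:
            raise ValueError("copy state must be non-negative")
        if not 0 <= self.start_bin < self.end_bin:
            raise ValueError("need 0 <= start_bin < end_bin")


@dataclass(frozen=True)
class CopyStateVector:
    """Integer copy state per bin for one clone (baseline ploidy 2)."""

    states: np.ndarray
    clone: str = "clone"

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int64)
        if np.any(states < 0):
            raise ValueError("copy states must be non-negative")
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class SimulationConfig:
    """Sequencing emulation parameters.

    total_reads: reads per cell (default 1e6; depth is a free choice, the
        analysis depends only on ratios).
    gc_bias: coefficients (c0, c1, c2) of a multiplicative quadratic bias
        c0 + c1*gc + c2*gc^2 applied to each bin's expected count.
    dispersion: 0 gives multinomial (Poisson-like) counts; > 0 adds
        gamma-multiplied (negative-binomial-style) overdispersion.
    """

    total_reads: int = 1_000_000
    gc_bias: tuple[float, float, float] = (1.0, 0.0, 0.0)
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def bias(self, gc: np.ndarray) -> np.ndarray:
        c0, c1, c2 = self.gc_bias
        b = c0 + c1 * gc + c2 * gc**2
        if np.any(b <= 0):
            raise ValueError("gc_bias must be positive over the observed GC range")
        return b


@dataclass(frozen=True)
class CellCountVector:
    """One cell's per-bin read counts plus metadata."""

    counts: np.ndarray
    bin_map: BinMap
    cell_id: str
    cell_type: str = "tumor"
    draw: int = 1
    parents: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if len(counts) != self.bin_map.n_bins:
            raise ValueError("counts length must match the bin map")
        if np.any(counts < 0):
            raise ValueError("read counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def make_truth_profile(
    bin_map: BinMap, events: list[CNAEvent], clone: str = "clone"
) -> CopyStateVector:
    """Lay CNA events over a diploid baseline; later events overwrite earlier."""
    states = np.full(bin_map.n_bins, 2, dtype=np.int64)
    for ev in events:
        sl = bin_map.chrom_slice(ev.chromosome)
        n_chrom = sl.stop - sl.start
        if ev.end_bin > n_chrom:
            raise ValueError(
                f"event [{ev.start_bin}, {ev.end_bin}) exceeds {ev.chromosome} "
                f"({n_chrom} bins)"
            )
        states[sl.start + ev.start_bin : sl.start + ev.end_bin] = ev.state
    return CopyStateVector(states, clone=clone)


def expected_bin_weights(
    truth: CopyStateVector, bin_map: BinMap, config: SimulationConfig
) -> np.ndarray:
    """Unnormalised expected count per bin: state x length x gc_bias."""
    return truth.states * bin_map.lengths.astype(float) * config.bias(bin_map.gc)


def simulate_counts(
    truth: CopyStateVector,
    bin_map: BinMap,
    config: SimulationConfig,
    cell_id: str = "cell",
    cell_type: str = "tumor",
    draw: int = 1,
) -> CellCountVector:
    """Draw one cell's bin counts.

    Expected count per bin is proportional to copy state x bin length x
    GC bias.  With dispersion 0 counts are multinomial over bins (per-bin
    marginals Poisson-like); with dispersion d > 0 each bin's rate is
    multiplied by an independent Gamma(1/d, d) variate before Poisson
    sampling, giving negative-binomial-style overdispersion.
    """
    if len(truth) != bin_map.n_bins:
        raise ValueError("truth length must match the bin map")
    if np.all(truth.states == 0):
        raise ValueError("truth profile is all-zero; nothing to sequence")
    rng = np.random.default_rng(config.seed)
    w = expected_bin_weights(truth, bin_map, config)
    p = w / w.sum()
    if config.dispersion == 0:
        counts = rng.multinomial(config.total_reads, p)
    else:
        g = rng.gamma(1.0 / config.dispersion, config.dispersion, size=len(p))
        counts = rng.poisson(config.total_reads * p * g)
    return CellCountVector(counts, bin_map, cell_id, cell_type, draw)


def fuse_counts(a: CellCountVector, b: CellCountVector) -> CellCountVector:
    """Sum two cells' bin counts, emulating a doublet / fusion genome."""
    if a.bin_map != b.bin_map:
        raise ValueError("cells must share a bin map to be fused")
    return CellCountVector(
        a.counts + b.counts,
        a.bin_map,
        cell_id=f"{a.cell_id}+{b.cell_id}",
        cell_type="fusion",
        draw=a.draw,
        parents=(a.cell_id, b.cell_id),
    )


# ---------------------------------------------------------------------------
# Canned CNA scenarios


def firestorm_events(
    chromosome: str, n_bins_chrom: int, n_blocks: int = 6
) -> list[CNAEvent]:
    """Alternating gain/loss blocks across one chromosome — the dense
    oscillating amplification pattern seen in rearranged breast cancer
    genomes ('firestorm')."""
    if n_blocks < 4:
        raise ValueError("a firestorm needs at least 4 alternating blocks")
    edges = np.linspace(0, n_bins_chrom, n_blocks + 1).astype(int)
    return [
        CNAEvent(chromosome, int(edges[i]), int(edges[i + 1]), 3 if i % 2 == 0 else 1)
        for i in range(n_blocks)
        if edges[i + 1] > edges[i]
    ]


def index_clone_events(bin_map: BinMap) -> list[CNAEvent]:
    """Clonal CNA set patterned on the index tumor: 1p loss and 1q gain,
    4q loss, a chromosome-8 firestorm, 16p gain, 16q loss."""

    def n_chrom(c: str) -> int:
        sl = bin_map.chrom_slice(c)
        return sl.stop - sl.start

    n1, n4, n8, n16 = (n_chrom(c) for c in ("chr1", "chr4", "chr8", "chr16"))
    events = [
        CNAEvent("chr1", 0, n1 // 3, 1),            # 1p loss
        CNAEvent("chr1", n1 // 2, n1, 3),           # 1q gain (covers PTPRC locus)
        CNAEvent("chr4", n4 // 2, n4, 1),           # 4q loss
        CNAEvent("chr16", 0, int(0.45 * n16), 3),   # 16p gain
        CNAEvent("chr16", int(0.45 * n16), n16, 1), # 16q loss
    ]
    events.extend(firestorm_events("chr8", n8))
    return events


# ---------------------------------------------------------------------------
# Immunofluorescence feature tables


@dataclass(frozen=True)
class FeaturePopulation:
    """One cell population on a slide: mixture fraction and Gaussian
    intensity distributions for the CK and CD45 channels."""

    name: str
    fraction: float
    ck_mean: float
    ck_sd: float
    cd45_mean: float
    cd45_sd: float
    annotation: str | None = None  # e.g. "CD45+/CK+" for classifier truth


def default_feature_populations(rare_fraction: float = 0.002) -> list[FeaturePopulation]:
    """A slide dominated by CK-negative nucleated background cells with rare
    CK+ spikes split ~97:3 between CD45+/CK+ and CD45-/CK+ phenotypes, the
    proportion seen in the index case."""
    f_im = rare_fraction * 0.97
    f_epi = rare_fraction * 0.03
    return [
        FeaturePopulation("background", 1.0 - rare_fraction, 100.0, 10.0, 150.0, 40.0),
        FeaturePopulation("im.CTC", f_im, 320.0, 25.0, 180.0, 25.0, "CD45+/CK+"),
        FeaturePopulation("epi.CTC", f_epi, 320.0, 25.0, 20.0, 8.0, "CD45-/CK+"),
    ]


def _apportion(n: int, fractions: np.ndarray) -> np.ndarray:
    """Exact largest-remainder apportionment of n items over fractions."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    short = n - counts.sum()
    for i in np.argsort(-rem)[:short]:
        counts[i] += 1
    return counts


def simulate_feature_table(
    n_cells: int,
    populations: list[FeaturePopulation],
    seed: int = 0,
    slide: str = "slide1",
) -> pd.DataFrame:
    """Per-cell mean CK / CD45 intensities with ground-truth labels.

    Population sizes are apportioned exactly from the requested fractions
    (largest remainder), then rows are shuffled.  Intensities are Gaussian,
    clipped at 0.
    """
    if not populations:
        raise ValueError("need at least one population")
    fracs = np.array([p.fraction for p in populations], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-8:
        raise ValueError("population fractions must sum to 1")
    cols = ["cell_id", "slide", "mean_ck", "mean_cd45", "population", "annotation"]
    if n_cells == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    sizes = _apportion(n_cells, fracs)
    frames = []
    for pop, k in zip(populations, sizes):
        if k == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "slide": slide,
                    "mean_ck": np.clip(rng.normal(pop.ck_mean, pop.ck_sd, k), 0, None),
                    "mean_cd45": np.clip(
                        rng.normal(pop.cd45_mean, pop.cd45_sd, k), 0, None
                    ),
                    "population": pop.name,
                    "annotation": pop.annotation,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df.insert(0, "cell_id", [f"{slide}_c{i:06d}" for i in range(len(df))])
    return df[cols]


# ---------------------------------------------------------------------------
# Imaging mass cytometry ion-count tables

# 22-marker analysis panel (DNA intercalator held in its own column).
IMC_MARKERS = [
    "CD45", "CD3", "CD4", "CD8a", "CD14", "CD16", "CD20", "CD56", "CD68",
    "CD44", "CD45RA", "CD45RO", "CK8_18", "CK19", "EpCAM", "Ecadherin",
    "HER2", "Vimentin", "Ki67", "CD31", "CD11b", "HLADR",
]

_BG = 0.5  # background mean ion count for unexpressed markers


@dataclass(frozen=True)
class IonPopulation:
    """One cell population's mean ion count per marker (Poisson sampling)."""

    name: str
    means: dict[str, float]

    def mean_vector(self, markers: list[str]) -> np.ndarray:
        return np.array([self.means.get(m, _BG) for m in markers], dtype=float)


def default_imc_populations() -> list[IonPopulation]:
    """Leukocyte lineages plus the two CTC phenotypes, with the qualitative
    expression pattern observed in the index case: im.CTCs are CK8/18+,
    CD45+, CD3+, CD4+, CD44-high, moderately CD14+ but CD68-negative —
    closest, among leukocytes, to CD4 T cells."""
    return [
        IonPopulation("CD4 T cell", {"CD45": 60, "CD3": 40, "CD4": 30,
                                     "CD45RA": 20, "CD45RO": 15, "CD44": 10}),
        IonPopulation("CD8 T cell", {"CD45": 60, "CD3": 40, "CD8a": 30,
                                     "CD45RA": 22, "CD45RO": 12, "CD44": 8}),
        IonPopulation("B cell", {"CD45": 55, "CD20": 40, "HLADR": 30}),
        IonPopulation("NK cell", {"CD45": 50, "CD56": 35, "CD16": 25}),
        IonPopulation("monocyte", {"CD45": 55, "CD14": 40, "CD68": 30,
                                   "CD11b": 30, "CD16": 15, "HLADR": 25}),
        IonPopulation("im.CTC", {"CK8_18": 45, "CK19": 25, "CD45": 55, "CD3": 35,
                                 "CD4": 35, "CD44": 60, "CD14": 8, "CD68": _BG,
                                 "CD45RO": 18, "CD45RA": 8, "Ki67": 6}),
        IonPopulation("epi.CTC", {"CK8_18": 50, "CK19": 30, "EpCAM": 5,
                                  "Ecadherin": 4, "CD44": 15, "Ki67": 6}),
    ]


def simulate_ion_counts(
    populations: list[IonPopulation],
    n_cells: dict[str, int] | int,
    seed: int = 0,
    markers: list[str] | None = None,
    area_mean: float = 100.0,
    area_sd: float = 30.0,
    dna1_mean: float = 30.0,
    qc_fail_fraction: float = 0.0,
    draw: int = 1,
    noise: str = "poisson",
) -> pd.DataFrame:
    """Cells x markers ion-count table with mask area and DNA1 columns.

    ``qc_fail_fraction`` of each population's masks (exact count, largest
    remainder ignored — rounded per population) are planted to violate mask
    QC (area outside [40, 200] or DNA1 < 4); the ``planted_qc_fail`` column
    records which, for filter bookkeeping tests.

    ``noise`` is "poisson" (default) or "none" (ion counts fixed at the
    rounded population means).
    """
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")
    if not populations:
        raise ValueError("need at least one population")
    markers = list(markers) if markers is not None else list(IMC_MARKERS)
    for pop in populations:
        unknown = set(pop.means) - set(markers)
        if unknown:
            raise ValueError(f"population {pop.name!r} has unknown markers {unknown}")
    if isinstance(n_cells, int):
        n_cells = {p.name: n_cells for p in populations}
    if any(v < 0 for v in n_cells.values()):
        raise ValueError("requested cell counts must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for pop in populations:
        k = n_cells.get(pop.name, 0)
        if k == 0:
            continue
        lam = pop.mean_vector(markers)
        if noise == "poisson":
            ions = rng.poisson(np.tile(lam, (k, 1)))
        else:
            ions = np.tile(np.round(lam).astype(int), (k, 1))
        area = np.clip(rng.normal(area_mean, area_sd, k), 41, 199).round().astype(int)
        dna1 = rng.poisson(dna1_mean, k).astype(float)
        dna1 = np.maximum(dna1, 4.0)
        n_fail = int(round(qc_fail_fraction * k))
        fail_idx = rng.choice(k, size=n_fail, replace=False)
        fail_kind = rng.integers(0, 3, size=n_fail)
        area[fail_idx[fail_kind == 0]] = rng.integers(5, 40, size=(fail_kind == 0).sum())
        area[fail_idx[fail_kind == 1]] = rng.integers(201, 400, size=(fail_kind == 1).sum())
        dna1[fail_idx[fail_kind == 2]] = rng.uniform(0, 3.99, size=(fail_kind == 2).sum())
        planted = np.zeros(k, dtype=bool)
        planted[fail_idx] = True
        df = pd.DataFrame(ions, columns=markers)
        df.insert(0, "population", pop.name)
        df.insert(1, "area", area)
        df.insert(2, "DNA1", dna1)
        df["planted_qc_fail"] = planted
        df["draw"] = draw
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "cell_id", [f"mask{i:06d}" for i in range(len(out))])
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: copy a config with a new seed."""
    return replace(config, seed=seed)
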
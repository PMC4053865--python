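"""Synthetic chromosome-arm generator with ground truth for every pipeline stage.

The generator emulates the statistical structure of a flow-sorted wheat
chromosome arm as seen by a BAC physical-mapping project, at a configurable
scale (defaults are a 1:10 scale model of a 314 Mb arm):

* restriction-site density gradients along the centromere->telomere axis
  (HindIII denser near the centromere, the fingerprinting enzymes likewise);
* a gene-density gradient rising towards the telomere, with most genes
  organized in small islands of 2-3 genes;
* a partial-digest, size-selected BAC library of configurable purity, with
  contaminating clones drawn from an unlinked decoy chromosome and a small
  fraction of chimeric (two-source) clones;
* noisy four-channel HICF fingerprints;
* three model-grass reference gene orders with per-gene synteny labels, a
  centromere->telomere gradient of non-syntenic genes, and one large inversion
  in the primary reference;
* three-dimensional (plate/row/column) pool hybridization signals for minimal
  tiling path clones.

Every operation draws from its own seeded generator derived from
``config.seed``, so identical configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .fingerprints import Fingerprint, FingerprintSet, ScoreParams, unify_channels

__all__ = [
    "SimulationConfig",
    "Gene",
    "SyntheticChromosome",
    "Clone",
    "CloneLibrary",
    "ReferenceSet",
    "PoolNoise",
    "PoolSignalMatrix",
    "simulate_chromosome",
    "simulate_decoy_chromosome",
    "simulate_clone_library",
    "simulate_fingerprints",
    "simulate_references",
    "simulate_pool_signals",
    "genes_to_clones",
]

#: channel order of the four labeled fingerprinting enzymes
CHANNEL_ENZYMES = ("BamHI", "EcoRI", "XbaI", "XhoI")
#: secondary (unlabeled) frequent cutter that terminates sized fragments
SECONDARY_ENZYME = "HaeIII"
#: enzyme used for library construction (clone ends fall on its sites)
LIBRARY_ENZYME = "HindIII"

#: cytological deletion-bin fractions of the arm, centromere first
BIN_FRACTIONS = (0.33, 0.22, 0.11, 0.10, 0.07, 0.17)


def _default_rates_cen() -> dict[str, float]:
    # sites per 100 kb in the centromeric region; EcoRI and XbaI carry no
    # reported gradient and are held uniform
    return {
        "HaeIII": 422.1,
        "BamHI": 27.2,
        "XhoI": 25.5,
        "EcoRI": 25.0,
        "XbaI": 25.0,
    }


def _default_rates_tel() -> dict[str, float]:
    return {
        "HaeIII": 349.3,
        "BamHI": 20.4,
        "XhoI": 18.9,
        "EcoRI": 25.0,
        "XbaI": 25.0,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic world.

    ``density_ratio_tel_cen`` is the ratio of mean gene density in the
    telomeric fifth of the arm to the centromeric fifth (the measurable
    regional contrast); the underlying linear density is calibrated so the
    fifth averages reproduce this ratio in expectation.
    """

    arm_length_kb: float = 31_400.0
    n_genes: int = 380
    density_ratio_tel_cen: float = 2.36
    island_fraction: float = 0.76
    island_size_range: tuple[int, int] = (2, 3)
    hindiii_rate_cen: float = 50.1
    hindiii_rate_tel: float = 42.8
    fp_enzyme_rates_cen: Mapping[str, float] = field(default_factory=_default_rates_cen)
    fp_enzyme_rates_tel: Mapping[str, float] = field(default_factory=_default_rates_tel)
    insert_mean_kb: float = 113.0
    insert_range_kb: tuple[float, float] = (100.0, 200.0)
    n_clones: int = 4941
    purity: float = 0.81
    contamination_rate: float = 0.02
    band_noise_sd: float = 2.0
    band_dropout: float = 0.05
    # reference / synteny model
    non_syntenic_cen: float = 0.42
    non_syntenic_tel: float = 0.58
    syntenic_retention: tuple[float, float, float] = (0.92, 0.74, 0.72)
    expansion_ratio_tel_cen: float = 2.0
    inversion_fraction: float = 0.15
    shared_inversion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        lo, hi = self.insert_range_kb
        if not (lo <= self.insert_mean_kb <= hi):
            raise ValueError("insert_range_kb must bracket insert_mean_kb")
        if self.density_ratio_tel_cen <= 0:
            raise ValueError("density_ratio_tel_cen must be positive")
        if self.hindiii_rate_cen < 0 or self.hindiii_rate_tel < 0:
            raise ValueError("site rates must be non-negative")
        if any(r < 0 for r in self.fp_enzyme_rates_cen.values()):
            raise ValueError("site rates must be non-negative")
        if self.purity + self.contamination_rate > 1.0 + 1e-12:
            raise ValueError("purity + contamination_rate must not exceed 1")
        if not (0.0 <= self.band_dropout < 1.0):
            raise ValueError("band_dropout must be in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Seeded generator for one operation (one stream per stage)."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass(frozen=True)
class Gene:
    gene_id: str
    position_kb: float
    island_id: int | None


@dataclass
class SyntheticChromosome:
    """Per-enzyme site maps, gene loci and deletion-bin boundaries."""

    site_maps: dict[str, np.ndarray]  # kb positions, sorted, centromere at 0
    genes: list[Gene]
    bin_bounds: np.ndarray  # fractions on [0, 1], first 0, last 1
    arm_length_kb: float

    def __post_init__(self) -> None:
        b = np.asarray(self.bin_bounds, dtype=float)
        if b[0] != 0.0 or b[-1] != 1.0 or np.any(np.diff(b) <= 0):
            raise ValueError("bin bounds must strictly increase from 0 to 1")
        self.bin_bounds = b
        for enz, sites in self.site_maps.items():
            s = np.asarray(sites, dtype=float)
            if s.size and (s[0] < 0 or s[-1] > self.arm_length_kb):
                raise ValueError(f"{enz} sites outside the arm")
            self.site_maps[enz] = s

    @property
    def gene_positions(self) -> np.ndarray:
        return np.array([g.position_kb for g in self.genes])


@dataclass(frozen=True)
class Clone:
    clone_id: str
    source: str  # target | decoy | chimera
    start_kb: float
    end_kb: float
    start2_kb: float | None = None  # secondary interval of a chimera
    end2_kb: float | None = None
    plate: int = 0
    row: int = 0
    column: int = 0

    @property
    def length_kb(self) -> float:
        length = self.end_kb - self.start_kb
        if self.start2_kb is not None:
            length += self.end2_kb - self.start2_kb
        return length


@dataclass
class CloneLibrary:
    clones: list[Clone]
    insert_mean_kb: float

    def __len__(self) -> int:
        return len(self.clones)

    def by_id(self) -> dict[str, Clone]:
        return {c.clone_id: c for c in self.clones}

    @property
    def mean_insert_kb(self) -> float:
        return float(np.mean([c.length_kb for c in self.clones]))


@dataclass
class ReferenceSet:
    """Three reference gene orders with per-gene homology labels.

    ``orders`` maps a reference id to the ordered list of (gene_id,
    position_kb) present in that reference; ``homology`` maps reference id ->
    gene_id -> label in {"syntenic", "non_syntenic", "absent"};
    ``inversion_intervals`` records planted inversions as (first, last)
    gene-id pairs per reference.  ``primary`` names the reference the zipper
    is built from.
    """

    orders: dict[str, list[tuple[str, float]]]
    homology: dict[str, dict[str, str]]
    inversion_intervals: dict[str, list[tuple[str, str]]]
    primary: str = "refA"
    #: (first, last) truth-order genes of a query-lineage inversion, if any
    query_inversion: tuple[str, str] | None = None


@dataclass(frozen=True)
class PoolNoise:
    """Noise model of the pooled-hybridization signals (log2 intensities)."""

    false_positive: float = 0.0019
    false_negative: float = 0.02
    background_mean: float = 8.0
    background_sd: float = 0.5
    signal_mean: float = 11.0
    signal_sd: float = 0.8


@dataclass
class PoolSignalMatrix:
    """Pools x probes matrix of log-intensities."""

    intensities: np.ndarray
    pool_ids: list[str]
    probe_ids: list[str]


# ---------------------------------------------------------------------------
# chromosome


def _endpoint_ratio(fifth_ratio: float) -> float:
    """Endpoint ratio of a linear density whose telomeric-fifth / centromeric-
    fifth mean-density ratio equals ``fifth_ratio``.

    For f(x) = 1 + (R - 1) x on [0, 1] the fifth means sit at x = 0.1 and
    x = 0.9, giving ratio rho = (0.1 + 0.9 R)/(0.9 + 0.1 R); invert for R.
    """
    rho = fifth_ratio
    denom = 0.9 - 0.1 * rho
    if denom <= 0:
        raise ValueError("density ratio too steep for a linear gradient")
    return 1.0 + (rho - 1.0) / denom


def _linear_gradient_sites(
    rng: np.random.Generator, length_kb: float, rate_cen: float, rate_tel: float
) -> np.ndarray:
    """Inhomogeneous Poisson sites with rate (per 100 kb) linear in position."""
    rmax = max(rate_cen, rate_tel)
    if rmax == 0:
        return np.empty(0)
    n = rng.poisson(rmax / 100.0 * length_kb)
    x = rng.uniform(0.0, length_kb, size=n)
    rate_x = rate_cen + (rate_tel - rate_cen) * x / length_kb
    keep = rng.uniform(0.0, rmax, size=n) < rate_x
    return np.sort(x[keep])


def simulate_chromosome(config: SimulationConfig) -> SyntheticChromosome:
    """Generate site maps, gene loci and bin boundaries for one arm.

    Gene density rises linearly from centromere (x=0) to telomere; genes are
    grouped into islands of ``island_size_range`` members placed within one
    mean-insert length of each other, with the remaining singletons drawn
    from the same density gradient.
    """
    rng = config.rng(0)
    length = config.arm_length_kb
    site_maps: dict[str, np.ndarray] = {}
    site_maps[LIBRARY_ENZYME] = _linear_gradient_sites(
        rng, length, config.hindiii_rate_cen, config.hindiii_rate_tel
    )
    for enz in (SECONDARY_ENZYME, *CHANNEL_ENZYMES):
        site_maps[enz] = _linear_gradient_sites(
            rng, length, config.fp_enzyme_rates_cen[enz], config.fp_enzyme_rates_tel[enz]
        )

    genes: list[Gene] = []
    if config.n_genes > 0:
        n_in_islands = int(round(config.island_fraction * config.n_genes))
        if 0 < n_in_islands < 2:
            raise ValueError(
                "island_fraction * n_genes < 2: cannot form any island"
            )
        lo, hi = config.island_size_range
        sizes: list[int] = []
        remaining = n_in_islands
        while remaining >= lo:
            s = int(rng.integers(lo, hi + 1))
            s = min(s, remaining)
            if remaining - s == 1:  # avoid a leftover singleton "island"
                s = remaining
            if s < lo:
                break
            sizes.append(s)
            remaining -= s
        n_in_islands = sum(sizes)
        n_single = config.n_genes - n_in_islands

        n_loci = len(sizes) + n_single
        ratio_end = _endpoint_ratio(config.density_ratio_tel_cen)
        anchors = _gradient_positions(rng, n_loci, length, ratio_end)
        rng.shuffle(anchors)
        island_anchors, single_pos = anchors[: len(sizes)], anchors[len(sizes):]

        positions: list[tuple[float, int | None]] = [
            (float(p), None) for p in single_pos
        ]
        for isl, (anchor, size) in enumerate(zip(island_anchors, sizes)):
            half = 0.5 * config.insert_mean_kb
            offsets = rng.uniform(-half, half, size=size)
            for off in offsets:
                positions.append((float(min(max(anchor + off, 1e-6), length - 1e-6)), isl))
        positions.sort()
        genes = [
            Gene(f"g{i:04d}", pos, isl) for i, (pos, isl) in enumerate(positions)
        ]

    bounds = np.concatenate([[0.0], np.cumsum(BIN_FRACTIONS)])
    bounds[-1] = 1.0
    return SyntheticChromosome(site_maps, genes, bounds, length)


def _gradient_positions(
    rng: np.random.Generator, n: int, length: float, endpoint_ratio: float
) -> np.ndarray:
    """Draw n positions from a linear density with the given endpoint ratio."""
    out = np.empty(n)
    fmax = max(1.0, endpoint_ratio)
    got = 0
    while got < n:
        need = n - got
        x = rng.uniform(0.0, length, size=max(2 * need, 16))
        f = 1.0 + (endpoint_ratio - 1.0) * x / length
        keep = x[rng.uniform(0.0, fmax, size=x.size) < f]
        take = min(need, keep.size)
        out[got : got + take] = keep[:take]
        got += take
    return out


def simulate_decoy_chromosome(config: SimulationConfig) -> SyntheticChromosome:
    """An unlinked chromosome of equal length for contaminating clones.

    Same generative model, distinct seed stream, no genes: decoy clones get
    realistic fingerprints that share no true overlap with target clones.
    """
    decoy_cfg = replace(config, n_genes=0, seed=config.seed)
    rng_stream = 10
    rng = decoy_cfg.rng(rng_stream)
    length = config.arm_length_kb
    site_maps = {
        LIBRARY_ENZYME: _linear_gradient_sites(
            rng, length, config.hindiii_rate_cen, config.hindiii_rate_tel
        )
    }
    for enz in (SECONDARY_ENZYME, *CHANNEL_ENZYMES):
        site_maps[enz] = _linear_gradient_sites(
            rng, length, config.fp_enzyme_rates_cen[enz], config.fp_enzyme_rates_tel[enz]
        )
    bounds = np.concatenate([[0.0], np.cumsum(BIN_FRACTIONS)])
    bounds[-1] = 1.0
    return SyntheticChromosome(site_maps, [], bounds, length)


# ---------------------------------------------------------------------------
# clone library


def _truncated_exp_mean(mu: float, lo: float, hi: float) -> float:
    a, b = lo / mu, hi / mu
    ea, eb = math.exp(-a), math.exp(-b)
    if ea - eb < 1e-300:
        return lo
    return mu + (lo * ea - hi * eb) / (ea - eb)


def _calibrate_insert_scale(mean: float, lo: float, hi: float) -> float:
    """Exponential scale whose [lo, hi]-truncated mean equals ``mean``.

    The partial digest walks past a geometric number of uncut sites, so the
    pre-selection insert length is exponential-like; size selection keeps the
    [lo, hi] window.  We sample directly from the truncated law and calibrate
    its scale so the post-selection mean matches the configured insert mean.
    """
    target = min(max(mean, lo + 1e-6), hi - 1e-6)
    f = lambda mu: _truncated_exp_mean(mu, lo, hi) - target
    return brentq(f, 1e-3, 1e6, xtol=1e-9)


def _sample_truncated_exp(
    rng: np.random.Generator, mu: float, lo: float, hi: float, size: int
) -> np.ndarray:
    u = rng.uniform(size=size)
    ea, eb = math.exp(-lo / mu), math.exp(-hi / mu)
    return -mu * np.log(ea - u * (ea - eb))


def _clone_interval(
    rng: np.random.Generator,
    sites: np.ndarray,
    length_target: float,
    lo: float,
    hi: float,
    max_tries: int = 64,
) -> tuple[float, float]:
    """One partial-digest clone: ends on library-enzyme sites, size-selected."""
    n = sites.size
    if n < 2:
        raise ValueError("HindIII site map too sparse to cut any clone")
    for _ in range(max_tries):
        i = int(rng.integers(0, n - 1))
        left = sites[i]
        j = int(np.searchsorted(sites, left + length_target, side="left"))
        if j >= n:
            continue
        right = sites[j]
        if lo <= right - left <= hi:
            return float(left), float(right)
        # overshoot by one gap: try the previous site
        if j - 1 > i and lo <= sites[j - 1] - left <= hi:
            return float(left), float(sites[j - 1])
    raise ValueError(
        f"no attainable insert in [{lo}, {hi}] kb on this site map"
    )


def simulate_clone_library(
    chrom: SyntheticChromosome,
    config: SimulationConfig,
    decoy: SyntheticChromosome | None = None,
) -> CloneLibrary:
    """Partial-digest, size-selected BAC library with decoys and chimeras.

    Source counts are fixed at ``round(n_clones * purity)`` target clones and
    ``round(n_clones * contamination_rate)`` chimeras, the remainder decoys.
    Chimeric clones concatenate two target intervals separated by at least
    ten insert lengths.  Plate layout is sequential over 384-well plates
    (16 rows x 24 columns).
    """
    sites = chrom.site_maps[LIBRARY_ENZYME]
    if sites.size == 0:
        raise ValueError("HindIII site map is empty")
    rng = config.rng(1)
    lo, hi = config.insert_range_kb
    mu = _calibrate_insert_scale(config.insert_mean_kb, lo, hi)

    n_target = int(round(config.n_clones * config.purity))
    n_chimera = int(round(config.n_clones * config.contamination_rate))
    n_decoy = config.n_clones - n_target - n_chimera
    if n_decoy > 0 and decoy is None:
        decoy = simulate_decoy_chromosome(config)

    clones: list[Clone] = []
    lengths = _sample_truncated_exp(rng, mu, lo, hi, n_target)
    for k in range(n_target):
        s, e = _clone_interval(rng, sites, float(lengths[k]), lo, hi)
        clones.append(Clone("", "target", s, e))
    if n_decoy > 0:
        dsites = decoy.site_maps[LIBRARY_ENZYME]
        lengths = _sample_truncated_exp(rng, mu, lo, hi, n_decoy)
        for k in range(n_decoy):
            s, e = _clone_interval(rng, dsites, float(lengths[k]), lo, hi)
            clones.append(Clone("", "decoy", s, e))
    lengths = _sample_truncated_exp(rng, mu, lo, hi, n_chimera)
    min_sep = 10.0 * config.insert_mean_kb
    for k in range(n_chimera):
        frac = rng.uniform(0.35, 0.65)
        half_lo = max(lo * 0.3, 10.0)
        for _ in range(64):
            s1, e1 = _clone_interval(
                rng, sites, float(lengths[k]) * frac, half_lo, hi
            )
            s2, e2 = _clone_interval(
                rng, sites, float(lengths[k]) * (1 - frac), half_lo, hi
            )
            if abs(s2 - s1) > min_sep:
                break
        clones.append(Clone("", "chimera", s1, e1, s2, e2))

    order = rng.permutation(len(clones))
    placed: list[Clone] = []
    for idx, k in enumerate(order):
        plate, well = divmod(idx, 384)
        row, col = divmod(well, 24)
        c = clones[k]
        placed.append(
            replace(
                c,
                clone_id=f"c{idx:05d}",
                plate=plate + 1,
                row=row,
                column=col + 1,
            )
        )
    return CloneLibrary(placed, config.insert_mean_kb)


# ---------------------------------------------------------------------------
# fingerprints


def _interval_raw_sizes(
    chrom: SyntheticChromosome,
    start: float,
    end: float,
    channel_range: tuple[int, int] = (50, 500),
) -> list[np.ndarray]:
    """Raw fragment sizes (bp) per channel for one genomic interval.

    A sized fragment runs from a labeled-enzyme site to the next cut site of
    any fingerprinting enzyme (or the clone end), and is retained when its
    length falls inside the instrument's calling window.
    """
    union = np.sort(
        np.concatenate(
            [chrom.site_maps[e] for e in (SECONDARY_ENZYME, *CHANNEL_ENZYMES)]
        )
    )
    lo_bp, hi_bp = channel_range
    out: list[np.ndarray] = []
    for enz in CHANNEL_ENZYMES:
        s = chrom.site_maps[enz]
        inside = s[(s >= start) & (s < end)]
        if inside.size == 0:
            out.append(np.empty(0))
            continue
        nxt_idx = np.searchsorted(union, inside, side="right")
        nxt = np.where(
            nxt_idx < union.size, union[np.minimum(nxt_idx, union.size - 1)], end
        )
        nxt = np.minimum(nxt, end)
        sizes_bp = (nxt - inside) * 1000.0
        keep = (sizes_bp >= lo_bp) & (sizes_bp <= hi_bp)
        out.append(sizes_bp[keep])
    return out


def simulate_fingerprints(
    library: CloneLibrary,
    chrom: SyntheticChromosome,
    config: SimulationConfig,
    decoy: SyntheticChromosome | None = None,
    params: ScoreParams = ScoreParams(),
) -> FingerprintSet:
    """HICF fingerprints for every clone, with jitter and dropout.

    Bands derive deterministically from the fragment structure of the clone's
    true interval(s); band-position jitter (sd ``band_noise_sd`` in unified
    band units) and band dropout are then applied.  Chimeras carry bands from
    both intervals; decoys from the decoy chromosome.
    """
    rng = config.rng(2)
    need_decoy = any(c.source == "decoy" for c in library.clones)
    if need_decoy and decoy is None:
        decoy = simulate_decoy_chromosome(config)
    fps = FingerprintSet()
    rng_range = (params.channel_min, params.channel_max)
    for clone in library.clones:
        source_chrom = decoy if clone.source == "decoy" else chrom
        raw = _interval_raw_sizes(
            source_chrom, clone.start_kb, clone.end_kb, rng_range
        )
        if clone.start2_kb is not None:
            raw2 = _interval_raw_sizes(
                chrom, clone.start2_kb, clone.end2_kb, rng_range
            )
            raw = [np.concatenate([a, b]) for a, b in zip(raw, raw2)]
        bands = unify_channels(raw, params)
        if config.band_noise_sd > 0 and bands.size:
            jitter = np.round(
                rng.normal(0.0, config.band_noise_sd, size=bands.size)
            ).astype(np.int64)
            bands = np.clip(bands + jitter, 0, params.gel_length)
        if config.band_dropout > 0 and bands.size:
            keep = rng.uniform(size=bands.size) >= config.band_dropout
            bands = bands[keep]
        fps.add(Fingerprint(clone.clone_id, np.sort(bands)))
    return fps


# ---------------------------------------------------------------------------
# references


def simulate_references(
    chrom: SyntheticChromosome,
    config: SimulationConfig,
) -> ReferenceSet:
    """Three reference gene orders with synteny labels and one inversion.

    A gene is non-syntenic overall with probability linear in position,
    calibrated so the centromeric and telomeric deletion-bin means equal
    ``non_syntenic_cen`` and ``non_syntenic_tel``.  Overall-syntenic genes
    are retained as syntenic in each reference independently with the
    per-reference retention probabilities.  Non-syntenic genes are either
    relocated to a random reference position or absent (50/50).  Reference
    coordinates contract relative to the arm by a linear expansion gradient
    (the wheat arm expands ``expansion_ratio_tel_cen`` times more per
    reference kb at the telomere than at the centromere).  One inversion
    spanning ``inversion_fraction`` of the syntenic genes is planted in the
    primary reference; with ``shared_inversion`` it is planted in all three
    (emulating an inversion in the query lineage).
    """
    if not chrom.genes:
        raise ValueError("chromosome has no genes")
    rng = config.rng(3)
    genes = sorted(chrom.genes, key=lambda g: g.position_kb)
    L = chrom.arm_length_kb
    bounds = chrom.bin_bounds
    # calibrate linear non-syntenic probability on first/last bin centers
    c_lo = 0.5 * (bounds[0] + bounds[1])
    c_hi = 0.5 * (bounds[-2] + bounds[-1])
    slope = (config.non_syntenic_tel - config.non_syntenic_cen) / (c_hi - c_lo)
    intercept = config.non_syntenic_cen - slope * c_lo

    ref_ids = ("refA", "refB", "refC")
    retention = dict(zip(ref_ids, config.syntenic_retention))

    # reference coordinate of each gene: integrate wheat gaps compressed by
    # the local expansion factor e(x) = 1 + (ratio - 1) x / L
    pos = np.array([g.position_kb for g in genes])
    gaps = np.diff(np.concatenate([[0.0], pos]))
    mid = pos - gaps / 2.0
    # expansion_ratio_tel_cen is the telomeric-bin / centromeric-bin average
    # expansion contrast; derive the endpoint ratio of the linear profile
    rho = config.expansion_ratio_tel_cen
    c_cen = 0.5 * (bounds[0] + bounds[1])
    c_tel = 0.5 * (bounds[-2] + bounds[-1])
    denom = c_tel - rho * c_cen
    r_end = 1.0 + (rho - 1.0) / denom if denom > 0 else rho
    e_local = 1.0 + (r_end - 1.0) * mid / L
    ref_pos = np.cumsum(gaps / e_local)

    homology: dict[str, dict[str, str]] = {r: {} for r in ref_ids}
    entries: dict[str, list[tuple[str, float]]] = {r: [] for r in ref_ids}
    overall_ns = rng.uniform(size=len(genes)) < np.clip(
        intercept + slope * (pos / L), 0.0, 1.0
    )
    for k, g in enumerate(genes):
        for r in ref_ids:
            if overall_ns[k]:
                syntenic = False
            else:
                syntenic = rng.uniform() < retention[r]
            if syntenic:
                homology[r][g.gene_id] = "syntenic"
                entries[r].append((g.gene_id, float(ref_pos[k])))
            elif rng.uniform() < 0.5:
                homology[r][g.gene_id] = "non_syntenic"
                entries[r].append(
                    (g.gene_id, float(rng.uniform(0.0, ref_pos[-1])))
                )
            else:
                homology[r][g.gene_id] = "absent"

    orders = {r: sorted(v, key=lambda t: t[1]) for r, v in entries.items()}

    inversion_intervals: dict[str, list[tuple[str, str]]] = {r: [] for r in ref_ids}
    query_inversion: tuple[str, str] | None = None

    def _reverse_in(r: str, window: set[str]) -> None:
        order = orders[r]
        sel = [
            i
            for i, (gid, _) in enumerate(order)
            if gid in window and homology[r][gid] == "syntenic"
        ]
        ids = [order[i][0] for i in sel]
        for i, gid in zip(sel, reversed(ids)):
            orders[r][i] = (gid, orders[r][i][1])
        if ids:
            inversion_intervals[r].append((ids[-1], ids[0]))

    if config.inversion_fraction > 0:
        if config.shared_inversion:
            # one physical window, inverted in the query lineage: every
            # reference shows the same genes in reversed order
            synt = [g.gene_id for k, g in enumerate(genes) if not overall_ns[k]]
            n_inv = max(2, int(round(config.inversion_fraction * len(synt))))
            if n_inv > len(synt):
                raise ValueError("inversion interval larger than gene count")
            hi = int(round(0.85 * (len(synt) - 1)))
            lo = hi - n_inv + 1
            window = set(synt[lo : hi + 1])
            query_inversion = (synt[lo], synt[hi])
            for r in ref_ids:
                _reverse_in(r, window)
        else:
            # reference-lineage inversion in the primary only (the case a
            # zipper must correct for)
            order = orders["refA"]
            synt_i = [
                i for i, (gid, _) in enumerate(order)
                if homology["refA"][gid] == "syntenic"
            ]
            n_inv = max(2, int(round(config.inversion_fraction * len(synt_i))))
            if n_inv > len(synt_i):
                raise ValueError("inversion interval larger than gene count")
            hi = int(round(0.85 * (len(synt_i) - 1)))
            window = {order[i][0] for i in synt_i[hi - n_inv + 1 : hi + 1]}
            _reverse_in("refA", window)
    out = ReferenceSet(orders, homology, inversion_intervals, primary="refA")
    out.query_inversion = query_inversion
    return out


# ---------------------------------------------------------------------------
# pools


def genes_to_clones(
    chrom: SyntheticChromosome,
    library: CloneLibrary,
    clone_ids: Sequence[str] | None = None,
) -> dict[str, list[str]]:
    """Ground-truth map from gene id to the clones covering its locus."""
    pool = library.clones
    if clone_ids is not None:
        wanted = set(clone_ids)
        pool = [c for c in pool if c.clone_id in wanted]
    out: dict[str, list[str]] = {}
    for g in chrom.genes:
        hits = []
        for c in pool:
            if c.source == "decoy":
                continue
            if c.start_kb <= g.position_kb < c.end_kb:
                hits.append(c.clone_id)
            elif (
                c.start2_kb is not None
                and c.start2_kb <= g.position_kb < c.end2_kb
            ):
                hits.append(c.clone_id)
        out[g.gene_id] = hits
    return out


def simulate_pool_signals(
    library: CloneLibrary,
    mtp_clone_ids: Sequence[str],
    gene_to_clone_truth: Mapping[str, Sequence[str]],
    noise: PoolNoise = PoolNoise(),
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Three-dimensional pool hybridization signals for MTP clones.

    Returns ``(signals, design)`` where the design is built from the
    plate/row/column addresses of the MTP clones.  A pool is truly positive
    for a probe when it contains a clone covering that probe's locus; each
    pool-probe cell then draws its log-intensity from the signal or the
    background component, with per-cell false-positive/false-negative flips.
    """
    from .pools import build_pool_design  # local import avoids a cycle

    if rng is None:
        rng = (config or SimulationConfig()).rng(4)
    by_id = library.by_id()
    for cid in mtp_clone_ids:
        if cid not in by_id:
            raise ValueError(f"MTP clone {cid!r} has no library address")
    design = build_pool_design({cid: by_id[cid] for cid in mtp_clone_ids})
    probe_ids = list(gene_to_clone_truth)
    mtp_set = set(mtp_clone_ids)
    pool_index = {pid: i for i, pid in enumerate(design.pool_ids)}
    clone_pools = design.clone_pools()

    n_pools, n_probes = len(design.pool_ids), len(probe_ids)
    positive = np.zeros((n_pools, n_probes), dtype=bool)
    for j, probe in enumerate(probe_ids):
        for cid in gene_to_clone_truth[probe]:
            if cid not in mtp_set:
                continue
            for pid in clone_pools[cid]:
                positive[pool_index[pid], j] = True

    flip_fp = rng.uniform(size=positive.shape) < noise.false_positive
    flip_fn = rng.uniform(size=positive.shape) < noise.false_negative
    observed = np.where(positive, ~flip_fn, flip_fp)
    intensities = np.where(
        observed,
        rng.normal(noise.signal_mean, noise.signal_sd, size=positive.shape),
        rng.normal(noise.background_mean, noise.background_sd, size=positive.shape),
    )
    signals = PoolSignalMatrix(intensities, list(design.pool_ids), probe_ids)
    return signals, design
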
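"""Synthetic data with known ground truth for every pipeline stage.

This module generates the inputs the analysis modules consume: a pair of
phased parental haplotypes with compartmentalized divergence, 4-spore
tetrads from a single simulated meiosis (configurable CO/NCO rates),
intratetrad matings, mutation-accumulation genealogies (configurable
per-site rate, AT bias, Ts:Tv and mitotic LOH), strain populations for
tree/LD analyses, and per-site read depths with allele-balance noise.

Conventions: coordinates 0-based half-open; parental origin codes are
``0`` (parent 1) and ``1`` (parent 2); every function is deterministic
under a fixed seed (one seeded generator per call).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import CO, NCO, RecombinationEvent
from .genome import DivergenceProfile, GenomeSpec

BASES = ("A", "C", "G", "T")
GC_BASES = frozenset("GC")


def as_rng(seed: "int | np.random.Generator | None") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class LengthDistribution:
    """Tract-length distribution spec: ``constant``, ``geometric`` or ``uniform``.

    Parameters are in bp: ``constant(length)``, ``geometric(mean)``,
    ``uniform(low, high)``.  Samples are always >= 1 bp.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in ("constant", "geometric", "uniform"):
            raise ValueError(f"unknown length distribution {self.family!r}")
        if any(p < 1 for p in self.params):
            raise ValueError("tract lengths must be >= 1 bp")
        n_expected = {"constant": 1, "geometric": 1, "uniform": 2}[self.family]
        if len(self.params) != n_expected:
            raise ValueError(f"{self.family} takes {n_expected} parameter(s)")
        if self.family == "uniform" and self.params[0] > self.params[1]:
            raise ValueError("uniform low > high")

    def sample(self, rng: np.random.Generator) -> int:
        if self.family == "constant":
            return max(1, int(round(self.params[0])))
        if self.family == "geometric":
            return int(rng.geometric(1.0 / self.params[0]))
        low, high = self.params
        return int(rng.integers(int(low), int(high) + 1))


@dataclass
class ParentalPair:
    """Two phased haploid parents: SNP positions and their allele pairs.

    ``positions[chrom]`` is strictly increasing (0-based); ``alleles[chrom]``
    has shape ``(n, 2)`` holding the parent-1 and parent-2 base at each
    position (always distinct).
    """

    genome: GenomeSpec
    positions: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = self.genome.chrom_lengths
        for chrom, pos in self.positions.items():
            if chrom not in lengths:
                raise ValueError(f"SNPs on unknown chromosome {chrom!r}")
            pos = np.asarray(pos, dtype=np.int64)
            self.positions[chrom] = pos
            if pos.size and (pos[0] < 0 or pos[-1] >= lengths[chrom]):
                raise ValueError(f"SNP position out of bounds on {chrom!r}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on {chrom!r}")
            alle = np.asarray(self.alleles[chrom])
            if alle.shape != (pos.size, 2):
                raise ValueError(f"allele array shape mismatch on {chrom!r}")
            if np.any(alle[:, 0] == alle[:, 1]):
                raise ValueError(f"identical parental alleles at a marker on {chrom!r}")

    @property
    def n_snps(self) -> int:
        return sum(int(p.size) for p in self.positions.values())


def _sample_positions_without_replacement(
    rng: np.random.Generator, n: int, pool_size: int
) -> np.ndarray:
    """Uniform draw of *n* distinct integers from ``[0, pool_size)``."""
    if n >= pool_size:
        return np.arange(pool_size, dtype=np.int64)
    if n > pool_size // 10:
        return rng.permutation(pool_size)[:n].astype(np.int64)
    # rejection sampling for sparse draws: avoids materializing the pool
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(0, pool_size, size=n - len(chosen))
        chosen.update(int(x) for x in draw)
    return np.fromiter(chosen, dtype=np.int64, count=n)


def simulate_parent_pair(
    genome: GenomeSpec,
    profile: DivergenceProfile,
    seed: "int | np.random.Generator | None" = None,
    exclude_masked: bool = True,
) -> ParentalPair:
    """Draw a ParentalPair under a compartmentalized divergence profile.

    Within each compartment the SNP count is Binomial(number of eligible
    sites, rate) and positions are uniform without replacement.  With
    ``exclude_masked`` (default) repeat-masked sites are ineligible, so
    the stated per-site rate applies to the callable fraction.
    """
    profile.validate(genome)
    rng = as_rng(seed if seed is not None else genome.seed)
    positions: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        chrom_pos: list[np.ndarray] = []
        callable_ivals = genome.callable_intervals(chrom) if exclude_masked else [(0, length)]
        for (start, end), rate in sorted(profile.compartments[chrom]):
            # eligible sites: compartment intersected with callable intervals
            sub = [(max(s, start), min(e, end)) for s, e in callable_ivals
                   if min(e, end) > max(s, start)]
            pool = sum(e - s for s, e in sub)
            if pool == 0 or rate == 0.0:
                continue
            n = int(rng.binomial(pool, rate))
            if n == 0:
                continue
            offsets = np.sort(_sample_positions_without_replacement(rng, n, pool))
            # map pooled offsets back to genomic coordinates
            mapped = np.empty(n, dtype=np.int64)
            cursor = 0
            for s, e in sub:
                width = e - s
                sel = (offsets >= cursor) & (offsets < cursor + width)
                mapped[sel] = offsets[sel] - cursor + s
                cursor += width
            chrom_pos.append(mapped)
        pos = np.sort(np.concatenate(chrom_pos)) if chrom_pos else np.empty(0, dtype=np.int64)
        positions[chrom] = pos
        # parent-1 base follows genome composition; parent-2 uniform among the rest
        gc = genome.gc_content
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        ref_idx = rng.choice(4, size=pos.size, p=p)
        alt_shift = rng.integers(1, 4, size=pos.size)
        alt_idx = (ref_idx + alt_shift) % 4
        base_arr = np.array(BASES)
        alleles[chrom] = np.stack([base_arr[ref_idx], base_arr[alt_idx]], axis=1)
    return ParentalPair(genome=genome, positions=positions, alleles=alleles)


@dataclass(frozen=True)
class MeiosisParams:
    """Rates and tract-length model for one simulated meiosis.

    ``co_rate`` and ``nco_rate`` are expected events per chromosome per
    meiosis (Poisson); ``tract_length`` governs NCO conversion tracts
    (defaults to a geometric with 1.5 kb mean, the short-tract regime of
    budding yeasts); ``obligate_co`` rejects chromosomes with zero COs.
    """

    co_rate: float = 0.0
    nco_rate: float = 0.0
    tract_length: LengthDistribution = LengthDistribution("geometric", (1500.0,))
    obligate_co: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.co_rate < 0 or self.nco_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.obligate_co and self.co_rate == 0:
            raise ValueError("obligate_co requires co_rate > 0")


@dataclass
class TetradTruth:
    """Ground truth of one meiosis: spore origin vectors plus exact events.

    ``spore_origins[chrom]`` has shape ``(4, n_markers)`` with values
    0/1 (parental origin).  Spores 0,1 are meiosis-II sisters from one
    meiosis-I pole; spores 2,3 from the other: non-sister pairs are
    exactly the cross-pole pairs.
    """

    pair: ParentalPair
    spore_origins: dict[str, np.ndarray]
    true_events: list[RecombinationEvent] = field(default_factory=list)

    SISTER_PAIRS = ((0, 1), (2, 3))
    NON_SISTER_PAIRS = ((0, 2), (0, 3), (1, 2), (1, 3))


def simulate_tetrad(
    pair: ParentalPair,
    params: MeiosisParams,
    seed: "int | np.random.Generator | None" = None,
) -> TetradTruth:
    """One meiosis: 4 chromatids, Poisson CO/NCO placement, 2+2 segregation.

    Each CO is a reciprocal exchange of everything distal to a continuous
    breakpoint between one chromatid of each homolog; each NCO converts a
    tract on one recipient chromatid to the opposite homolog's alleles.
    Chromatids segregate by centromere origin at meiosis I (spores 0,1
    vs 2,3), then randomly at meiosis II.
    """
    rng = as_rng(seed if seed is not None else params.seed)
    spore_origins: dict[str, np.ndarray] = {}
    truth: list[RecombinationEvent] = []
    for chrom, length in pair.genome.chromosomes:
        pos = pair.positions[chrom]
        n = pos.size
        # chromatids 0,1 copy parent 1; 2,3 copy parent 2
        origins = np.zeros((4, n), dtype=np.int8)
        origins[2:, :] = 1
        cen = pair.genome.centromere(chrom)
        cen_origin = [0, 0, 1, 1]
        chrom_events: list[tuple[RecombinationEvent, tuple[int, ...]]] = []

        n_co = int(rng.poisson(params.co_rate))
        if params.obligate_co:
            while n_co == 0:
                n_co = int(rng.poisson(params.co_rate))
        for x in np.sort(rng.uniform(0.0, float(length), size=n_co)):
            c1 = int(rng.integers(0, 2))
            c2 = 2 + int(rng.integers(0, 2))
            distal = pos > x
            tmp = origins[c1, distal].copy()
            origins[c1, distal] = origins[c2, distal]
            origins[c2, distal] = tmp
            if cen > x:
                cen_origin[c1], cen_origin[c2] = cen_origin[c2], cen_origin[c1]
            ev = RecombinationEvent(kind=CO, chromosome=chrom, inner_start=x, inner_end=x,
                                    n_markers=0)
            chrom_events.append((ev, (c1, c2)))

        n_nco = int(rng.poisson(params.nco_rate))
        for _ in range(n_nco):
            tract_len = params.tract_length.sample(rng)
            u = float(rng.uniform(0.0, float(length)))
            v = min(u + tract_len, float(length))
            recipient = int(rng.integers(0, 4))
            donor = 1 - (0 if recipient < 2 else 1)
            mask = (pos >= u) & (pos < v)
            origins[recipient, mask] = donor
            ev = RecombinationEvent(kind=NCO, chromosome=chrom, inner_start=u, inner_end=v,
                                    n_markers=int(mask.sum()))
            chrom_events.append((ev, (recipient,)))

        # meiosis I: split by centromere origin; meiosis II: random order within pole
        pole = int(rng.integers(0, 2))
        cell1 = [c for c in range(4) if cen_origin[c] == pole]
        cell2 = [c for c in range(4) if cen_origin[c] != pole]
        rng.shuffle(cell1)
        rng.shuffle(cell2)
        order = cell1 + cell2
        spore_of = {chromatid: spore for spore, chromatid in enumerate(order)}
        spore_origins[chrom] = origins[order]
        for ev, chromatids in chrom_events:
            ev.spores = tuple(sorted(spore_of[c] for c in chromatids))
            truth.append(ev)
    return TetradTruth(pair=pair, spore_origins=spore_origins, true_events=truth)


@dataclass
class DiploidGenotype:
    """A fused diploid from two spores: per-marker origin pairs.

    ``origins[chrom]`` has shape ``(n, 2)`` with the two parental-origin
    codes at each marker; a marker is heterozygous iff they differ.
    """

    spore_pair: tuple[int, int]
    origins: dict[str, np.ndarray]

    def het_mask(self, chrom: str) -> np.ndarray:
        o = self.origins[chrom]
        return o[:, 0] != o[:, 1]

    def het_fraction(self) -> float:
        total = sum(o.shape[0] for o in self.origins.values())
        if total == 0:
            return float("nan")
        het = sum(int(self.het_mask(c).sum()) for c in self.origins)
        return het / total


def intratetrad_mate(
    truth: TetradTruth,
    mode: str = "non-sister",
    seed: "int | np.random.Generator | None" = None,
) -> DiploidGenotype:
    """Fuse two spores of one tetrad: ``non-sister`` pairs cross meiosis-I poles.

    Non-sister intratetrad mating of an achiasmate tetrad restores
    heterozygosity at every marker (each chromosome recovers one chromatid
    of each homolog); sister mating yields complete homozygosity.
    """
    rng = as_rng(seed)
    if mode == "non-sister":
        pairs = TetradTruth.NON_SISTER_PAIRS
    elif mode == "sister":
        pairs = TetradTruth.SISTER_PAIRS
    else:
        raise ValueError(f"unknown mating mode {mode!r}")
    a, b = pairs[int(rng.integers(0, len(pairs)))]
    origins = {
        chrom: np.stack([mat[a], mat[b]], axis=1)
        for chrom, mat in truth.spore_origins.items()
    }
    return DiploidGenotype(spore_pair=(a, b), origins=origins)


# ---------------------------------------------------------------------------
# mutation accumulation


FOUNDER_ZYGOSITIES = ("homozygous-haploid", "homozygous-diploid", "heterozygous-diploid")


@dataclass(frozen=True)
class MAParams:
    """Mutation-accumulation genealogy parameters.

    ``mu`` is the per-site per-generation base-substitution rate;
    ``at_bias`` the ratio of per-site GC->AT to AT->GC rates; ``ts_tv``
    the expected transition:transversion ratio; ``loh_rate`` (relevant
    for heterozygous founders) is LOH events per line per generation.
    """

    mu: float
    n_lines: int
    generations: int
    founder_zygosity: str = "homozygous-haploid"
    at_bias: float = 3.6
    ts_tv: float = 1.21
    loh_rate: float = 0.0
    loh_length: LengthDistribution = LengthDistribution("geometric", (10_000.0,))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mu < 0 or self.at_bias < 0 or self.ts_tv < 0 or self.loh_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_lines < 1 or self.generations < 1:
            raise ValueError("n_lines and generations must be >= 1")
        if self.founder_zygosity not in FOUNDER_ZYGOSITIES:
            raise ValueError(f"unknown founder zygosity {self.founder_zygosity!r}")

    @property
    def ploidy(self) -> int:
        return 1 if self.founder_zygosity == "homozygous-haploid" else 2


@dataclass
class TrueSNM:
    """A simulated line-exclusive single-nucleotide mutation."""

    line: int
    chromosome: str
    position: int
    ref: str
    alt: str
    zygosity_change: str  # "hom->hom" or "hom->het"

    @property
    def from_gc(self) -> bool:
        return self.ref in GC_BASES

    @property
    def to_at(self) -> bool:
        return self.alt not in GC_BASES


@dataclass
class TrueLOH:
    """A simulated mitotic LOH tract: founder-het markers made homozygous."""

    line: int
    chromosome: str
    start: float
    end: float
    retained: int  # parental origin kept (0/1)


@dataclass
class MAGenealogy:
    """Simulated MA lines with their true mutations and LOH tracts."""

    genome: GenomeSpec
    params: MAParams
    snms: list[TrueSNM]
    loh_tracts: list[TrueLOH]
    founder_pair: ParentalPair | None = None

    def snms_of_line(self, line: int) -> list[TrueSNM]:
        return [m for m in self.snms if m.line == line]


def substitution_probabilities(gc: float, at_bias: float, ts_tv: float) -> dict[tuple[str, str], float]:
    """Joint probability of each directed substitution type for one mutation.

    Built from per-site rates: GC sites mutate to AT at ``at_bias`` times
    the per-site rate of the reverse flux, and the transition weight is
    solved so the expected Ts:Tv over all mutations equals ``ts_tv``.
    GC<->GC and AT<->AT transversions have unit weight.
    """
    b = at_bias
    at = 1.0 - gc
    denom = gc * b + at
    if denom <= 0:
        raise ValueError("degenerate composition")
    kappa = ts_tv * (gc * (b + 1.0) + 2.0 * at) / denom
    # weights per directed type, ref base drawn from composition
    w: dict[tuple[str, str], float] = {}
    for ref, comp in (("G", gc / 2), ("C", gc / 2)):
        ts_alt = "A" if ref == "G" else "T"       # transition, to AT
        tv_at = "T" if ref == "G" else "A"        # transversion, to AT
        tv_gc = "C" if ref == "G" else "G"        # transversion, within GC
        w[(ref, ts_alt)] = comp * b * kappa
        w[(ref, tv_at)] = comp * b
        w[(ref, tv_gc)] = comp * 1.0
    for ref, comp in (("A", at / 2), ("T", at / 2)):
        ts_alt = "G" if ref == "A" else "C"       # transition, to GC
        tv_gc = "C" if ref == "A" else "G"        # transversion, to GC
        tv_at = "T" if ref == "A" else "A"        # transversion, within AT
        w[(ref, ts_alt)] = comp * kappa
        w[(ref, tv_gc)] = comp * 1.0
        w[(ref, tv_at)] = comp * 1.0
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def simulate_ma_genealogy(
    genome: GenomeSpec,
    params: MAParams,
    founder_pair: ParentalPair | None = None,
    seed: "int | np.random.Generator | None" = None,
) -> MAGenealogy:
    """Simulate MA lines: Poisson mutation counts, AT/Ts:Tv-shaped spectra, LOH.

    Per line the mutation count is Poisson(mu x callable_sites x ploidy x
    generations); each mutation's type is drawn from
    :func:`substitution_probabilities` and its position uniformly over
    callable sites.  Heterozygous-diploid founders require a
    ``founder_pair`` (the het map) and additionally receive LOH tracts at
    ``loh_rate`` per generation.
    """
    rng = as_rng(seed if seed is not None else params.seed)
    if params.founder_zygosity == "heterozygous-diploid" and founder_pair is None:
        raise ValueError("heterozygous-diploid founder requires a ParentalPair het map")
    probs = substitution_probabilities(genome.gc_content, params.at_bias, params.ts_tv)
    types = list(probs)
    pvals = np.array([probs[t] for t in types])
    chrom_names = [c for c, _ in genome.chromosomes]
    callable_lens = np.array(
        [sum(e - s for s, e in genome.callable_intervals(c)) for c in chrom_names], dtype=float
    )
    chrom_p = callable_lens / callable_lens.sum()
    mean_muts = params.mu * genome.callable_sites * params.ploidy * params.generations
    zyg = "hom->hom" if params.ploidy == 1 else "hom->het"

    snms: list[TrueSNM] = []
    loh_tracts: list[TrueLOH] = []
    for line in range(params.n_lines):
        n_mut = int(rng.poisson(mean_muts))
        if n_mut:
            type_idx = rng.choice(len(types), size=n_mut, p=pvals)
            chrom_idx = rng.choice(len(chrom_names), size=n_mut, p=chrom_p)
            for ti, ci in zip(type_idx, chrom_idx):
                chrom = chrom_names[ci]
                ivals = genome.callable_intervals(chrom)
                widths = np.array([e - s for s, e in ivals], dtype=float)
                k = int(rng.choice(len(ivals), p=widths / widths.sum()))
                pos = int(rng.integers(ivals[k][0], ivals[k][1]))
                ref, alt = types[ti]
                snms.append(TrueSNM(line=line, chromosome=chrom, position=pos,
                                    ref=ref, alt=alt, zygosity_change=zyg))
        if params.founder_zygosity == "heterozygous-diploid" and params.loh_rate > 0:
            n_loh = int(rng.poisson(params.loh_rate * params.generations))
            lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
            for _ in range(n_loh):
                ci = int(rng.choice(len(chrom_names), p=lengths / lengths.sum()))
                chrom = chrom_names[ci]
                L = genome.chrom_lengths[chrom]
                tract_len = params.loh_length.sample(rng)
                u = float(rng.uniform(0.0, float(L)))
                v = min(u + tract_len, float(L))
                loh_tracts.append(TrueLOH(line=line, chromosome=chrom, start=u, end=v,
                                          retained=int(rng.integers(0, 2))))
    return MAGenealogy(genome=genome, params=params, snms=snms,
                       loh_tracts=loh_tracts, founder_pair=founder_pair)


def simulate_depths(
    genotypes: np.ndarray,
    mean_depth: float,
    error_rate: float = 0.0,
    seed: "int | np.random.Generator | None" = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (ref_depth, alt_depth) for coded genotypes 0/1/2.

    Total depth is Poisson(mean_depth); alt reads are Binomial(depth, p)
    with p = error, 0.5, 1-error for hom-ref, het, hom-alt.  Cells coded
    negative (missing) get zero depth.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = as_rng(seed)
    g = np.asarray(genotypes)
    depth = rng.poisson(mean_depth, size=g.shape)
    p_alt = np.where(g == 1, 0.5, np.where(g >= 2, 1.0 - error_rate, error_rate))
    alt = rng.binomial(depth, p_alt)
    alt = np.where(g < 0, 0, alt)
    depth = np.where(g < 0, 0, depth)
    return (depth - alt).astype(np.int64), alt.astype(np.int64)


# ---------------------------------------------------------------------------
# strain populations for tree-concordance and LD analyses


def simulate_population(
    n_strains: int,
    genome: GenomeSpec,
    snp_density: float = 1e-3,
    n_genealogies: int = 1,
    recombination_rate: float = 0.0,
    chromosome_genealogy: dict[str, int] | None = None,
    seed: "int | np.random.Generator | None" = None,
):
    """Haploid strain genotypes from latent clonal genealogies.

    Each genealogy is a random unrooted topology over the strains; every
    site takes a random bipartition (clade) of its genealogy as its
    allele-sharing pattern.  With one genealogy and zero recombination
    all sites share one history (flat LD, concordant trees). A positive
    ``recombination_rate`` (per bp) switches the active genealogy along
    each chromosome as a Markov process, decoupling distant sites.
    ``chromosome_genealogy`` pins whole chromosomes to a given genealogy
    index.  Returns a :class:`achiasma.trees.GenotypeMatrix` plus the
    per-site genealogy assignment (ground truth).
    """
    from .trees import GenotypeMatrix, random_topology  # deferred: avoid cycle

    if n_strains < 4:
        raise ValueError("need >= 4 strains")
    if n_genealogies < 1:
        raise ValueError("need >= 1 genealogy")
    rng = as_rng(seed)
    strains = [f"strain{i:02d}" for i in range(n_strains)]
    genealogies = [random_topology(strains, rng) for _ in range(n_genealogies)]
    splits_per_gen = [g.nontrivial_splits() for g in genealogies]

    chroms, positions, dosage_cols, assignment = [], [], [], []
    for chrom, length in genome.chromosomes:
        n_sites = int(rng.binomial(length, snp_density))
        if n_sites == 0:
            continue
        pos = np.sort(_sample_positions_without_replacement(rng, n_sites, length))
        if chromosome_genealogy and chrom in chromosome_genealogy:
            gidx = np.full(n_sites, chromosome_genealogy[chrom] % n_genealogies)
        elif recombination_rate > 0 and n_genealogies > 1:
            gidx = np.empty(n_sites, dtype=np.int64)
            gidx[0] = rng.integers(0, n_genealogies)
            for i in range(1, n_sites):
                gap = float(pos[i] - pos[i - 1])
                if rng.random() < 1.0 - math.exp(-recombination_rate * gap):
                    gidx[i] = rng.integers(0, n_genealogies)
                else:
                    gidx[i] = gidx[i - 1]
        else:
            gidx = np.zeros(n_sites, dtype=np.int64)
        for i in range(n_sites):
            splits = splits_per_gen[int(gidx[i])]
            clade = splits[int(rng.integers(0, len(splits)))]
            if rng.random() < 0.5:  # random orientation of the derived allele
                clade = frozenset(strains) - clade
            dosages = np.fromiter((2 if s in clade else 0 for s in strains),
                                  dtype=np.int8, count=n_strains)
            chroms.append(chrom)
            positions.append(int(pos[i]))
            dosage_cols.append(dosages)
            assignment.append(int(gidx[i]))
    gm = GenotypeMatrix(
        samples=strains,
        chromosomes=np.array(chroms),
        positions=np.array(positions, dtype=np.int64),
        dosages=np.array(dosage_cols, dtype=np.int8)
        if dosage_cols else np.empty((0, n_strains), dtype=np.int8),
    )
    return gm, np.array(assignment, dtype=np.int64)


# ---------------------------------------------------------------------------
# bridging simulated genealogies to the variant-call representation


def ma_sites(genealogy: MAGenealogy):
    """Joint genotypes of founder + lines at every informative site.

    Yields ``(chrom, pos, ref, alt, {sample: gt_tuple})`` sorted by
    position, covering founder-het sites (with LOH applied) and true SNM
    sites; sample names are ``founder`` then ``line00``.. in order.
    """
    params = genealogy.params
    lines = [f"line{i:02d}" for i in range(params.n_lines)]
    ploidy = params.ploidy
    sites: dict[tuple[str, int], tuple[str, str, dict[str, tuple]]] = {}

    if params.founder_zygosity == "heterozygous-diploid":
        pair = genealogy.founder_pair
        loh_by_line: dict[int, list[TrueLOH]] = {}
        for tr in genealogy.loh_tracts:
            loh_by_line.setdefault(tr.line, []).append(tr)
        for chrom, _ in genealogy.genome.chromosomes:
            for pos, (a1, a2) in zip(pair.positions[chrom], pair.alleles[chrom]):
                gts = {"founder": (0, 1)}
                for li, line in enumerate(lines):
                    gt = (0, 1)
                    for tr in loh_by_line.get(li, []):
                        if tr.chromosome == chrom and tr.start <= pos < tr.end:
                            gt = (0, 0) if tr.retained == 0 else (1, 1)
                            break
                    gts[line] = gt
                sites[(chrom, int(pos))] = (str(a1), str(a2), gts)

    for snm in genealogy.snms:
        key = (snm.chromosome, snm.position)
        if key in sites:
            continue  # SNM colliding with a founder-het site: negligible, skipped
        gt_ref = (0,) * ploidy
        gt_mut = (1,) if ploidy == 1 else (0, 1)
        gts = {"founder": gt_ref}
        for li, line in enumerate(lines):
            gts[line] = gt_mut if li == snm.line else gt_ref
        sites[key] = (snm.ref, snm.alt, gts)

    for (chrom, pos), (ref, alt, gts) in sorted(sites.items()):
        yield chrom, pos, ref, alt, gts


def ma_site_calls(
    genealogy: MAGenealogy,
    mean_depth: float = 50.0,
    error_rate: float = 0.0,
    seed: "int | np.random.Generator | None" = None,
):
    """SiteCall records (with simulated depths) for a MA genealogy."""
    from .markers import SampleCall, SiteCall

    rng = as_rng(seed)
    ploidy = genealogy.params.ploidy
    sites = list(ma_sites(genealogy))
    if not sites:
        return []
    sample_names = list(sites[0][4])
    g = np.empty((len(sites), len(sample_names)), dtype=np.int8)
    for i, (_, _, _, _, gts) in enumerate(sites):
        for j, name in enumerate(sample_names):
            code = sum(1 for a in gts[name] if a != 0)
            g[i, j] = (0 if code == 0 else 2) if ploidy == 1 else code
    ref_d, alt_d = simulate_depths(g, mean_depth, error_rate, rng)
    out = []
    for i, (chrom, pos, ref, alt, gts) in enumerate(sites):
        samples = {
            name: SampleCall(
                ref_depth=int(ref_d[i, j]),
                alt_depth=int(alt_d[i, j]),
                genotype="/".join(str(a) for a in gts[name]),
            )
            for j, name in enumerate(sample_names)
        }
        out.append(SiteCall(chromosome=chrom, position=pos + 1, ref=ref,
                            alts=(alt,), samples=samples))
    return out
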
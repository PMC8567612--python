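"""Genome metadata: chromosome sizes, base composition, repeat masks.

All coordinates are 0-based, half-open.  1-based coordinates appear only at
VCF/TSV boundaries (see :mod:`achiasma.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


Interval = tuple[int, int]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths, GC content and repeat-masked intervals.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    gc_content:
        Genome-wide G+C fraction, used to draw reference bases and to
        compute callable base composition.
    masked_intervals:
        Per-chromosome half-open intervals excluded from analysis
        (repeats). Must lie within bounds and not overlap.
    centromeres:
        Optional per-chromosome centromere position; defaults to the
        chromosome midpoint. Determines which chromatids co-segregate at
        meiosis I in the tetrad simulator.
    seed:
        Default seed for simulations that receive this genome and no
        explicit seed of their own.
    """

    chromosomes: tuple[tuple[str, int], ...]
    gc_content: float = 0.296
    masked_intervals: dict[str, list[Interval]] = field(default_factory=dict)
    centromeres: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        lengths = dict(self.chromosomes)
        for chrom, ivals in self.masked_intervals.items():
            if chrom not in lengths:
                raise ValueError(f"masked intervals on unknown chromosome {chrom!r}")
            prev_end = -1
            for start, end in sorted(ivals):
                if not (0 <= start < end <= lengths[chrom]):
                    raise ValueError(f"masked interval ({start}, {end}) out of bounds on {chrom!r}")
                if start < prev_end:
                    raise ValueError(f"overlapping masked intervals on {chrom!r}")
                prev_end = end
            self.masked_intervals[chrom] = sorted(ivals)
        for chrom, pos in self.centromeres.items():
            if chrom not in lengths:
                raise ValueError(f"centromere on unknown chromosome {chrom!r}")
            if not 0 <= pos <= lengths[chrom]:
                raise ValueError(f"centromere position {pos} out of bounds on {chrom!r}")
        if self.callable_sites <= 0:
            raise ValueError("no callable sites left after masking")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @property
    def masked_length(self) -> int:
        return sum(e - s for ivals in self.masked_intervals.values() for s, e in ivals)

    @property
    def callable_sites(self) -> int:
        return self.total_length - self.masked_length

    def centromere(self, chrom: str) -> int:
        return self.centromeres.get(chrom, self.chrom_lengths[chrom] // 2)

    def callable_intervals(self, chrom: str) -> list[Interval]:
        """Half-open intervals of *chrom* not covered by the repeat mask."""
        length = self.chrom_lengths[chrom]
        out: list[Interval] = []
        cursor = 0
        for start, end in self.masked_intervals.get(chrom, []):
            if start > cursor:
                out.append((cursor, start))
            cursor = end
        if cursor < length:
            out.append((cursor, length))
        return out

    def composition(self) -> tuple[float, float]:
        """Callable (N_GC, N_AT) base counts implied by ``gc_content``."""
        n = self.callable_sites
        return n * self.gc_content, n * (1.0 - self.gc_content)


@dataclass(frozen=True)
class DivergenceProfile:
    """Per-site divergence rate in compartments tiling each chromosome.

    The hybrid genome studied here is compartmentalized: somewhat less
    than half of it diverges at ~3.3% between the two parental
    haplotypes while the rest sits near 0.2%.  ``compartments`` maps each
    chromosome to ``((start, end), rate)`` entries that tile the
    chromosome without gaps or overlap.
    """

    compartments: dict[str, list[tuple[Interval, float]]]

    def validate(self, genome: GenomeSpec) -> None:
        lengths = genome.chrom_lengths
        if set(self.compartments) != set(lengths):
            raise ValueError("profile chromosomes do not match genome")
        for chrom, comps in self.compartments.items():
            cursor = 0
            for (start, end), rate in sorted(comps):
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"divergence rate {rate} outside [0, 1]")
                if start != cursor:
                    raise ValueError(f"compartments do not tile {chrom!r} (gap/overlap at {start})")
                cursor = end
            if cursor != lengths[chrom]:
                raise ValueError(f"compartments do not tile {chrom!r} (end at {cursor})")

    @classmethod
    def uniform(cls, genome: GenomeSpec, rate: float) -> "DivergenceProfile":
        return cls({c: [((0, l), rate)] for c, l in genome.chromosomes})

    @classmethod
    def two_rate(
        cls,
        genome: GenomeSpec,
        high_rate: float = 0.033,
        low_rate: float = 0.002,
        high_fraction: float = 0.446,
    ) -> "DivergenceProfile":
        """Split every chromosome into a high- and a low-divergence block.

        The first ``high_fraction`` of each chromosome diverges at
        ``high_rate``, the remainder at ``low_rate``; defaults follow the
        observed hybrid structure (3.3% over 44.6% of the genome, 0.2%
        elsewhere).
        """
        comps = {}
        for chrom, length in genome.chromosomes:
            cut = int(round(length * high_fraction))
            cut = min(max(cut, 0), length)
            entries = []
            if cut > 0:
                entries.append(((0, cut), high_rate))
            if cut < length:
                entries.append(((cut, length), low_rate))
            comps[chrom] = entries
        return cls(comps)


def study_genome(scale: float = 1.0, seed: int | None = None) -> GenomeSpec:
    """A genome shaped like the 12.5-Mb, 7-chromosome study assembly.

    ``scale`` shrinks every chromosome proportionally (tests and examples
    use scaled-down genomes); ~7% of each chromosome is repeat-masked as
    a single interval in the middle, and GC content is 0.296.
    """
    # chromosome sizes roughly proportional to a 7-chromosome 12.5-Mb karyotype,
    # with chrA the largest (~25% of the genome)
    fractions = {"chrA": 0.25, "chrB": 0.18, "chrC": 0.15, "chrD": 0.13,
                 "chrE": 0.11, "chrF": 0.10, "chrG": 0.08}
    total = int(12_500_000 * scale)
    chroms = tuple((name, max(1, int(total * f))) for name, f in fractions.items())
    masked = {}
    for name, length in chroms:
        span = int(length * 0.07)
        if span >= 1:
            mid = length // 2
            masked[name] = [(mid - span // 2, mid - span // 2 + span)]
    return GenomeSpec(chromosomes=chroms, gc_content=0.296, masked_intervals=masked, seed=seed)
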
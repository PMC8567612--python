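"""File-format boundaries: VCF (pysam), BED, marker/truth TSV.

All internal coordinates are 0-based half-open; positions become
1-based in VCF and TSV files and the BED columns stay 0-based half-open
as the format demands.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .events import RecombinationEvent
from .genome import GenomeSpec
from .markers import SampleCall, SiteCall
from .simulate import MAGenealogy, ParentalPair, TetradTruth, as_rng, simulate_depths
from .trees import GenotypeMatrix


# ---------------------------------------------------------------------------
# reading


def read_site_calls(path, samples: Sequence[str] | None = None) -> list[SiteCall]:
    """Parse a VCF into SiteCall records (GT and AD per sample)."""
    out: list[SiteCall] = []
    with pysam.VariantFile(str(path)) as vf:
        names = list(samples) if samples else list(vf.header.samples)
        for rec in vf:
            calls: dict[str, SampleCall] = {}
            for name in names:
                sd = rec.samples[name]
                ad = sd.get("AD")
                ref_d, alt_d = 0, 0
                if ad is not None and len(ad) >= 1 and ad[0] is not None:
                    ref_d = int(ad[0])
                    alt_d = int(sum(x for x in ad[1:] if x is not None))
                gt = sd.get("GT")
                gt_str = None
                if gt is not None and not all(a is None for a in gt):
                    gt_str = "/".join("." if a is None else str(a) for a in gt)
                calls[name] = SampleCall(ref_depth=ref_d, alt_depth=alt_d, genotype=gt_str)
            out.append(SiteCall(
                chromosome=rec.contig,
                position=rec.pos,  # pysam .pos is 1-based
                ref=rec.ref,
                alts=tuple(rec.alts or ()),
                samples=calls,
            ))
    return out


def genotype_matrix_from_vcf(path) -> GenotypeMatrix:
    """Biallelic sites -> alt-dosage matrix (multiallelic sites skipped)."""
    chroms, positions, rows = [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if not rec.alts or len(rec.alts) != 1:
                continue
            dosages = []
            for name in samples:
                gt = rec.samples[name].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages.append(-1)
                else:
                    dosages.append(int(sum(1 for a in gt if a != 0)))
            chroms.append(rec.contig)
            positions.append(rec.pos - 1)
            rows.append(dosages)
    return GenotypeMatrix(
        samples=samples,
        chromosomes=np.array(chroms),
        positions=np.array(positions, dtype=np.int64),
        dosages=np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8),
    )


def read_mask_bed(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.setdefault(chrom, []).append((int(start), int(end)))
    return {c: sorted(v) for c, v in out.items()}


# ---------------------------------------------------------------------------
# writing


def _vcf_header(genome: GenomeSpec, samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in genome.chromosomes:
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s)
    return header


def _write_vcf(path, genome: GenomeSpec, samples: Sequence[str], records) -> None:
    """records: iterable of (chrom, pos0, ref, alt, {sample: (gt_tuple, (ref_d, alt_d))})."""
    header = _vcf_header(genome, samples)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for chrom, pos0, ref, alt, per_sample in records:
            rec = vf.new_record(contig=chrom, start=int(pos0), stop=int(pos0) + 1,
                                alleles=(ref, alt))
            for name in samples:
                gt, ad = per_sample[name]
                rec.samples[name]["GT"] = gt
                rec.samples[name]["AD"] = ad
            vf.write(rec)


def write_parent_pair_vcf(
    pair: ParentalPair,
    path,
    mean_depth: float = 30.0,
    error_rate: float = 0.0,
    seed=None,
    sample_names: tuple[str, str] = ("P1", "P2"),
) -> None:
    """Two-parent VCF: REF = parent-1 allele, ALT = parent-2 allele."""
    rng = as_rng(seed)
    records = []
    for chrom, _ in pair.genome.chromosomes:
        pos = pair.positions[chrom]
        alle = pair.alleles[chrom]
        if pos.size == 0:
            continue
        # parent 1 is hom-ref, parent 2 hom-alt at every discriminant site
        g = np.tile(np.array([[0, 2]]), (pos.size, 1))
        ref_d, alt_d = simulate_depths(g, mean_depth, error_rate, rng)
        for i in range(pos.size):
            records.append((
                chrom, int(pos[i]), str(alle[i, 0]), str(alle[i, 1]),
                {
                    sample_names[0]: ((0,), (int(ref_d[i, 0]), int(alt_d[i, 0]))),
                    sample_names[1]: ((1,), (int(ref_d[i, 1]), int(alt_d[i, 1]))),
                },
            ))
    _write_vcf(path, pair.genome, sample_names, records)


def write_tetrad_vcf(
    truth: TetradTruth,
    path,
    mean_depth: float = 30.0,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed=None,
    sample_names: tuple[str, str, str, str] = ("spore1", "spore2", "spore3", "spore4"),
) -> None:
    """Four haploid spore samples; GT follows parental origin at each marker."""
    rng = as_rng(seed)
    pair = truth.pair
    records = []
    for chrom, _ in pair.genome.chromosomes:
        pos = pair.positions[chrom]
        if pos.size == 0:
            continue
        alle = pair.alleles[chrom]
        origins = truth.spore_origins[chrom]  # (4, n)
        g = np.where(origins.T == 1, 2, 0)    # hom-alt when parent-2 origin
        if missing_rate > 0:
            g = g.copy()
            g[rng.random(g.shape) < missing_rate] = -1
        ref_d, alt_d = simulate_depths(g, mean_depth, error_rate, rng)
        for i in range(pos.size):
            per_sample = {}
            for j, name in enumerate(sample_names):
                if g[i, j] < 0:
                    per_sample[name] = ((None,), (0, 0))
                else:
                    per_sample[name] = (
                        (int(origins[j, i]),),
                        (int(ref_d[i, j]), int(alt_d[i, j])),
                    )
            records.append((chrom, int(pos[i]), str(alle[i, 0]), str(alle[i, 1]), per_sample))
    _write_vcf(path, pair.genome, sample_names, records)


def write_events_bed(events: Iterable[RecombinationEvent], path) -> None:
    """BED: chrom, maxTractStart, maxTractEnd, kind, sporeIds, markerCount, innerStart, innerEnd."""
    rows = []
    for ev in events:
        rows.append((
            ev.chromosome,
            int(ev.max_start if ev.max_start is not None else ev.inner_start),
            int(np.ceil(ev.max_end if ev.max_end is not None else ev.inner_end)),
            ev.kind,
            ",".join(str(s) for s in ev.spores) or ".",
            ev.n_markers,
            f"{ev.inner_start:.0f}",
            f"{ev.inner_end:.0f}",
        ))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_events_bed(path) -> list[RecombinationEvent]:
    events = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        spores = () if f[4] == "." else tuple(int(x) for x in f[4].split(","))
        events.append(RecombinationEvent(
            kind=f[3], chromosome=f[0],
            inner_start=float(f[6]), inner_end=float(f[7]),
            max_start=float(f[1]), max_end=float(f[2]),
            spores=spores, n_markers=int(f[5]),
        ))
    return events


def write_ma_vcf(
    genealogy: MAGenealogy,
    path,
    mean_depth: float = 30.0,
    error_rate: float = 0.0,
    seed=None,
    founder_name: str = "founder",
) -> list[str]:
    """Joint VCF of founder + MA lines at all true SNM and founder-het sites.

    Returns the sample order used.  Founder-het sites carry the parental
    alleles as REF/ALT; LOH tracts turn line genotypes homozygous for
    the retained haplotype.  SNM sites show the mutant allele in exactly
    the carrier line.
    """
    from .simulate import ma_sites

    rng = as_rng(seed)
    params = genealogy.params
    lines = [f"line{i:02d}" for i in range(params.n_lines)]
    samples = [founder_name] + lines
    ploidy = params.ploidy
    records = []
    for chrom, pos, ref, alt, gts in ma_sites(genealogy):
        per_sample = {}
        for name in samples:
            gt = gts["founder" if name == founder_name else name]
            code = sum(1 for a in gt if a != 0)
            g = (0 if code == 0 else 2) if ploidy == 1 else code
            ref_d, alt_d = simulate_depths(np.array([[g]]), mean_depth, error_rate, rng)
            per_sample[name] = (gt, (int(ref_d[0, 0]), int(alt_d[0, 0])))
        records.append((chrom, pos, ref, alt, per_sample))
    _write_vcf(path, genealogy.genome, samples, records)
    return samples


def ma_truth_table(genealogy: MAGenealogy) -> pd.DataFrame:
    """True SNMs as a tidy table (1-based positions, like the VCF)."""
    rows = [
        (f"line{m.line:02d}", m.chromosome, m.position + 1, m.ref, m.alt, m.zygosity_change)
        for m in genealogy.snms
    ]
    return pd.DataFrame(rows, columns=["line", "chrom", "pos", "ref", "alt", "zygosity_change"])


def write_mask_bed(genome: GenomeSpec, path) -> None:
    rows = [
        (chrom, start, end)
        for chrom, ivals in genome.masked_intervals.items()
        for start, end in ivals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_genotype_matrix_vcf(gm: GenotypeMatrix, genome: GenomeSpec, path) -> None:
    """Strain dosages as a diploid multi-sample VCF (placeholder A/T alleles)."""
    records = []
    order = np.lexsort((gm.positions, gm.chromosomes))
    for i in order:
        per_sample = {}
        for j, name in enumerate(gm.samples):
            d = int(gm.dosages[i, j])
            gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}.get(d, (None, None))
            per_sample[name] = (gt, (0, 0))
        records.append((str(gm.chromosomes[i]), int(gm.positions[i]), "A", "T", per_sample))
    _write_vcf(path, genome, gm.samples, records)
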
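"""Mutation-accumulation analysis: SNM filtering, rates, bias, LOH.

The base-substitutional mutation rate of a genealogy is

    mu_bs = n_mutations / (callable_sites * ploidy * generations * n_lines)

with an exact (chi-square) Poisson 95% CI on the mutation count scaled
by the same denominator.  The AT bias is composition-weighted:

    bias = (m_GC->AT / N_GC) / (m_AT->GC / N_AT)

and the mutation-driven equilibrium GC content is 1 / (1 + bias).
``callable_sites`` is always an explicit input — the analyzed genome
fraction is an experimental quantity, never inferred here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .markers import SiteCall

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
GC_BASES = frozenset("GC")

ZYGOSITY_CHANGES = ("hom->hom", "hom->het", "het->hom")
BACKGROUNDS = ("homozygous-haploid", "homozygous-diploid", "heterozygous-diploid")
_ALLOWED_CHANGES = {
    "homozygous-haploid": {"hom->hom"},
    "homozygous-diploid": {"hom->het"},
    "heterozygous-diploid": {"hom->het", "het->hom"},
}


def substitution_class(ref: str, alt: str) -> str:
    """One of the 4 directional flux classes: GC>AT, AT>GC, GC>GC, AT>AT."""
    a = "GC" if ref in GC_BASES else "AT"
    b = "GC" if alt in GC_BASES else "AT"
    return f"{a}>{b}"


def is_transition(ref: str, alt: str) -> bool:
    return (ref in PURINES) == (alt in PURINES) and ref != alt


@dataclass(frozen=True)
class SNMRecord:
    """A line-exclusive single-nucleotide mutation."""

    line: str
    chromosome: str
    position: int
    ref: str
    alt: str
    zygosity_change: str

    def __post_init__(self) -> None:
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("SNM requires two distinct single bases")
        if self.zygosity_change not in ZYGOSITY_CHANGES:
            raise ValueError(f"unknown zygosity change {self.zygosity_change!r}")

    @property
    def substitution_class(self) -> str:
        return substitution_class(self.ref, self.alt)

    @property
    def is_transition(self) -> bool:
        return is_transition(self.ref, self.alt)


@dataclass(frozen=True)
class RateEstimate:
    """mu_bs with its exact Poisson 95% CI and the bookkeeping behind it."""

    mu_bs: float
    ci95: tuple[float, float]
    n_mutations: int
    n_lines: int
    generations: float
    callable_sites: float
    ploidy: int

    def __post_init__(self) -> None:
        low, high = self.ci95
        if not (low <= self.mu_bs <= high):
            raise ValueError("point estimate outside its CI")


@dataclass(frozen=True)
class BiasEstimate:
    """Composition-weighted AT bias and the equilibrium GC it implies."""

    at_bias: float
    equilibrium_gc: float
    m_gc_to_at: int
    m_at_to_gc: int
    n_gc: float
    n_at: float


@dataclass(frozen=True)
class LOHEvent:
    """A mitotic loss-of-heterozygosity tract in one MA line."""

    line: str
    chromosome: str
    start: int
    end: int
    kind: str  # interstitial | terminal
    n_markers: int
    retained: int = -1  # parental origin kept, -1 if unknown

    def __post_init__(self) -> None:
        if self.kind not in ("interstitial", "terminal"):
            raise ValueError(f"unknown LOH kind {self.kind!r}")


def poisson_ci(n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (chi-square) two-sided CI for a Poisson count."""
    alpha = 1.0 - conf
    low = 0.0 if n == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * n)
    high = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * n + 2)
    return float(low), float(high)


def estimate_rate(
    n_mutations: int,
    n_lines: int,
    generations: float,
    callable_sites: float,
    ploidy: int = 1,
) -> RateEstimate:
    """Point estimate and exact Poisson 95% CI of mu_bs."""
    if n_lines <= 0 or generations <= 0 or callable_sites <= 0 or ploidy <= 0:
        raise ValueError("all denominator terms must be positive")
    if n_mutations < 0:
        raise ValueError("negative mutation count")
    denom = callable_sites * ploidy * generations * n_lines
    low, high = poisson_ci(n_mutations)
    return RateEstimate(
        mu_bs=n_mutations / denom,
        ci95=(low / denom, high / denom),
        n_mutations=n_mutations,
        n_lines=n_lines,
        generations=generations,
        callable_sites=callable_sites,
        ploidy=ploidy,
    )


def compute_at_bias(
    snms: Iterable[SNMRecord],
    n_gc: float,
    n_at: float,
) -> BiasEstimate:
    """Composition-weighted AT bias from classified SNMs.

    GC<->GC and AT<->AT substitutions carry no GC-content flux and are
    ignored.  With zero AT->GC events the bias is infinite and the
    equilibrium GC is 0.
    """
    if n_gc <= 0 or n_at <= 0:
        raise ValueError("composition counts must be positive")
    snm_list = list(snms)
    m_gc_at = sum(1 for m in snm_list if m.substitution_class == "GC>AT")
    m_at_gc = sum(1 for m in snm_list if m.substitution_class == "AT>GC")
    return _bias_from_counts(m_gc_at, m_at_gc, n_gc, n_at)


def _bias_from_counts(m_gc_at: int, m_at_gc: int, n_gc: float, n_at: float) -> BiasEstimate:
    if m_at_gc == 0:
        bias = math.inf
        eq = 0.0
    else:
        bias = (m_gc_at / n_gc) / (m_at_gc / n_at)
        eq = equilibrium_gc(bias)
    return BiasEstimate(at_bias=bias, equilibrium_gc=eq,
                        m_gc_to_at=m_gc_at, m_at_to_gc=m_at_gc, n_gc=n_gc, n_at=n_at)


def bias_from_counts(m_gc_at: int, m_at_gc: int, n_gc: float, n_at: float) -> BiasEstimate:
    """AT bias directly from flux counts and callable composition."""
    if n_gc <= 0 or n_at <= 0:
        raise ValueError("composition counts must be positive")
    return _bias_from_counts(m_gc_at, m_at_gc, n_gc, n_at)


def equilibrium_gc(at_bias: float) -> float:
    """GC content at mutational equilibrium: 1 / (1 + bias)."""
    if at_bias < 0:
        raise ValueError("bias must be >= 0")
    if math.isinf(at_bias):
        return 0.0
    return 1.0 / (1.0 + at_bias)


def pooled_bias(
    biases: Sequence[float],
    weights: Sequence[float],
) -> tuple[float, float]:
    """Count-weighted pooled AT bias and pooled equilibrium GC.

    Both quantities are weighted means over genealogies — the pooled
    equilibrium is the mean of per-genealogy equilibria, not the
    equilibrium of the pooled bias (the two differ; this convention
    reproduces the study-style summary).
    """
    w = np.asarray(weights, dtype=float)
    b = np.asarray(biases, dtype=float)
    if w.size != b.size or w.size == 0:
        raise ValueError("biases and weights must be equal-length and non-empty")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be >= 0 and not all zero")
    pooled_b = float(np.average(b, weights=w))
    eqs = np.array([equilibrium_gc(x) for x in b])
    pooled_eq = float(np.average(eqs, weights=w))
    return pooled_b, pooled_eq


def ts_tv(snms: Iterable[SNMRecord]) -> float:
    """Transition:transversion ratio; infinite when no transversions."""
    n_ts = n_tv = 0
    for m in snms:
        if m.is_transition:
            n_ts += 1
        else:
            n_tv += 1
    if n_ts + n_tv == 0:
        raise ValueError("no substitutions")
    if n_tv == 0:
        return math.inf
    return n_ts / n_tv


# ---------------------------------------------------------------------------
# SNM filtering from joint line calls


def _genotype_alleles(call, ref: str, alt: str, ploidy: int) -> tuple[str, ...] | None:
    """Alleles implied by a sample's GT string, or None when uncalled."""
    if call is None or call.genotype is None:
        return None
    mapping = {"0": ref, "1": alt}
    alleles = tuple(mapping.get(tok) for tok in call.genotype.replace("|", "/").split("/"))
    if any(a is None for a in alleles):
        return None
    if ploidy == 1 and len(alleles) == 1:
        return alleles
    if len(alleles) != ploidy:
        return None
    return alleles


def filter_snms(
    calls: Iterable[SiteCall],
    founder: str,
    background: str,
    min_depth: int = 10,
    balance: tuple[float, float] = (0.4, 0.6),
    loh_events: Sequence[LOHEvent] | None = None,
) -> list[SNMRecord]:
    """Line-exclusive SNMs from jointly-called MA lines.

    Retains single-alt sites where every sample has depth strictly
    greater than ``min_depth``, exactly one line deviates from the
    founder genotype, heterozygous calls sit inside the allele-balance
    window, the zygosity change is possible for the background, and
    het->hom calls do not fall inside a detected LOH tract.
    """
    if background not in BACKGROUNDS:
        raise ValueError(f"unknown background {background!r}")
    allowed = _ALLOWED_CHANGES[background]
    ploidy = 1 if background == "homozygous-haploid" else 2
    loh_by_line: dict[str, list[LOHEvent]] = {}
    for ev in loh_events or []:
        loh_by_line.setdefault(ev.line, []).append(ev)

    out: list[SNMRecord] = []
    for site in calls:
        if len(site.alts) != 1:
            continue
        alt = site.alts[0]
        if len(site.ref) != 1 or len(alt) != 1:
            continue
        if founder not in site.samples:
            raise ValueError(f"founder sample {founder!r} absent at "
                             f"{site.chromosome}:{site.position}")
        if any(c.depth <= min_depth for c in site.samples.values()):
            continue
        founder_gt = _genotype_alleles(site.samples[founder], site.ref, alt, ploidy)
        if founder_gt is None:
            continue
        deviants = []
        for name, call in site.samples.items():
            if name == founder:
                continue
            gt = _genotype_alleles(call, site.ref, alt, ploidy)
            if gt is None or set(gt) != set(founder_gt):
                deviants.append((name, call, gt))
        if len(deviants) != 1:
            continue
        line, call, gt = deviants[0]
        if gt is None:
            continue
        founder_het = len(set(founder_gt)) > 1
        line_het = len(set(gt)) > 1
        change = f"{'het' if founder_het else 'hom'}->{'het' if line_het else 'hom'}"
        if change not in allowed:
            continue
        if line_het:
            ab = call.alt_depth / call.depth if call.depth else 0.0
            if not (balance[0] <= ab <= balance[1]):
                continue
        if change == "het->hom":
            pos0 = site.position - 1
            inside_loh = any(
                ev.chromosome == site.chromosome and ev.start <= pos0 < ev.end
                for ev in loh_by_line.get(line, [])
            )
            if inside_loh:
                continue
            lost = (set(founder_gt) - set(gt)).pop()
            gained = gt[0]
            out.append(SNMRecord(line=line, chromosome=site.chromosome,
                                 position=pos0, ref=lost, alt=gained,
                                 zygosity_change=change))
            continue
        new_allele = (set(gt) - set(founder_gt)).pop()
        old_allele = founder_gt[0]
        out.append(SNMRecord(line=line, chromosome=site.chromosome,
                             position=site.position - 1, ref=old_allele,
                             alt=new_allele, zygosity_change=change))
    return out


# ---------------------------------------------------------------------------
# mitotic LOH detection


def detect_ma_loh(
    het_positions: dict[str, np.ndarray],
    line_states: dict[str, dict[str, np.ndarray]],
    chrom_lengths: dict[str, int],
    n_lines: int,
    generations: float,
    min_markers: int = 2,
) -> tuple[list[LOHEvent], float]:
    """LOH tracts as runs of founder-het sites gone homozygous in one line.

    ``line_states[line][chrom]`` is aligned to ``het_positions[chrom]``:
    ``-1`` still heterozygous, ``0``/``1`` homozygous for that parental
    haplotype.  A maximal run of >= ``min_markers`` consecutive
    homozygous sites retaining the same haplotype is one event; it is
    terminal when its maximal extent (to the nearest flanking het site,
    else the chromosome end) touches an end.  The rate is events per
    line per generation times lines, i.e. total events / (n_lines x
    generations).
    """
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    for chrom in het_positions:
        if chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {chrom!r}")
    events: list[LOHEvent] = []
    for line, states in line_states.items():
        for chrom, st in states.items():
            pos = het_positions[chrom]
            st = np.asarray(st)
            if st.shape != pos.shape:
                raise ValueError(f"state vector misaligned on {chrom!r}")
            i = 0
            n = st.size
            while i < n:
                if st[i] < 0:
                    i += 1
                    continue
                j = i
                while j + 1 < n and st[j + 1] == st[i]:
                    j += 1
                if j - i + 1 >= min_markers:
                    max_start = int(pos[i - 1]) + 1 if i > 0 else 0
                    max_end = int(pos[j + 1]) if j + 1 < n else chrom_lengths[chrom]
                    kind = "terminal" if (max_start == 0 or max_end == chrom_lengths[chrom]) \
                        else "interstitial"
                    events.append(LOHEvent(line=line, chromosome=chrom,
                                           start=int(pos[i]), end=int(pos[j]) + 1,
                                           kind=kind, n_markers=j - i + 1,
                                           retained=int(st[i])))
                i = j + 1
    rate = loh_rate(len(events), n_lines, generations)
    return events, rate


def loh_rate(n_events: int, n_lines: int, generations: float) -> float:
    """Genomic LOH rate: events per generation across the genealogy."""
    if n_lines <= 0 or generations <= 0:
        raise ValueError("n_lines and generations must be positive")
    return n_events / (n_lines * generations)


def loh_states_from_calls(
    calls: Iterable[SiteCall],
    founder: str,
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, np.ndarray]]]:
    """Founder-het positions and per-line zygosity-state vectors.

    Returns ``(het_positions, line_states)`` ready for
    :func:`detect_ma_loh`: state -1 while heterozygous, 0/1 when
    homozygous for the reference/alternate haplotype (uncalled sites
    count as still heterozygous).
    """
    per_chrom: dict[str, list[tuple[int, dict[str, int]]]] = {}
    line_names: list[str] = []
    for site in sorted(calls, key=lambda s: (s.chromosome, s.position)):
        fgt = site.samples.get(founder)
        if fgt is None or fgt.genotype is None:
            continue
        alleles = set(fgt.genotype.replace("|", "/").split("/"))
        if alleles != {"0", "1"}:
            continue  # founder not heterozygous here
        states: dict[str, int] = {}
        for name, call in site.samples.items():
            if name == founder:
                continue
            if name not in line_names:
                line_names.append(name)
            gt = None if call.genotype is None else \
                set(call.genotype.replace("|", "/").split("/"))
            if gt == {"0"}:
                states[name] = 0
            elif gt == {"1"}:
                states[name] = 1
            else:
                states[name] = -1
        per_chrom.setdefault(site.chromosome, []).append((site.position - 1, states))
    het_positions = {
        chrom: np.array([p for p, _ in rows], dtype=np.int64)
        for chrom, rows in per_chrom.items()
    }
    line_states = {
        line: {
            chrom: np.array([st.get(line, -1) for _, st in rows], dtype=np.int8)
            for chrom, rows in per_chrom.items()
        }
        for line in line_names
    }
    return het_positions, line_states


def ma_generations(n_cycles: int, generations_per_cycle: float) -> float:
    """Total generations of a bottleneck regime: cycles x generations/cycle."""
    if n_cycles < 1 or generations_per_cycle <= 0:
        raise ValueError("cycles and generations/cycle must be positive")
    return n_cycles * generations_per_cycle
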
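"""Parameter-recovery experiments: simulate with known truth, measure detection.

These drive the package's end-to-end checks: CO/NCO detection over many
simulated tetrads, mutation-rate/bias recovery over replicated MA
genealogies, and heterozygosity restitution under intratetrad mating.
An event is counted as *resolvable* only when the marker landscape can
express it: at least two informative markers on each side of a CO
breakpoint, and no second event inside the local marker window (two
events between the same flanking markers are physically
indistinguishable from their superposition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import CO, NCO
from .ma_rates import compute_at_bias, estimate_rate, filter_snms
from .simulate import (
    MAParams,
    MeiosisParams,
    ParentalPair,
    as_rng,
    intratetrad_mate,
    ma_site_calls,
    simulate_ma_genealogy,
    simulate_tetrad,
)
from .tetrad_events import OriginMatrix, call_events
from .genome import GenomeSpec


@dataclass
class CODetectionResult:
    n_tetrads: int = 0
    n_true_co: int = 0
    n_resolvable_co: int = 0
    n_recovered_co: int = 0
    n_correct_inner: int = 0
    n_called_co: int = 0
    n_false_co: int = 0
    n_co_mimics: int = 0  # CO calls explained by overlapping opposite conversions

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered_co / self.n_resolvable_co if self.n_resolvable_co else float("nan")


def co_detection_experiment(
    pair: ParentalPair,
    params: MeiosisParams,
    n_tetrads: int,
    seed=None,
    merge_distance: int = 5000,
) -> CODetectionResult:
    """Simulate tetrads and score CO recovery against the exact truth.

    A true CO is resolvable when >= 2 markers flank its breakpoint on
    each side and no other simulated event touches the surrounding
    2-marker window (closer events are below the method's resolution by
    construction).  Every called CO must correspond to a true CO with
    matching spores and a max tract containing its breakpoint; anything
    else counts as false.
    """
    rng = as_rng(seed)
    res = CODetectionResult(n_tetrads=n_tetrads)
    for _ in range(n_tetrads):
        truth = simulate_tetrad(pair, params, seed=rng)
        events = call_events(OriginMatrix.from_truth(truth),
                             merge_distance=merge_distance)
        called_by_chrom: dict[str, list] = {}
        for ev in events:
            called_by_chrom.setdefault(ev.chromosome, []).append(ev)
        true_cos = [e for e in truth.true_events if e.kind == CO]
        true_ncos = [e for e in truth.true_events if e.kind == NCO]
        res.n_true_co += len(true_cos)
        for tc in true_cos:
            x = tc.inner_start
            pos = pair.positions[tc.chromosome]
            left, right = pos[pos < x], pos[pos > x]
            if left.size < 2 or right.size < 2:
                continue
            lo2, hi2 = float(left[-2]), float(right[1])
            other_break = [
                e.inner_start for e in true_cos
                if e is not tc and e.chromosome == tc.chromosome
            ]
            if any(lo2 < y < hi2 for y in other_break):
                continue
            # complex-merge resolution limit: a second CO separated by
            # fewer than 2 markers within merge_distance collapses both
            too_close = any(
                abs(y - x) <= merge_distance
                and np.sum((pos > min(x, y)) & (pos < max(x, y))) < 2
                for y in other_break
            )
            if too_close:
                continue
            nco_overlap = any(
                e.chromosome == tc.chromosome
                and e.inner_start < hi2 and e.inner_end > lo2
                for e in true_ncos
            )
            if nco_overlap:
                continue
            # visibility: multi-CO chromatid collisions can exchange
            # identical-origin segments, leaving no switch at the
            # breakpoint (undetectable in principle).  The observable is
            # the origin matrix: require the flanking markers to differ
            # in exactly the recorded spore pair.
            mat = truth.spore_origins[tc.chromosome]
            pos_idx = np.searchsorted(pos, [left[-1], right[0]])
            col_l, col_r = mat[:, pos_idx[0]], mat[:, pos_idx[1]]
            switched = tuple(s for s in range(4) if col_l[s] != col_r[s])
            if switched != tc.spores:
                continue
            res.n_resolvable_co += 1
            matches = [
                e for e in called_by_chrom.get(tc.chromosome, [])
                if e.kind == CO and e.spores == tc.spores
                and e.max_start <= x <= e.max_end
            ]
            if matches:
                res.n_recovered_co += 1
                if any(e.inner_start == float(left[-1])
                       and e.inner_end == float(right[0]) for e in matches):
                    res.n_correct_inner += 1
        for ev in events:
            if ev.kind != CO:
                continue
            res.n_called_co += 1
            # a multi-CO chromatid collision can displace the visible
            # switch away from either breakpoint, so attribution is by
            # chromosome + spore pair (position-free)
            matched = any(
                tc.chromosome == ev.chromosome and tc.spores == ev.spores
                for tc in true_cos
            )
            if matched:
                continue
            # two kinds of indistinguishable coincidence: overlapping
            # conversions on two spores reproduce a CO's signature, and
            # two true COs inside one flanking-marker interval appear as
            # their composition (a single switch with composite spores)
            nco_mimic = any(
                a is not b and a.chromosome == ev.chromosome
                and b.chromosome == ev.chromosome
                and a.inner_start < b.inner_end and b.inner_start < a.inner_end
                and a.inner_start < ev.max_end and ev.max_start < a.inner_end
                for a in true_ncos for b in true_ncos
            )
            co_superposition = sum(
                1 for tc in true_cos
                if tc.chromosome == ev.chromosome
                and ev.max_start <= tc.inner_start <= ev.max_end
            ) >= 2
            if nco_mimic or co_superposition:
                res.n_co_mimics += 1
            else:
                res.n_false_co += 1
    return res


@dataclass
class NCODetectionResult:
    n_tetrads: int = 0
    n_called_co: int = 0
    n_co_mimics: int = 0
    n_true_nco: int = 0
    n_detectable_nco: int = 0
    n_recovered_nco: int = 0
    n_correct_bounds: int = 0


def nco_detection_experiment(
    pair: ParentalPair,
    params: MeiosisParams,
    n_tetrads: int,
    seed=None,
) -> NCODetectionResult:
    """Achiasmate-style run: count called COs (should be none when
    ``co_rate`` is 0) and score NCO tract recovery with exact bounds.

    A true NCO is detectable when it converts >= 1 marker and no other
    conversion touches its marker window (tract markers plus one flank
    on each side).
    """
    rng = as_rng(seed)
    res = NCODetectionResult(n_tetrads=n_tetrads)
    for _ in range(n_tetrads):
        truth = simulate_tetrad(pair, params, seed=rng)
        events = call_events(OriginMatrix.from_truth(truth))
        true_ncos = [e for e in truth.true_events if e.kind == NCO]
        # two conversions with overlapping tracts on spores of opposite
        # origin reproduce a CO's marker signature exactly; such
        # coincidences are tallied apart as mimics
        has_overlap = any(
            a is not b and a.chromosome == b.chromosome
            and a.inner_start < b.inner_end and b.inner_start < a.inner_end
            for a in true_ncos for b in true_ncos
        )
        n_co_calls = sum(1 for e in events if e.kind == CO)
        if has_overlap:
            res.n_co_mimics += n_co_calls
        else:
            res.n_called_co += n_co_calls
        res.n_true_nco += len(true_ncos)
        for tn in true_ncos:
            pos = pair.positions[tn.chromosome]
            n = pos.size
            covered = np.flatnonzero((pos >= tn.inner_start) & (pos < tn.inner_end))
            if covered.size == 0:
                continue
            i, j = int(covered[0]), int(covered[-1])
            window_lo = i - 1 if i > 0 else 0
            window_hi = j + 1 if j + 1 < n else n - 1
            others_touch = any(
                o is not tn and o.chromosome == tn.chromosome
                and np.any((pos[window_lo:window_hi + 1] >= o.inner_start)
                           & (pos[window_lo:window_hi + 1] < o.inner_end))
                for o in true_ncos
            )
            if others_touch:
                continue
            res.n_detectable_nco += 1
            exp_max_lo = float(pos[i - 1]) if i > 0 else 0.0
            exp_max_hi = float(pos[j + 1]) if j + 1 < n else \
                float(pair.genome.chrom_lengths[tn.chromosome])
            matches = [
                e for e in events
                if e.kind == NCO and e.chromosome == tn.chromosome
                and e.spores == tn.spores
                and e.inner_start == float(pos[i]) and e.inner_end == float(pos[j])
            ]
            if matches:
                res.n_recovered_nco += 1
                if any(e.max_start == exp_max_lo and e.max_end == exp_max_hi
                       for e in matches):
                    res.n_correct_bounds += 1
    return res


@dataclass
class RateRecoveryResult:
    n_replicates: int
    n_covered: int
    pooled_at_bias: float
    true_mu: float
    true_at_bias: float
    mu_estimates: list[float] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_replicates


def mu_recovery_experiment(
    n_replicates: int = 100,
    mu: float = 5e-9,
    n_lines: int = 20,
    generations: int = 1000,
    genome_length: int = 1_000_000,
    at_bias: float = 3.6,
    ts_tv: float = 1.21,
    gc_content: float = 0.296,
    mean_depth: float = 50.0,
    seed=None,
) -> RateRecoveryResult:
    """Replicated haploid MA genealogies through the full call-and-filter
    pipeline; checks exact-Poisson-CI coverage of mu and pooled AT bias."""
    rng = as_rng(seed)
    genome = GenomeSpec(chromosomes=(("chr1", genome_length),), gc_content=gc_content)
    n_covered = 0
    all_snms = []
    estimates = []
    for _ in range(n_replicates):
        params = MAParams(mu=mu, n_lines=n_lines, generations=generations,
                          at_bias=at_bias, ts_tv=ts_tv)
        gen = simulate_ma_genealogy(genome, params, seed=rng)
        calls = ma_site_calls(gen, mean_depth=mean_depth, seed=rng)
        snms = filter_snms(calls, founder="founder", background="homozygous-haploid")
        est = estimate_rate(len(snms), n_lines, generations, genome.callable_sites, 1)
        estimates.append(est.mu_bs)
        if est.ci95[0] <= mu <= est.ci95[1]:
            n_covered += 1
        all_snms.extend(snms)
    n_gc, n_at = genome.composition()
    pooled = compute_at_bias(all_snms, n_gc, n_at)
    return RateRecoveryResult(
        n_replicates=n_replicates, n_covered=n_covered,
        pooled_at_bias=pooled.at_bias, true_mu=mu, true_at_bias=at_bias,
        mu_estimates=estimates,
    )


def het_restitution_experiment(
    pair: ParentalPair,
    n_tetrads: int = 200,
    seed=None,
) -> float:
    """Fraction of markers kept heterozygous by non-sister intratetrad
    mating of achiasmate tetrads, averaged over simulated meioses."""
    rng = as_rng(seed)
    fracs = []
    for _ in range(n_tetrads):
        truth = simulate_tetrad(pair, MeiosisParams(), seed=rng)
        fracs.append(intratetrad_mate(truth, "non-sister", seed=rng).het_fraction())
    return float(np.mean(fracs))
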
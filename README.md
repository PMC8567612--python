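# achiasma

Tetrad SNP-segregation, mutation-accumulation and population-genomic
analyses for yeast genomes in which meiotic crossing over is absent or
nearly so — the situation found in *Saccharomycodes ludwigii*, a budding
yeast that mates predominantly within its own meiotic tetrad and
segregates chromosomes through an achiasmate meiosis I.

The package is aimed at researchers who want to (re)run this style of
analysis on their own variant calls, or to study how well such analyses
detect recombination, using simulations with exact ground truth.

## What it computes

**Tetrad segregation analysis.** From two haploid parents and the four
spores of a tetrad, high-confidence discriminant markers are selected
(single alternate allele; ≥ 10 reads in each parent; > 90% of reads on
one allele), each spore is assigned a parental origin at each marker,
and runs of segregation patterns are turned into events: a crossover
(CO) is a reciprocal origin switch of exactly two spores between 2:2
flanks, a non-crossover (NCO) gene conversion is a 3:1 run on a single
spore, a 4:0 run is a premeiotic (mitotic) LOH, and anything
contradictory is flagged complex. Maximum tract bounds extend to the
closest flanking 2:2 markers.

**Mutation accumulation.** From jointly-called MA lines, line-exclusive
single-nucleotide mutations are filtered (depth > 10 in every sample,
heterozygous allele balance in [0.4, 0.6], zygosity change consistent
with the founder, LOH-screened) and summarized as

```
mu_bs = m / (callable_sites × ploidy × generations × n_lines)
```

with the exact Poisson 95% CI (low = χ²(0.025, 2m)/2, high =
χ²(0.975, 2m+2)/2, same denominator). The composition-weighted AT bias
is `(m_GC→AT / N_GC) / (m_AT→GC / N_AT)` and the mutation-driven
equilibrium GC content is `1 / (1 + bias)`. Mitotic LOH tracts are
runs of founder-heterozygous markers gone homozygous in one line.

**Population signals of recombination.** Allele-sharing distances →
BIONJ trees per chromosome and genome-wide; per-chromosome topologies
are compared with five unrooted topological metrics (RF, matching
split, path difference, quartet, maximum agreement subtree), each
normalized by its mean over 1000 random pairs of uniform topologies.
Linkage disequilibrium is the squared genotype correlation r² per site
pair, binned by physical distance and smoothed with a moving average.

**Synthetic data.** Every input above can be simulated with known
truth: hybrid parental haplotypes with compartmentalized divergence
(~3.3% in somewhat under half the genome, ~0.2% elsewhere), tetrads
with Poisson CO/NCO placement and 2+2 segregation, non-sister or sister
intratetrad matings, MA genealogies with configurable μ, AT bias,
Ts:Tv and mitotic LOH, strain populations with latent genealogies, and
Poisson/binomial read depths.

## Worked example

```python
import achiasma as a
from achiasma.tetrad_events import OriginMatrix

# a scaled-down hybrid cross with compartmentalized divergence
genome = a.study_genome(scale=0.02, seed=1)
profile = a.DivergenceProfile.two_rate(genome)     # 3.3% / 0.2% blocks
pair = a.simulate_parent_pair(genome, profile, seed=1)
print(f"markers: {pair.n_snps}")

# an achiasmate meiosis that still initiates gene conversion
truth = a.simulate_tetrad(pair, a.MeiosisParams(co_rate=0.0, nco_rate=0.5), seed=2)
events = a.call_events(OriginMatrix.from_truth(truth))
print(f"called events: {a.meiotic_event_counts(events)}")
for e in events:
    if e.kind == "NCO":
        print(f"  NCO on {e.chromosome}, spore {e.spores[0]}, "
              f"{e.n_markers} markers, max tract {e.max_tract_length/1000:.1f} kb")

diploid = a.intratetrad_mate(truth, "non-sister", seed=3)
print(f"intratetrad heterozygosity: {diploid.het_fraction():.4f}")

est = a.estimate_rate(n_mutations=85, n_lines=30, generations=2037,
                      callable_sites=11.6e6, ploidy=1)
print(f"mu_bs = {est.mu_bs:.3g} (95% CI {est.ci95[0]:.3g} - {est.ci95[1]:.3g})")
bias, eq = a.pooled_bias([2.92, 5.85, 2.63], weights=[85, 48, 53])
print(f"pooled AT bias = {bias:.2f}, equilibrium GC = {100*eq:.1f}%")
```

prints

```
markers: 3886
called events: {'CO': 0, 'NCO': 3, 'PREMEIOTIC_LOH': 0, 'COMPLEX': 0}
  NCO on chrC, spore 2, 16 markers, max tract 0.4 kb
  NCO on chrF, spore 1, 8 markers, max tract 0.2 kb
  NCO on chrF, spore 1, 9 markers, max tract 3.7 kb
intratetrad heterozygosity: 0.9956
mu_bs = 1.2e-10 (95% CI 9.58e-11 - 1.48e-10)
pooled AT bias = 3.59, equilibrium GC = 23.3%
```

Zero COs are called on the achiasmate tetrad while all three
marker-covered conversion tracts are recovered; non-sister intratetrad
mating keeps essentially every marker heterozygous (only the converted
tracts homozygose). The haploid MA genealogy's 85 mutations over
30 lines × 2037 generations on an 11.6-Mb callable genome give
μ_bs = 1.2 × 10⁻¹⁰ per site per generation, and pooling the three
genealogies' AT biases by mutation count gives 3.59, i.e. a mutational
equilibrium GC of 23.3%.

A command-line interface mirrors the library
(`achiasma simulate|markers|tetrad|marates|trees|ld`, see `--help`).

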
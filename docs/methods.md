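# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices that were genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Coordinates and conventions

All internal coordinates are 0-based, half-open. Positions become
1-based only at VCF/TSV boundaries (and in the Seg file, which follows
the VCF convention). Parental origins are coded 0 (parent 1) and 1
(parent 2), missing as −1. Every simulation routine takes a seed (or a
shared `numpy` generator) and is bitwise reproducible; each call uses a
single seeded stream.

## The meiosis simulator

A cross is a `ParentalPair`: SNP positions drawn per divergence
compartment as Binomial(eligible sites, rate), uniform without
replacement, with repeat-masked sites ineligible by default (so the
stated rate applies to the callable fraction). The default hybrid
profile places ~3.3% divergence over 44.6% of the genome and ~0.2%
over the rest, matching the compartmentalized heterozygosity structure
of the hybrid cross this kind of analysis is applied to.

One meiosis replicates each chromosome into four chromatids (two per
homolog), then:

* **COs** — Poisson(`co_rate`) per chromosome. Each breakpoint is a
  continuous uniform position; one chromatid of each homolog (chosen
  uniformly) exchanges everything distal. Chromatid and chiasma
  interference are not modeled (independent placement);
  `obligate_co` is implemented by rejection sampling. Breakpoints fall
  between markers by construction, which is also all that real data can
  resolve — called COs report the flanking-marker interval.
* **NCOs** — Poisson(`nco_rate`); a uniformly chosen recipient
  chromatid has a tract (default geometric, mean 1.5 kb — the short
  gene-conversion tract regime of budding yeasts) overwritten with the
  other homolog's alleles. Donor and direction carry no asymmetry.
* **Segregation** — meiosis I separates chromatids by centromere
  origin (which COs can re-assign when the breakpoint is
  centromere-proximal); meiosis II splits each pair randomly. Spores
  0,1 and 2,3 are sisters; non-sister intratetrad mating draws one
  spore from each meiosis-I pole, restoring heterozygosity at every
  marker when the meiosis was achiasmate.

Not modeled (out of scope): read-level sequence simulation, mapping
error, indels/SVs, aneuploidy, and the two-spore diploid asci observed
in some strains (meiosis completed with a single division) — the
simulator always produces four spores.

## Event calling

Markers with a missing spore are excluded from event support but do not
break runs. Complete markers compress into runs of identical origin
patterns; then:

* a phase switch between adjacent 2:2 runs with exactly two spores
  changing (necessarily reciprocally) is a CO; four spores changing at
  once is flagged complex;
* a single-pattern 3:1/1:3 block with equal 2:2 flanks is an NCO
  (minimum supporting markers configurable, default 1 — single-marker
  conversions are real and detectable); with flanks differing by a
  reciprocal two-spore switch it is a CO with an attached conversion
  annotation; any other disagreement is complex;
* 4:0/0:4 blocks are premeiotic LOH — reported, but excluded from
  meiotic event counts, since both chromatids of one homolog carrying
  the other parent's alleles implies the event preceded meiosis;
* a reciprocal double switch restoring the original phase is reported
  as two COs only when ≥ 2 markers separate the switches or they are
  more than `merge_distance` (default 5 kb) apart; otherwise it is one
  complex event, being indistinguishable from a short double event.

Maximum tracts run to the nearest flanking 2:2 markers, or to the
chromosome end where none exist. Nothing is silently dropped: every
contradictory configuration surfaces as a complex event.

The Seg serialization is a minimal 6-column TSV (header naming the four
spores, `P1`/`P2`/`NA` codes); it round-trips losslessly but does not
reproduce any particular legacy dialect byte-for-byte.

### Resolution limits scored honestly

The detection experiments in `achiasma.evaluation` score the caller
against what the origin matrix can express, not against raw event
counts: a CO is *resolvable* when ≥ 2 markers flank the breakpoint on
each side, no other event touches the two-marker window, and the truth
matrix actually switches at the flanking interval (multi-CO chromatid
collisions can exchange identical-origin segments, which no method can
see). Two conversions with overlapping tracts on spores of opposite
origin reproduce a CO's signature marker-for-marker, and two COs inside
one flanking interval appear as their composition; such coincidences
are tallied as mimics/superpositions, separately from false calls.
Under the test conditions (0.5 CO + 0.3 NCO per chromosome, ~1.2 kb
marker spacing) they are at the level of a few events per thousand
tetrads.

## Marker selection

"At least 10 reads across both parents" is applied per parent (≥ 10 in
each), which the reduced-coverage variant ("lowered to 3 for each
parent") confirms as the intended semantics. Depth uses ≥ ("at
least"), purity uses strict > ("more than 90%"). Sites where both
parents' majority alleles agree are dropped as non-discriminant
regardless of quality. Raising either threshold can only shrink the
retained set (tested as a property).

## Mutation-accumulation estimators

`mu_bs = m / (callable_sites × ploidy × generations × n_lines)`. The
denominator includes ploidy — required for the diploid genealogies'
arithmetic to come out right even though verbal descriptions of the
formula often omit it. `callable_sites` is always an explicit input:
the analyzed fraction of a genome is an experimental fact that should
never be inferred silently. (For the hybrid-diploid genealogy the
consistent denominator is the full ~12.5-Mb assembly span rather than
the 93% masked fraction; per-genealogy analyzed sizes differ, which is
exactly why the parameter is exposed.)

The 95% CI is the exact Poisson interval via chi-square quantiles,
`[χ²(0.025, 2m)/2, χ²(0.975, 2m+2)/2]`, scaled by the same denominator;
with m = 0 the lower bound is 0 (one-sided). A test cross-checks the
quantiles against the defining Poisson tail equations.

AT bias is composition-weighted over the *callable* genome (mutations
were only called there): `(m_GC→AT/N_GC)/(m_AT→GC/N_AT)`; GC↔GC and
AT↔AT changes carry no flux. Equilibrium GC is `1/(1+bias)`; zero
reverse flux yields an infinite bias and equilibrium 0. Pooling across
genealogies uses count-weighted means of both the biases and the
per-genealogy equilibria — two separate weighted means, documented as
such because the mean of equilibria is not the equilibrium of the mean.

SNM filtering keeps single-alt sites with depth strictly > 10 in every
sample, the variant in exactly one line, heterozygous calls with allele
balance in [0.4, 0.6] (inclusive window), a zygosity change possible
for the founder background, and het→hom calls outside detected LOH
tracts. LOH detection itself is run-length encoding of founder-het
sites gone homozygous for one haplotype in one line (default
`min_markers` 2, to suppress single-site genotyping noise; configurable
to 1); an event is terminal when its maximal extent reaches a
chromosome end. The LOH rate is events/(lines × generations).

The MA simulator draws per-line counts as Poisson(μ × callable × ploidy
× generations) and shapes each mutation's type from a 12-entry directed
substitution table constructed so that the per-site GC→AT/AT→GC ratio
equals `at_bias` exactly and the expected Ts:Tv equals `ts_tv` (the
transition weight is solved in closed form from the composition).
Positions are uniform over callable sites; the abstract genome carries
no per-position base identity, so base composition enters only through
`gc_content`.

## Trees

Strain distances are allele-sharing dissimilarities: mean |dosage
difference|/2 with pairwise deletion (hom vs het = 0.5, opposite homs
= 1) — a documented, testable stand-in for unpublished package-specific
formulas; topology-level conclusions are insensitive to the exact
sharing kernel on the simulations tested. Trees are built with BIONJ
(variance-weighted NJ; the reduction weight λ is clamped to [0, 1], the
Q-criterion tie-break is the first row-major minimum, so output is
deterministic); additive matrices are recovered exactly, branch lengths
included.

The five comparison metrics are purely topological (branch lengths
ignored): RF (split symmetric difference), MS (minimum-weight perfect
matching between split sets under the orientation-minimized symmetric
difference, via the Hungarian algorithm), PD (Euclidean distance of
leaf-pair edge-count vectors), Q (quartets resolved differently —
quartets in binary trees are always resolved, decided by the smallest
topological distance-sum pairing), MAS (leaves minus the largest leaf
subset with identical restricted split sets, exhaustive over subsets —
exact and fast to ~16 leaves, which covers study-sized strain panels).
Splits are bitmasks, so the exhaustive searches stay cheap. Random
reference topologies come from uniform sequential leaf insertion over
the 2k−5 edges; normalized distance = raw / mean over `n_random`
random pairs (default 1000), so ≈ 1 means "as discordant as unrelated
random trees". Tests verify all five metrics against naive
graph-algorithm oracles at ≤ 8 taxa, RF against dendropy, and the
generator's uniformity by chi-square over all 15 five-taxon topologies.

## Linkage disequilibrium

r² is the squared Pearson correlation of alt-dosage vectors
(heterozygotes count 1; missing genotypes pairwise-deleted) — a
genotype-based estimator chosen because unphased diploids preclude
haplotype-frequency r², and group comparisons are relative so a
consistent estimator is what matters. Pairs are intra-chromosomal up
to `max_dist` (default 300 kb); means are taken per exact distance and
smoothed with a centered moving average over the distance axis
(default window 50 points; both recorded in the output). Sites
monomorphic in the sample are undefined and skipped; an input with no
scorable pair yields an empty curve, not an error. Comparisons should
always use equal-sized strain groups; a test checks that random
11-strain subsets of a 30-strain population give closely agreeing
curves.

The population simulator assigns each site a random bipartition of a
latent genealogy (a random topology over the strains); with one
genealogy all sites share one history (flat LD in distance, concordant
chromosome trees), and a per-bp switching rate between several
genealogies makes nearby sites share histories while distant ones
decouple (monotone LD decay, discordant pinned chromosomes). This
reproduces the *qualitative* contrasts the analyses are designed to
detect; it is not a coalescent and makes no claim about absolute LD
levels or realistic allele-frequency spectra.

## Problem sizes in the test suite

The default suite and the acceptance script run simulations at reduced
scale, chosen as the smallest sizes at which the checked properties are
statistically unambiguous: 1000 tetrads on a 200-kb chromosome with
~165 markers for CO detection; 500 achiasmate tetrads for NCO bounds;
100 replicate genealogies of 20 lines × 1000 generations on 1 Mb
(μ = 5 × 10⁻⁹, ~100 mutations per replicate) for CI coverage, with the
AT bias pooled across replicates (per-replicate counts are too small
for a tight bias estimate); trees at 6–11 taxa where the exhaustive
oracles are exact. Passing these shows the estimators and callers are
correct and calibrated under the generative model; it does not by
itself validate mapping/calling upstream of the VCF, which is outside
the package's scope.

## Known limitations

* Event attribution near coincident events is fundamentally ambiguous
  (see resolution limits above); the caller flags rather than guesses.
* The MS metric's split-to-dummy cost uses min(|A|, |B|); other
  padding conventions exist and differ on non-binary inputs.
* The dissimilarity and r² estimators are documented stand-ins where
  published pipelines leave their exact formulas unstated; results are
  internally consistent but not byte-identical to any external tool.
* The LD plateau height depends on sample size (E[r²] ≈ 1/(n−1) under
  independence), which is why only equal-sized groups are comparable.
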
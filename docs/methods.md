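# Methods

## The question and the signal

Gene flow into a sampled population from an *unsampled* ("ghost") source
cannot be detected by allele-sharing methods, because there is nothing to
share alleles with. It does, however, leave a genealogical footprint: an
introgressed haplotype places its carriers next to the root of the local
genealogy, and the boundaries of the introgressed region are recombination
breakpoints. `argscan` works with this footprint.

A population is an **outgroup** at a site if one of the two branches
adjacent to the root of the local tree subtends all of that population's
samples and no others. Scanning along a gene, the outgroup status of a
population toggles at certain breakpoints; the recombination events at the
boundaries of each maximal outgroup interval are called **disrupting**.
Each disrupting event is classified by the descendant sample set of the
recombinant lineage, read from the local tree on the side of the
breakpoint where the population is the outgroup (there, every lineage
below the root is pure with respect to the outgroup/rest partition):

* `R_A` — the lineage is ancestral only to members of the outgroup clade;
* `R_O` — it is ancestral only to samples from other populations.

Ordinary coalescent fluctuation produces both kinds. Gene flow from a
divergent unsampled source produces an *excess* of `R_A`. The method's
output is therefore a per-population tally of `R_A` versus `R_O` events
over a genome's worth of gene windows, compared against a null fraction
computed under an explicit demographic model.

## Closed form under panmixia

For a sample of `n` with a designated outgroup clade of size `k`, condition
on the clade being an outgroup (`O_A`). Track the *level* `j` — the number
of ancestors of the whole sample — and the number `a_j` of those that are
ancestral to the clade. Conditional on `O_A`, only within-clade and
within-rest coalescences occur before the root, and the chain `a_j` is
Markov with transition weights proportional to `a(a-1)/2` and
`b(b-1)/2` against the total pair rate (where `b = j - a`). A single
recombination is placed with intensity `rho/2` per lineage per unit time;
the recombinant lineage recoalesces at pair rate 1 with each surviving
lineage, possibly beyond the grand MRCA with the root stem.

Whether the regraft disrupts outgroup status is purely topological:

* recombination on a clade lineage (`R_A` candidate): disrupting unless
  the partner is clade-ancestral, or the pruned lineage carries the whole
  clade and the partner is the complete non-clade stem or the beyond-root
  stem (then the clade is still an outgroup after the swap);
* recombination on a non-clade lineage (`R_O` candidate): disrupting iff
  the partner is clade-ancestral, unless the pruned lineage carries the
  whole non-clade side and the partner is the clade stem.

Because level durations are `Exp(j(j-1)/2)`, the time integrals have the
closed forms `A_j = 2/(j(j+1))`, `B_j = 4/(j(j^2-1))`,
`E[e^{-l T_l}] = (l-1)/(l+1)`, and the whole computation reduces to a
forward–backward dynamic program over `(level, clade count)` — `O(n^2 k)`
time, exact in double precision over the full tabulated range (`n` up to
100). The probability of more than one recombination is `O(rho^2)` and is
dropped; `rho` and the probability of the conditioning event cancel in the
reported fraction `p_RA / (p_RA + p_RO)`.

Three independent routes guard this computation: a brute-force enumeration
of level profiles (exponential in `k`, used at small `n`), and a
Monte-Carlo oracle that simulates conditioned trees, performs the subtree
regraft explicitly and re-tests outgroup status from leaf sets, sharing no
case analysis with the closed form.

A useful aside with the same machinery: for `n` exchangeable lineages a
prespecified one is an outgroup with probability `2/(n(n-1))` (it must
dodge every merge but the last), and none is with probability
`1 - 2/(n-1)`; for five populations these are 0.1 and 0.5.

### Uniformity of the conditioned merge levels

Conditional on `O_A`, the *configuration* of levels at which the clade's
internal merges occur is exactly uniform over its valid range (verified
both by exact computation and simulation). For `k = 2` this makes the
number of lineages remaining at the clade MRCA, `m`, itself uniform on
`{2, ..., n-1}`; for `k >= 3` the marginal of `m` is not uniform (it
decreases linearly), only the joint configuration is. The test suite
checks the uniform object in each case.

## Island-model estimates

The same fraction is estimated under a symmetric `d`-island structured
coalescent by importance sampling. Timescale: units of `2N` generations
of a reference deme; within a deme of relative size `N_d` each lineage
pair coalesces at rate `1/N_d`; each lineage leaves its deme at total
rate `M/2`, uniformly over the other demes — the standard `M = 4Nm`
scaling, which we fixed by calibration against the published simulation
grid. A merge schedule can relocate whole demes into an ancestral pool at
set times (emulating populations that were panmictic beyond some age);
rates for inactive demes are zeroed per epoch.

Protocol per accepted tree: simulate until the pre-chosen target
population is an outgroup clade (rejection, with early abort as soon as no
harvestable population can still be monophyletic-and-outgroup); place one
recombination uniformly at random on the branches; let the floating
lineage migrate and recoalesce at the prior rates, replaying the recorded
deme occupancy of every branch; classify `R_A` / `R_O` / neither by the
topological rules; discard "neither"; weight each tree by its total branch
length `L(T)` (correcting for the fact that every accepted tree was forced
to host exactly one event). The estimate is the weighted `R_A` share among
disrupting events, with a standard error from the weighted effective
sample size. In the symmetric model the populations of equal sample size
are exchangeable, so a tree accepted for any same-size population is a
valid draw after relabeling; the pooled estimator uses this to raise the
acceptance rate. `M = infinity` is treated as a single panmictic deme and
computed exactly from the closed form.

The hot loop is compiled with numba; a fixed seed gives bit-identical
results. The pure-Python reference simulator
(`island.simulate_conditioned_tree`) implements the same model
event-by-event and is used in validation.

## FST and the migration parameter

For a population pair, FST is one minus the ratio of within- to
between-population diversity, with diversity the mean number of pairwise
sequence differences (missing alleles are skipped pairwise; negative
estimates are clamped to zero and flagged). On the timescale above the
expected pairwise coalescence times in the symmetric island model are `d`
within and `d + (d-1)/M` between demes, giving

    FST = 1 / (1 + M d / (d-1)),    M^ = (d-1)(1-FST) / (d FST).

Per-gene estimates are summarized as percentiles weighted by gene length
times the fraction of complete-data sites. Parameter recovery from the
package's own simulator (pooled median within a factor of two of the true
`M` over `M` in 0.5–2) is part of the test suite.

## The gene-flow test

For each population, `x` = number of `R_A` events and `n` = `R_A + R_O`
events over all genes. Nearby events within a gene are not independent,
so the binomial sample is conservatively rescaled to the locus scale:
`n_eff = ceil(n_genes * f)` where `f` is the fraction of genes in which
the population occupies the outgroup position, and
`x_eff = floor(x * n_eff / n)` (clamped to `n_eff`), with the one-tailed
p-value `P(X >= x_eff)` under `Binomial(n_eff, p0)` and a Bonferroni
factor for the number of populations tested. Rounding `n_eff` up and
`x_eff` down can only weaken the evidence. The null fraction `p0` comes
from the panmictic closed form or from the island sampler at a chosen
`M`; since power shrinks as the assumed `M` grows, testing against an
overestimate of `M` is the conservative application, and reports are
emitted over a ladder of `M` values.

## The synthetic-genome generator

`argscan.simulate` is a Hudson-style coalescent-with-recombination
simulator that emits *true* ARGs (single grand root, prefix/suffix-labeled
recombination nodes), an event log carrying the site-resolved descendant
set of every recombinant lineage (tracked independently of the graph, so
log-versus-graph consistency is a real check), and infinite-sites SNP
matrices. Crossover rate is `rho/2` per base of a lineage's
ancestral-material span; material whose marginal genealogy is complete
stops attracting recombination, so every emitted breakpoint is ancestral
to sampled material. Mutations either hit an exact per-gene target count
(matching designs where each gene is matched for its number of segregating
sites) or fall as a Poisson field at rate `theta/2` per bp of branch
length; sites land in marginal-tree intervals proportionally to tree
length and on branches proportionally to branch length. Physics is
cross-validated against msprime under matched rates.

### Study conditions

The reduced-scale study uses 200 gene windows of 2 kb with 25 segregating
sites each, sampling 3/3/3/2/2 haplotypes from five islands at `M = 1`
with `rho = 4e-4` per bp, the sampled islands joining an ancestral
panmictic pool 8 coalescent units ago — the null, "model (i)". The
gene-flow variant, "model (ii)", adds a single admixture pulse into
population 1 from an unsampled sixth deme 0.5 units ago, replacing 80% of
the recipient's gamete pool; the ghost deme itself stays isolated until
20 units ago. Two features of this design matter and were chosen
deliberately:

* the ghost deme rejoins the ancestral pool *later* than the sampled
  islands. If every deme rejoins at one deep time, recombination bubbles
  that open on the two long stems during the isolation phase generate
  `R_A` and `R_O` toggles symmetrically and wash out the signal; letting
  the sampled metapopulation reach its common ancestor first (after which
  bubble pieces close at panmictic rates) keeps the introgressed stem's
  boundaries clean. This is the regime in which an introgressed haplotype
  is identifiable at all;
* the pulse predates most coalescence of the recipient's ancestry with
  other populations (at `M = 1` that mixing happens within roughly one
  coalescent unit), so whole-clade jumps dominate over signal-destroying
  partial jumps.

At this scale a whole genome simulates and scans in seconds, so the test
suite runs replicate null genomes for calibration and a paired
null/pulse comparison for power. The admixture fraction is far larger
than anything the genome-scale study would need: with 200 genes the
rescaled binomial test has few effective trials, and the pulse strength
is what buys back the power that gene count cannot provide. Passing
these tests therefore demonstrates that the machinery is calibrated and
can detect a strong ghost pulse at small scale; it does not quantify
sensitivity to subtle introgression, nor does it exercise ARG
*reconstruction* — analyses run on true ARGs, whereas the empirical
pipeline inferred parsimony ARGs from sequence, a step that is out of
scope here and adds error the original study addressed separately.

## Aggregation of ARG replicates

When a gene has several reconstructed ARGs, outgroup identity over each
elementary interval is decided by strict majority across replicates (ties
drop the interval), boundary scores are averaged over the replicates
agreeing with the consensus, and genes whose replicates disagree on the
number of recombination events are excluded outright. Events whose
breakpoint coincides with a window edge are unidentifiable and enter no
tally. Two populations can be outgroups simultaneously (both root
children monophyletic); each is recorded in its own population's
statistics.

## Numerical and interface choices

* Internal coordinates are 0-based half-open; the kwarg-style dot dialect
  is read as 1-based inclusive, with the prefix (`P`) parent governing
  sites up to and including the breakpoint. The dot reader is tolerant
  about attribute-versus-label placement and edge orientation.
* The tabular ARG format round-trips bit-exactly; writer output is
  deterministically sorted.
* Multifurcations below the root are accepted on read; a non-binary local
  root is an error, since outgroup logic inspects exactly two root
  children.
* Indels and SNPs are both binary sites.
* All stochastic entry points take explicit seeds; genome simulations
  spawn per-gene seeds from the master seed so any gene is independently
  reproducible.
* Accepted-count defaults for the island sampler (10^5) match the
  published grid's precision; the test suite uses smaller per-cell counts
  with correspondingly wider Monte-Carlo error bands.

## Known limitations

* The closed form is single-recombination (`rho -> 0`); simulated genomes
  with realistic `rho` show mild excess disruption from multi-event
  histories, which the conservative test absorbs.
* The generator has no sequencing error, no recurrent mutation, no gaps,
  and polarization is perfect — real data add all four.
* The binomial rescaling treats loci as exchangeable trials; linked genes
  on a chromosome are not fully independent.
* Donor identity is never inferred: the output is evidence for an
  unsampled source, not a source.
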
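# argscan

Genealogy-based detection of gene flow from **unsampled** ("ghost")
populations, for population-genomic samples where the donor of an
introgressed haplotype is not in the data. Built for shallowly sampled,
multi-population designs such as the environmental *Saccharomyces
cerevisiae* isolates (five populations, 3/3/3/2/2 haplotypes), but the
machinery is general.

## The idea

A population forms an **outgroup** at a site when one of the two branches
adjacent to the root of the local genealogy subtends all of that
population's samples and no others. Introgression from a divergent,
unsampled source pushes the recipient to the outgroup position, and the
edges of the introgressed region are recombination breakpoints. Scanning
an ancestral recombination graph (ARG) gene by gene, `argscan` finds the
maximal intervals where each population is an outgroup and classifies the
*disrupting* recombination events at the interval boundaries by the
descendant set of the recombinant lineage:

* `R_A` — the recombination occurred in a lineage ancestral only to
  members of the outgroup clade;
* `R_O` — in a lineage ancestral only to samples from other populations.

Neutral coalescence produces both; ghost gene flow produces an excess of
`R_A`. Under the standard coalescent the expected `R_A` share of
disrupting events has a closed form — for a clade of size `k` in a sample
of `n`, e.g. 0.395 at `(n=13, k=3)` — and under island-model structure it
is estimated by importance sampling (conditioned trees weighted by total
branch length). The observed tally is tested against the null fraction
with a binomial test conservatively rescaled to the locus scale and
Bonferroni-corrected across populations.

## Worked example

Closed-form expectations for the yeast-like design (total sample 13,
outgroup clades of size 3 or 2):

```bash
$ argscan theory-table --n 3-5,13,100 --k 2,3
n       k=2     k=3
3       0.750
4       0.500   0.733
5       0.436   0.564
13      0.352   0.395
100     0.315   0.327
```

Read: conditional on a clade of 3 being an outgroup in a sample of 13,
39.5% of the recombination events that toggle its status occur in
lineages ancestral to that same clade — far more than a naive 3/13,
because the clade's stem persists deep into the tree. Any observed
fraction must beat *this* baseline (or its island-model analogue) before
it is evidence of ghost gene flow.

Simulate a 200-gene genome under the island null with an admixture pulse
into population 1 from an unsampled sixth deme, scan the true ARGs, and
test:

```bash
$ argscan simulate --model ii --genes 200 --seed 0 -o sim_ii
$ argscan scan sim_ii/*.arg.tsv --popmap sim_ii/popmap.tsv --tally tally.tsv
$ argscan test tally.tsv --null '{"1": {"3": 0.335, "2": 0.305}}'
M       pop1    pop2    pop3    pop4    pop5
1       3.87e-07        1                       1
```

Population 1 is the outgroup in 56 of the 200 genes, with 7 of its 10
identifiable disrupting events in lineages ancestral to the clade
itself, and is flagged (Bonferroni-corrected p = 3.9e-7 against the
migration-rate-1 null; the null fractions 0.335/0.305 come from
`argscan island-sim -M 1 --merge-time 8`, the same demography the
simulator uses). The other populations
are consistent with the null (blank cells had no disrupting events to
test). Per-gene FST and migration
estimates for any population pair come from `argscan fst`.

ARGs are accepted either in a kwarg-style dot dialect (1-based inclusive
coordinates, `P`/`S`-labeled recombination parents) or in the package's
tabular format; the simulator emits the tabular format plus ms-style
haplotype blocks and a truth log of every recombination, migration and
pulse event.

## Layout

| module | contents |
|---|---|
| `argscan.arg` | ARG structures, validation, marginal trees, dot/tabular I/O |
| `argscan.scan` | outgroup intervals, scores, R_A/R_O classification, replicate aggregation |
| `argscan.panmictic` | closed-form theory, clade/outgroup probabilities, Monte-Carlo oracle |
| `argscan.island` | island-model demography and the importance-sampling estimator |
| `argscan.geneflow` | FST, migration-parameter inversion, the rescaled binomial test |
| `argscan.simulate` | coalescent-with-recombination simulator emitting true ARGs |
| `argscan.cli` | `argscan` command-line entry points |

`docs/methods.md` documents the model, the estimators, the simulator's
study conditions and the known limitations.
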
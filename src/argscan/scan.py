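"""Scan ARGs for outgroup clades and the recombination events disrupting them.

A population is an *outgroup* at a site if one of the two branches adjacent
to the root of the local tree subtends all of that population's samples and
no others.  Over each maximal interval where a population is an outgroup,
up to two *disrupting* recombination events sit at the interval boundaries
— the events whose breakpoints toggle the outgroup status.  Each disrupting
event is classified by the descendant set of the recombinant lineage,
evaluated in the local tree on the side of the breakpoint where the
population is the outgroup (where every lineage below the root is pure with
respect to the outgroup/non-outgroup partition):

* ``R_A`` — the lineage is ancestral only to members of the outgroup clade;
* ``R_O`` — it is ancestral only to samples from other populations;
* ``other`` — mixed descent (cannot occur on true genealogies, but can on
  reconstructed ARGs evaluated away from the outgroup side).

Events whose breakpoint coincides with the window edge are unidentifiable
and contribute to no tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import pandas as pd

from .arg import Arg, LocalTree, PopulationMap, marginal_trees

R_A = "R_A"
R_O = "R_O"
OTHER = "other"


@dataclass(frozen=True)
class RecombEvent:
    """A recombination event at an outgroup-interval boundary."""

    breakpoint: int  # internal coordinate; boundary site is breakpoint + 1
    node_id: str
    descendants: frozenset[str]  # recombinant lineage's sample set
    classification: str | None = None

    def __post_init__(self):
        if not self.descendants:
            raise ValueError("recombinant lineage subtends no samples")


@dataclass
class OutgroupInterval:
    population: str
    interval: tuple[int, int]
    left_event: RecombEvent | None = None
    right_event: RecombEvent | None = None

    @property
    def boundary_events(self) -> list[RecombEvent]:
        return [e for e in (self.left_event, self.right_event) if e is not None]


@dataclass
class GeneSummary:
    gene_id: str
    n_replicates: int
    replicates_agree: bool
    excluded: bool
    consensus_intervals: list[OutgroupInterval] = field(default_factory=list)
    mean_scores: dict = field(default_factory=dict)  # (pop, interval) -> scores
    classifications: dict = field(default_factory=dict)  # (pop, interval, side) -> label
    n_intervals: int = 0  # marginal intervals in the consensus partition


def is_outgroup(tree: LocalTree, population: str, popmap: PopulationMap) -> bool:
    """True iff one root child subtends exactly this population's samples."""
    target = popmap.samples_of(population)
    root_kids = tree.children.get(tree.root, ())
    if len(root_kids) != 2:
        raise ValueError(f"local tree root must be binary, has {len(root_kids)} children")
    return any(ls == target for ls in tree.root_child_leafsets())


def outgroup_populations(tree: LocalTree, popmap: PopulationMap) -> list[str]:
    """All populations in outgroup position in this tree (0, 1 or 2)."""
    out = []
    leafsets = tree.root_child_leafsets()
    for pop in popmap.populations:
        if any(ls == popmap.samples_of(pop) for ls in leafsets):
            out.append(pop)
    return out


def recombination_score(event: RecombEvent, popmap: PopulationMap) -> dict[str, float]:
    """Per-population attribution score of a recombination event.

    Population ``P`` subtending a fraction ``f_P`` of its samples under the
    recombinant lineage receives ``f_P`` normalized by the sum over all
    populations, so the scores sum to 1.
    """
    fs = {}
    for pop in popmap.populations:
        members = popmap.samples_of(pop)
        fs[pop] = len(event.descendants & members) / len(members)
    total = sum(fs.values())
    if total == 0:
        raise ValueError("event subtends no mapped samples")
    return {pop: f / total for pop, f in fs.items()}


def classify_disrupting(event: RecombEvent, population: str,
                        popmap: PopulationMap) -> str:
    members = popmap.samples_of(population)
    if event.descendants <= members:
        return R_A
    if not (event.descendants & members):
        return R_O
    return OTHER


def _boundary_event(arg: Arg, boundary: int, outgroup_site: int) -> RecombEvent | None:
    """The recombination event whose breakpoint defines ``boundary``.

    The descendant set of the recombinant lineage is evaluated at
    ``outgroup_site`` — a site on the side of the breakpoint where the
    population is the outgroup.  If several recombination nodes share the
    breakpoint, the (deterministically) first is taken.
    """
    for nid in arg.recombination_nodes:
        if arg.nodes[nid].breakpoint + 1 == boundary:
            desc = arg.descendants_at(nid, outgroup_site)
            if not desc:
                continue
            return RecombEvent(arg.nodes[nid].breakpoint, nid, desc)
    return None


def outgroup_intervals(arg: Arg, popmap: PopulationMap) -> list[OutgroupInterval]:
    """Maximal per-population outgroup intervals with their boundary events.

    Boundary events are attached only when the defining breakpoint lies
    strictly inside the sequence span (identifiable inside the gene
    window); intervals abutting a window edge have no event on that side.
    """
    start, end = arg.sequence_span
    pieces = marginal_trees(arg)
    out: list[OutgroupInterval] = []
    for pop in popmap.populations:
        flags = [is_outgroup(tree, pop, popmap) for _, tree in pieces]
        i = 0
        while i < len(pieces):
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(pieces) and flags[j + 1]:
                j += 1
            lo = pieces[i][0][0]
            hi = pieces[j][0][1]
            iv = OutgroupInterval(pop, (lo, hi))
            if lo > start:
                iv.left_event = _boundary_event(arg, lo, outgroup_site=lo)
            if hi < end:
                iv.right_event = _boundary_event(arg, hi, outgroup_site=hi - 1)
            for ev_attr in ("left_event", "right_event"):
                ev = getattr(iv, ev_attr)
                if ev is not None:
                    setattr(iv, ev_attr, RecombEvent(
                        ev.breakpoint, ev.node_id, ev.descendants,
                        classification=classify_disrupting(ev, pop, popmap)))
            out.append(iv)
            i = j + 1
    return out


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------

def aggregate_gene(gene_id: str, replicates: list[Arg],
                   popmap: PopulationMap) -> GeneSummary:
    """Aggregate a gene's ARG replicates by majority vote.

    The outgroup identity over each site interval is decided by a strict
    majority across replicates (ties give no consensus and are dropped);
    boundary scores are averaged over the replicates whose interval agrees
    with the consensus.  Genes whose replicates disagree on the number of
    recombination events are flagged excluded and carry no consensus.
    """
    if not replicates:
        raise ValueError("need at least one ARG replicate")
    sample_sets = {tuple(a.samples) for a in replicates}
    if len(sample_sets) != 1:
        raise ValueError("replicates have differing sample sets")
    counts = {len(a.breakpoints) for a in replicates}
    agree = len(counts) == 1
    summary = GeneSummary(gene_id=gene_id, n_replicates=len(replicates),
                          replicates_agree=agree, excluded=not agree)
    if not agree:
        return summary

    span = replicates[0].sequence_span
    cuts = sorted({c for a in replicates for b in a.breakpoints
                   if span[0] < (c := b + 1) < span[1]})
    bounds = [span[0]] + cuts + [span[1]]
    per_rep = [outgroup_intervals(a, popmap) for a in replicates]
    summary.n_intervals = len(bounds) - 1

    def covering(intervals, pop, piece):
        for iv in intervals:
            if iv.population == pop and iv.interval[0] <= piece[0] and \
                    iv.interval[1] >= piece[1]:
                return iv
        return None

    half = len(replicates) / 2
    for pop in popmap.populations:
        # majority vote per elementary piece, then merge runs
        votes = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            n_yes = sum(1 for ivs in per_rep if covering(ivs, pop, (a, b)))
            votes.append(n_yes > half)
        i = 0
        while i < len(votes):
            if not votes[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(votes) and votes[j + 1]:
                j += 1
            lo, hi = bounds[i], bounds[j + 1]
            consensus = OutgroupInterval(pop, (lo, hi))
            # average boundary scores over agreeing replicates
            agreeing = [covering(ivs, pop, (lo, hi)) for ivs in per_rep]
            agreeing = [iv for iv in agreeing if iv is not None]
            for side in ("left_event", "right_event"):
                evs = [getattr(iv, side) for iv in agreeing]
                evs = [e for e in evs if e is not None]
                if not evs:
                    continue
                setattr(consensus, side, evs[0])
                score_sum: Counter = Counter()
                for e in evs:
                    score_sum.update(recombination_score(e, popmap))
                summary.mean_scores[(pop, (lo, hi), side)] = {
                    p: score_sum[p] / len(evs) for p in popmap.populations}
                labels = Counter(e.classification for e in evs)
                summary.classifications[(pop, (lo, hi), side)] = \
                    labels.most_common(1)[0][0]
            summary.consensus_intervals.append(consensus)
            i = j + 1
    return summary


def gene_table(summaries: list[GeneSummary],
               popmap: PopulationMap) -> pd.DataFrame:
    """Per-gene long-format table of consensus outgroup intervals."""
    rows = []
    for s in summaries:
        for iv in s.consensus_intervals:
            for side, ev in (("left", iv.left_event), ("right", iv.right_event)):
                key = (iv.population, iv.interval, f"{side}_event")
                row = {
                    "gene": s.gene_id,
                    "population": iv.population,
                    "start": iv.interval[0],
                    "end": iv.interval[1],
                    "side": side,
                    "classification": (
                        s.classifications.get(key, ev.classification)
                        if ev is not None else "unidentifiable"),
                }
                scores = s.mean_scores.get(
                    key,
                    recombination_score(ev, popmap) if ev is not None else {})
                for pop in popmap.populations:
                    row[f"score_{pop}"] = scores.get(pop, 0.0)
                rows.append(row)
    return pd.DataFrame(rows)


def genome_tally(summaries: list[GeneSummary],
                 popmap: PopulationMap) -> pd.DataFrame:
    """Genome-level disrupting-event tally per population.

    ``frac_outgroup`` is the fraction of non-excluded genes (loci) in which
    the population occupies the outgroup position over at least one
    interval — the per-locus outgroup frequency used to rescale the
    binomial gene-flow test.  Both the binary classification counts and
    the summed fractional attribution scores are reported.
    """
    rows = []
    n_genes = sum(1 for s in summaries if not s.excluded)
    for pop in popmap.populations:
        n_ra = n_ro = n_other = 0
        frac_score = 0.0
        for s in summaries:
            if s.excluded:
                continue
            for (p, interval, side), label in s.classifications.items():
                if p != pop:
                    continue
                if label == R_A:
                    n_ra += 1
                elif label == R_O:
                    n_ro += 1
                else:
                    n_other += 1
            for (p, interval, side), scores in s.mean_scores.items():
                if p == pop:
                    frac_score += scores.get(pop, 0.0)
        n_elem = 0
        n_genes_out = 0
        for s in summaries:
            if s.excluded:
                continue
            here = sum(1 for iv in s.consensus_intervals if iv.population == pop)
            n_elem += here
            n_genes_out += here > 0
        rows.append({
            "population": pop,
            "k": popmap.size_of(pop),
            "n_RA": n_ra,
            "n_RO": n_ro,
            "n_other": n_other,
            "score_sum": frac_score,
            "n_outgroup_intervals": n_elem,
            "n_outgroup_genes": n_genes_out,
            "n_genes": n_genes,
            "frac_outgroup": n_genes_out / n_genes if n_genes else 0.0,
        })
    return pd.DataFrame(rows)


def scan_genes(genes: list[tuple[str, list[Arg]]],
               popmap: PopulationMap) -> list[GeneSummary]:
    """Aggregate every gene's replicate ARGs; genes are (id, replicates)."""
    return [aggregate_gene(gid, reps, popmap) for gid, reps in genes]
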
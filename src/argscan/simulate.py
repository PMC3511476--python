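"""Coalescent-with-recombination simulator emitting true ARGs.

The ancestral process runs backward in time under the island model of
:class:`argscan.island.Demography`: within-deme pair coalescence at rate
1/N_d, per-lineage migration at the configured rates, deme merges at
scheduled times, an optional instantaneous admixture pulse (each lineage
in the recipient deme at the pulse time jumps to the donor deme with the
pulse probability), and crossover recombination at rate rho/2 per base of
a lineage's ancestral-material span, where rho is the population-scaled
recombination rate 4*N_ref*r per bp.  Material whose marginal genealogy is
complete (a single carrier remains) stops attracting recombination, so
every emitted breakpoint is ancestral to sampled material; lineages keep
coalescing to a single grand MRCA so the emitted graph has one root.

Mutations follow the infinite-sites model on integer site coordinates:
either a Poisson number per marginal-tree interval (rate theta/2 per bp of
branch length) or an exact target count per gene ("matching" mode, used to
mirror datasets where each gene is matched for its number of segregating
sites); in both cases sites land in intervals proportionally to tree
length and mutations hit branches proportionally to branch length.

Every stochastic choice derives from a single seed; a genome is a
collection of genes with per-gene seeds spawned from the master seed, so
any single gene can be re-simulated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arg import Arg, ArgEdge, ArgNode, PopulationMap, marginal_trees
from .island import Demography
from . import hapio


@dataclass(frozen=True)
class GenomeDesign:
    """Per-gene window design for a simulated genome."""

    n_genes: int = 200
    gene_length: int = 2000  # bp per window
    target_snps: int | None = 25  # exact segregating sites; None -> Poisson
    rho_per_bp: float = 4e-4  # population-scaled recombination rate / bp
    theta_per_bp: float = 0.01  # used when target_snps is None

    def __post_init__(self):
        if self.gene_length <= 0 or self.n_genes < 1:
            raise ValueError("need positive gene count and length")
        if self.rho_per_bp < 0:
            raise ValueError("rho must be nonnegative")


@dataclass(frozen=True)
class AdmixturePulse:
    """Instantaneous gene flow from an (unsampled) donor deme.

    Backward in time, each lineage found in the recipient deme at
    ``time`` relocates to the donor deme with probability ``fraction`` —
    the forward-time replacement of that fraction of the recipient's
    gamete pool.
    """

    recipient: int
    donor: int
    time: float
    fraction: float

    def __post_init__(self):
        if not (0 < self.fraction < 1):
            raise ValueError("pulse fraction must be in (0,1)")
        if self.time < 0:
            raise ValueError("pulse time must be nonnegative")


@dataclass
class SimulatedGene:
    gene_id: str
    arg: Arg
    node_times: dict[str, float]
    matrix: np.ndarray  # samples x sites, 0/1, rows follow arg.samples
    sites: list[int]
    length: int
    events: list[dict]  # truth log
    seed: int

    def recombination_descendants(self) -> dict[str, frozenset[str]]:
        return {e["node"]: e["descendants"] for e in self.events
                if e["type"] == "recombination"}


class _Lineage:
    __slots__ = ("node", "side", "segments", "deme", "samples", "segmap")

    def __init__(self, node, side, segments, deme, samples, segmap):
        self.node = node
        self.side = side  # edge side to attach when this lineage ends
        self.segments = segments  # carried-and-active material [(a,b), ...)
        self.deme = deme
        self.samples = samples  # union of descendant sample ids
        # site-resolved descendants: ordered (start, end, frozenset) pieces;
        # kept independently of the graph so truth logs can be checked
        # against graph traversals without circularity
        self.segmap = segmap

    def span(self):
        if not self.segments:
            return 0
        return self.segments[-1][1] - self.segments[0][0]


def _segmap_lookup(segmap, s):
    for a, b, members in segmap:
        if a <= s < b:
            return members
    return frozenset()


def _segmap_split(segmap, x):
    left, right = [], []
    for a, b, members in segmap:
        if b <= x:
            left.append((a, b, members))
        elif a >= x:
            right.append((a, b, members))
        else:
            left.append((a, x, members))
            right.append((x, b, members))
    return left, right


def _segmap_merge(m1, m2):
    cuts = sorted({a for a, _, _ in m1 + m2} | {b for _, b, _ in m1 + m2})
    out = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        members = _segmap_lookup(m1, a) | _segmap_lookup(m2, a)
        if not members:
            continue
        if out and out[-1][1] == a and out[-1][2] == members:
            out[-1] = (out[-1][0], b, members)
        else:
            out.append((a, b, members))
    return out


def _merge_segments(a, b):
    out = []
    for s in sorted(a + b):
        if out and s[0] <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], s[1]))
        else:
            out.append(s)
    return out


def _split_segments(segs, x):
    left, right = [], []
    for a, b in segs:
        if b <= x:
            left.append((a, b))
        elif a >= x:
            right.append((a, b))
        else:
            left.append((a, x))
            right.append((x, b))
    return left, right


def _subtract(segs, cut):
    """Remove interval ``cut`` from a sorted segment list."""
    ca, cb = cut
    out = []
    for a, b in segs:
        if b <= ca or a >= cb:
            out.append((a, b))
            continue
        if a < ca:
            out.append((a, ca))
        if b > cb:
            out.append((cb, b))
    return out


def simulate_gene(length: int, rho_per_bp: float, demography: Demography,
                  pulse: AdmixturePulse | None = None,
                  target_snps: int | None = 25,
                  theta_per_bp: float = 0.01,
                  seed: int = 0, gene_id: str = "gene",
                  popmap: PopulationMap | None = None) -> SimulatedGene:
    """Simulate one gene window: true ARG, truth log and SNP matrix."""
    rng = np.random.default_rng(seed)
    d = demography.n_demes
    sizes = np.asarray(demography.deme_sizes, dtype=float)
    mig = np.asarray(demography.migration, dtype=float)
    merges = list(demography.merges)
    if pulse is not None:
        if not (0 <= pulse.recipient < d and 0 <= pulse.donor < d):
            raise ValueError("pulse demes outside demography")
        if merges and pulse.time >= merges[0][0]:
            raise ValueError("pulse must predate the first deme merge")

    # sample naming: <label>_<i> per sampled deme
    leaf_ids: list[str] = []
    leaf_demes: list[int] = []
    pairs = []
    for dm, (s, lab) in enumerate(zip(demography.sample_sizes,
                                      demography.labels)):
        for i in range(s):
            sid = f"{lab}_{i + 1}"
            leaf_ids.append(sid)
            leaf_demes.append(dm)
            pairs.append((sid, lab))
    if popmap is None:
        popmap = PopulationMap.from_pairs(pairs)

    full = [(0, length)]
    lineages = [
        _Lineage(sid, None, list(full), dm, frozenset([sid]),
                 [(0, length, frozenset([sid]))])
        for sid, dm in zip(leaf_ids, leaf_demes)
    ]

    nodes: list[ArgNode] = [ArgNode(sid, "leaf", sample_id=sid)
                            for sid in leaf_ids]
    edge_list: list[tuple] = []  # (child, parent, side)
    node_times: dict[str, float] = {sid: 0.0 for sid in leaf_ids}
    events: list[dict] = []
    n_coal = n_rec = 0
    t = 0.0
    epoch = 0
    pulse_done = pulse is None
    active_mig = mig.copy()

    def mrca_update():
        """Drop material that has reached its marginal MRCA."""
        bounds = sorted({a for l in lineages for a, _ in l.segments}
                        | {b for l in lineages for _, b in l.segments})
        for a, b in zip(bounds[:-1], bounds[1:]):
            count = sum(1 for l in lineages
                        if any(sa <= a and b <= sb for sa, sb in l.segments))
            if count == 1:
                for l in lineages:
                    l.segments = _subtract(l.segments, (a, b))

    while len(lineages) > 1:
        per_deme: dict[int, list[int]] = {}
        for i, l in enumerate(lineages):
            per_deme.setdefault(l.deme, []).append(i)
        coal = sum(len(v) * (len(v) - 1) / 2 / sizes[dm]
                   for dm, v in per_deme.items())
        spans = [max(l.span() - 1, 0) for l in lineages]
        rec = rho_per_bp / 2.0 * sum(spans)
        migr = sum(active_mig[l.deme].sum() for l in lineages)
        tot = coal + rec + migr
        t_pulse = pulse.time if (pulse is not None and not pulse_done) \
            else math.inf
        t_merge = merges[epoch][0] if epoch < len(merges) else math.inf
        t_next = min(t_pulse, t_merge)
        dt = rng.exponential(1 / tot) if tot > 0 else math.inf
        if t + dt >= t_next:
            if not math.isfinite(t_next):
                raise RuntimeError("stuck ancestral process: no rates, no merges")
            t = t_next
            if t_pulse <= t_merge:
                for l in lineages:
                    if l.deme == pulse.recipient and rng.uniform() < pulse.fraction:
                        l.deme = pulse.donor
                        events.append({"type": "pulse", "time": t,
                                       "node": l.node,
                                       "descendants": l.samples})
                pulse_done = True
            else:
                _, src, dst = merges[epoch]
                for l in lineages:
                    if l.deme == src:
                        l.deme = dst
                active_mig[src, :] = 0.0
                active_mig[:, src] = 0.0
                epoch += 1
            continue
        t += dt
        u = rng.uniform() * tot
        if u < coal:
            ds = [dm for dm in per_deme if len(per_deme[dm]) >= 2]
            wts = np.array([len(per_deme[dm]) * (len(per_deme[dm]) - 1)
                            / 2 / sizes[dm] for dm in ds])
            dm = ds[rng.choice(len(ds), p=wts / wts.sum())]
            ia, ib = rng.choice(per_deme[dm], size=2, replace=False)
            la, lb = lineages[ia], lineages[ib]
            n_coal += 1
            cid = f"c{n_coal}"
            node_times[cid] = t
            nodes.append(ArgNode(cid, "coalescence"))
            edge_list.append((la.node, cid, la.side))
            edge_list.append((lb.node, cid, lb.side))
            merged = _Lineage(cid, None,
                              _merge_segments(la.segments, lb.segments), dm,
                              la.samples | lb.samples,
                              _segmap_merge(la.segmap, lb.segmap))
            lineages = [l for i, l in enumerate(lineages) if i not in (ia, ib)]
            lineages.append(merged)
            events.append({"type": "coalescence", "time": t, "node": cid,
                           "descendants": merged.samples})
            mrca_update()
        elif u < coal + rec:
            r = (u - coal) / (rho_per_bp / 2.0)
            il = 0
            acc = 0.0
            for i, sp in enumerate(spans):
                acc += sp
                if r < acc:
                    il = i
                    break
            l = lineages[il]
            lo = l.segments[0][0]
            hi = l.segments[-1][1]
            x = int(rng.integers(lo + 1, hi))  # cut between sites x-1 and x
            n_rec += 1
            rid = f"r{n_rec}"
            node_times[rid] = t
            nodes.append(ArgNode(rid, "recombination", breakpoint=x - 1))
            edge_list.append((l.node, rid, l.side))
            left, right = _split_segments(l.segments, x)
            mleft, mright = _segmap_split(l.segmap, x)
            lp = _Lineage(rid, "P", left, l.deme, l.samples, mleft)
            ls = _Lineage(rid, "S", right, l.deme, l.samples, mright)
            lineages = [ln for i, ln in enumerate(lineages) if i != il]
            lineages.extend([lp, ls])
            events.append({"type": "recombination", "time": t, "node": rid,
                           "breakpoint": x - 1,
                           "descendants": _segmap_lookup(l.segmap, x - 1),
                           "descendants_suffix": _segmap_lookup(l.segmap, x),
                           "lineage_samples": l.samples})
        else:
            r = u - coal - rec
            il = 0
            acc = 0.0
            for i, l in enumerate(lineages):
                acc += active_mig[l.deme].sum()
                if r < acc:
                    il = i
                    break
            l = lineages[il]
            row = active_mig[l.deme]
            dest = int(rng.choice(d, p=row / row.sum()))
            events.append({"type": "migration", "time": t, "node": l.node,
                           "from": l.deme, "to": dest,
                           "descendants": l.samples})
            l.deme = dest

    arg = Arg(nodes, [ArgEdge(c, p, side=s) for c, p, s in edge_list],
              (0, length), samples=tuple(leaf_ids))

    # ---- infinite-sites mutations on the marginal trees
    pieces = marginal_trees(arg)
    tree_lengths = []
    for (a, b), tree in pieces:
        tl = 0.0
        for n, cs in tree.children.items():
            for c in cs:
                tl += node_times[n] - node_times[c]
        tree_lengths.append(tl)
    weights = np.array([tl * (b - a) for ((a, b), _), tl
                        in zip(pieces, tree_lengths)])
    mut_edges: dict[tuple, list[int]] = {}
    sites: list[int] = []
    carriers_by_site: dict[int, frozenset[str]] = {}
    if weights.sum() > 0:
        if target_snps is not None:
            n_mut = target_snps
        else:
            n_mut = int(rng.poisson(theta_per_bp / 2.0 *
                                    float(np.dot(tree_lengths,
                                                 [b - a for (a, b), _ in pieces]))))
        placed = set()
        attempts = 0
        while len(placed) < n_mut and attempts < 50 * n_mut + 1000:
            attempts += 1
            pi = int(rng.choice(len(pieces), p=weights / weights.sum()))
            (a, b), tree = pieces[pi]
            s = int(rng.integers(a, b))
            if s in placed:
                continue
            # branch proportional to length
            branches = []
            blens = []
            for n, cs in tree.children.items():
                for c in cs:
                    branches.append((c, n))
                    blens.append(node_times[n] - node_times[c])
            blens_a = np.array(blens)
            bi = int(rng.choice(len(branches), p=blens_a / blens_a.sum()))
            child, par = branches[bi]
            u_t = node_times[child] + rng.uniform() * blens[bi]
            # walk the ARG chain from child up to the tree parent; the edge
            # whose time span contains u_t carries the mutation
            cur = child
            edge_key = None
            while edge_key is None:
                e = arg.parent_edge_at(cur, s)
                if e is None or node_times[e.parent] > u_t or e.parent == par:
                    if e is None:  # pragma: no cover - u_t below the root
                        raise RuntimeError("mutation time above grand MRCA")
                    edge_key = (e.child, e.parent, e.side)
                else:
                    cur = e.parent
            mut_edges.setdefault(edge_key, []).append(s)
            placed.add(s)
            carriers_by_site[s] = tree.clades()[child]
        sites = sorted(placed)

    final_edges = [ArgEdge(c, p, side=s,
                           mutations=tuple(sorted(mut_edges.get((c, p, s), []))))
                   for c, p, s in edge_list]
    arg = Arg(nodes, final_edges, (0, length), samples=tuple(leaf_ids))
    matrix = np.zeros((len(leaf_ids), len(sites)), dtype=np.int8)
    for j, s in enumerate(sites):
        for i, sid in enumerate(leaf_ids):
            if sid in carriers_by_site[s]:
                matrix[i, j] = 1
    return SimulatedGene(gene_id=gene_id, arg=arg, node_times=node_times,
                         matrix=matrix, sites=sites, length=length,
                         events=events, seed=seed)


def simulate_genome(design: GenomeDesign, demography: Demography,
                    pulse: AdmixturePulse | None = None,
                    seed: int = 0) -> tuple[list[SimulatedGene], pd.DataFrame]:
    """Simulate a multi-gene dataset with per-gene seeds from a master seed."""
    child_seeds = np.random.SeedSequence(seed).generate_state(design.n_genes)
    genes = []
    rows = []
    for g in range(design.n_genes):
        gseed = int(child_seeds[g] & 0x7FFFFFFF)
        gene = simulate_gene(
            length=design.gene_length, rho_per_bp=design.rho_per_bp,
            demography=demography, pulse=pulse,
            target_snps=design.target_snps, theta_per_bp=design.theta_per_bp,
            seed=gseed, gene_id=f"g{g + 1:04d}")
        genes.append(gene)
        rows.append({"gene": gene.gene_id, "length": gene.length,
                     "n_snps": len(gene.sites),
                     "n_recombinations": len(gene.arg.breakpoints),
                     "seed": gseed})
    return genes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-design presets
# ---------------------------------------------------------------------------

#: Conditions of the simulated-genome study: a symmetric five-island model
#: with the yeast-like sampling design (3/3/3/2/2), migration parameter 1,
#: and the sampled islands joining an ancestral panmictic pool 8 coalescent
#: units ago.  The gene-flow variant adds an admixture pulse into
#: population 1 from an isolated, unsampled sixth deme 0.5 units ago,
#: replacing 80% of the recipient gamete pool; the ghost deme rejoins the
#: ancestral pool at 20 units, deep enough that the sampled metapopulation
#: has found its common ancestor first, which is the regime in which an
#: introgressed haplotype surfaces as an outgroup clade.
DEFAULT_M = 1.0
DEFAULT_TAU = 8.0
DEFAULT_TAU_DONOR = 20.0
DEFAULT_PULSE_TIME = 0.5
DEFAULT_PULSE_FRACTION = 0.8


def model_i_demography(M: float = DEFAULT_M,
                       tau: float = DEFAULT_TAU,
                       samples=(3, 3, 3, 2, 2)) -> Demography:
    """Null model: symmetric five-island, panmictic beyond ``tau``."""
    return Demography.symmetric_island(d=len(samples), M=M, samples=samples,
                                       merge_time=tau)


def model_ii_demography(M: float = DEFAULT_M, tau: float = DEFAULT_TAU,
                        tau_donor: float = DEFAULT_TAU_DONOR,
                        samples=(3, 3, 3, 2, 2)
                        ) -> tuple[Demography, AdmixturePulse]:
    """Gene-flow model: model (i) plus a pulse from an unsampled 6th deme.

    The sampled islands merge into the ancestral pool at ``tau``; the
    donor deme stays isolated until ``tau_donor``.
    """
    d = len(samples)
    rate = 0.5 * M / (d - 1)
    mig = [[0.0] * (d + 1) for _ in range(d + 1)]
    for i in range(d):
        for j in range(d):
            if i != j:
                mig[i][j] = rate
    merges = sorted([(tau, i, 0) for i in range(1, d)] + [(tau_donor, d, 0)])
    demo = Demography(
        deme_sizes=(1.0,) * (d + 1),
        migration=tuple(tuple(r) for r in mig),
        sample_sizes=tuple(samples) + (0,),
        labels=tuple(f"pop{i + 1}" for i in range(d)) + ("ghost",),
        merges=tuple(merges))
    return demo, AdmixturePulse(recipient=0, donor=d,
                                time=DEFAULT_PULSE_TIME,
                                fraction=DEFAULT_PULSE_FRACTION)


def truth_log_frame(gene: SimulatedGene) -> pd.DataFrame:
    rows = []
    for e in gene.events:
        rows.append({
            "gene": gene.gene_id,
            "type": e["type"],
            "time": e["time"],
            "node": e.get("node", ""),
            "breakpoint": e.get("breakpoint", ""),
            "descendants": ",".join(sorted(e.get("descendants", ()))),
        })
    return pd.DataFrame(rows)


def write_ms_block(gene: SimulatedGene, path_or_file) -> None:
    hapio.write_ms(gene.matrix, gene.sites, gene.length, path_or_file,
                   header=f"// gene={gene.gene_id} seed={gene.seed}")
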
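"""Ancestral recombination graph (ARG) data structures and I/O.

An ARG encodes the genealogical history of a sample of recombining
sequences.  Leaves are sampled haplotypes; internal nodes are coalescences;
recombination nodes carry a breakpoint and have two parents, a *prefix*
parent (edge side ``P``) governing sites up to and including the breakpoint
and a *suffix* parent (side ``S``) governing sites downstream.  At every
site the ARG induces a marginal genealogy ("local tree") obtained by
routing each lineage through the appropriate parent at each recombination
node and contracting the nodes that become unary.

Coordinates are 0-based half-open internally.  The kwarg-style dot dialect
uses 1-based inclusive coordinates and is converted on read: a dot
breakpoint ``c`` becomes the internal breakpoint ``c - 1``, so the prefix
side governs internal sites ``s <= c - 1`` (the half-open interval
``[start, c)``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class ArgError(ValueError):
    """Structural problem in an ARG; carries the offending node when known."""

    def __init__(self, message: str, node: str | None = None):
        super().__init__(message if node is None else f"{message} (node {node!r})")
        self.node = node


@dataclass(frozen=True)
class ArgNode:
    id: str
    kind: str  # 'leaf' | 'coalescence' | 'recombination'
    breakpoint: int | None = None  # recombination nodes only (internal coords)
    sample_id: str | None = None  # leaves only

    def __post_init__(self):
        if (self.kind == "recombination") != (self.breakpoint is not None):
            raise ArgError("breakpoint present iff kind=recombination", self.id)
        if (self.kind == "leaf") != (self.sample_id is not None):
            raise ArgError("sample_id present iff kind=leaf", self.id)


@dataclass(frozen=True)
class ArgEdge:
    child: str
    parent: str
    side: str | None = None  # 'P' | 'S' for recombination children, else None
    mutations: tuple[int, ...] = ()


@dataclass(frozen=True)
class PopulationMap:
    """Sample-to-population assignment with a stable population order."""

    mapping: Mapping[str, str]
    populations: tuple[str, ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PopulationMap":
        mapping = dict(pairs)
        pops: list[str] = []
        for p in mapping.values():
            if p not in pops:
                pops.append(p)
        return cls(mapping=mapping, populations=tuple(pops))

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sample, pop = line.split("\t")[:2]
                pairs.append((sample, pop))
        return cls.from_pairs(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.mapping.items():
                fh.write(f"{s}\t{p}\n")

    def population_of(self, sample: str) -> str:
        return self.mapping[sample]

    def samples_of(self, population: str) -> frozenset[str]:
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        return frozenset(s for s, p in self.mapping.items() if p == population)

    def size_of(self, population: str) -> int:
        return len(self.samples_of(population))


class LocalTree:
    """Marginal genealogy of the sample over one site interval.

    ``children`` maps every internal node to its child nodes after unary
    contraction; ``leaf_samples`` maps leaf node ids to sample ids.
    """

    def __init__(self, root: str, children: Mapping[str, tuple[str, ...]],
                 leaf_samples: Mapping[str, str],
                 interval: tuple[int, int] | None = None):
        self.root = root
        self.children = dict(children)
        self.leaf_samples = dict(leaf_samples)
        self.interval = interval
        self._clades: dict[str, frozenset[str]] | None = None

    def clades(self) -> dict[str, frozenset[str]]:
        """Leaf-sample set subtended by every node of the tree."""
        if self._clades is None:
            out: dict[str, frozenset[str]] = {}

            def rec(n: str) -> frozenset[str]:
                if n in self.leaf_samples:
                    out[n] = frozenset([self.leaf_samples[n]])
                else:
                    acc: frozenset[str] = frozenset()
                    for c in self.children[n]:
                        acc = acc | rec(c)
                    out[n] = acc
                return out[n]

            rec(self.root)
            self._clades = out
        return self._clades

    @property
    def samples(self) -> frozenset[str]:
        return self.clades()[self.root]

    def root_child_leafsets(self) -> list[frozenset[str]]:
        clades = self.clades()
        return [clades[c] for c in self.children[self.root]]

    def signature(self) -> frozenset[frozenset[str]]:
        """Topology signature: the multiset of clades (as a frozen set)."""
        return frozenset(self.clades().values())

    def __eq__(self, other):
        return isinstance(other, LocalTree) and self.signature() == other.signature()

    def __hash__(self):
        return hash(self.signature())


class Arg:
    """Validated ancestral recombination graph.

    Parameters
    ----------
    nodes, edges
        Node and edge collections.  Node kinds are checked against the
        edge structure: recombination nodes must have exactly one ``P`` and
        one ``S`` parent edge, other non-root nodes exactly one unlabeled
        parent edge, and exactly one node (the grand MRCA) none.
    sequence_span
        Half-open ``[start, end)`` interval of sites the graph covers.
    samples
        Optional explicit sample order; defaults to sorted leaf sample ids.
    """

    def __init__(self, nodes: Iterable[ArgNode], edges: Iterable[ArgEdge],
                 sequence_span: tuple[int, int],
                 samples: Sequence[str] | None = None):
        self.nodes: dict[str, ArgNode] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise ArgError("duplicate node id", n.id)
            self.nodes[n.id] = n
        self.edges: tuple[ArgEdge, ...] = tuple(edges)
        self.sequence_span = (int(sequence_span[0]), int(sequence_span[1]))
        self._parents: dict[str, list[ArgEdge]] = {nid: [] for nid in self.nodes}
        self._children: dict[str, list[ArgEdge]] = {nid: [] for nid in self.nodes}
        for e in self.edges:
            if e.child not in self.nodes or e.parent not in self.nodes:
                raise ArgError(f"edge {e.child}->{e.parent} references unknown node")
            self._parents[e.child].append(e)
            self._children[e.parent].append(e)
        leaf_ids = [nid for nid, n in self.nodes.items() if n.kind == "leaf"]
        if samples is None:
            samples = sorted(self.nodes[nid].sample_id for nid in leaf_ids)
        self.samples: tuple[str, ...] = tuple(samples)
        self._leaf_of_sample = {self.nodes[nid].sample_id: nid for nid in leaf_ids}
        self.validate()

    # -- structure ---------------------------------------------------------

    def parents_of(self, node_id: str) -> list[ArgEdge]:
        return self._parents[node_id]

    def children_of(self, node_id: str) -> list[ArgEdge]:
        return self._children[node_id]

    @property
    def root(self) -> str:
        return self._root

    @property
    def leaves(self) -> list[str]:
        return [self._leaf_of_sample[s] for s in self.samples]

    @property
    def breakpoints(self) -> list[int]:
        return sorted(n.breakpoint for n in self.nodes.values()
                      if n.kind == "recombination")

    @property
    def recombination_nodes(self) -> list[str]:
        out = [nid for nid, n in self.nodes.items() if n.kind == "recombination"]
        return sorted(out, key=lambda nid: (self.nodes[nid].breakpoint, nid))

    @property
    def multifurcating_nodes(self) -> list[str]:
        return [nid for nid in self.nodes if len(self._children[nid]) > 2]

    def validate(self) -> None:
        start, end = self.sequence_span
        if not end > start:
            raise ArgError("empty sequence span")
        roots = [nid for nid in self.nodes if not self._parents[nid]]
        if len(roots) != 1:
            raise ArgError(f"expected exactly one root, found {sorted(roots)}")
        self._root = roots[0]
        n_leaves = 0
        for nid, node in self.nodes.items():
            pedges = self._parents[nid]
            if node.kind == "recombination":
                sides = sorted(e.side or "" for e in pedges)
                if sides != ["P", "S"]:
                    raise ArgError("recombination node needs one P and one S parent",
                                   nid)
                if not (start <= node.breakpoint <= end - 2):
                    raise ArgError(
                        f"breakpoint {node.breakpoint} not strictly inside span "
                        f"[{start},{end})", nid)
                if not self._children[nid]:
                    raise ArgError("recombination node has no child", nid)
            else:
                if nid != self._root and len(pedges) != 1:
                    raise ArgError("non-recombination node needs one parent", nid)
                if any(e.side for e in pedges):
                    raise ArgError("side label on non-recombination child", nid)
            if node.kind == "leaf":
                n_leaves += 1
                if self._children[nid]:
                    raise ArgError("leaf has children", nid)
            elif not self._children[nid]:
                raise ArgError("internal node has no children", nid)
        if n_leaves != len(self.samples):
            raise ArgError(f"{n_leaves} leaves != {len(self.samples)} samples")
        # acyclicity via Kahn's algorithm on child->parent edges
        indeg = {nid: len(self._children[nid]) for nid in self.nodes}
        queue = [nid for nid, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            nid = queue.pop()
            seen += 1
            for e in self._parents[nid]:
                indeg[e.parent] -= 1
                if indeg[e.parent] == 0:
                    queue.append(e.parent)
        if seen != len(self.nodes):
            raise ArgError("graph contains a cycle")

    # -- marginal genealogies ----------------------------------------------

    def parent_edge_at(self, node_id: str, site: int) -> ArgEdge | None:
        """Parent edge followed at ``site``; None at the grand MRCA."""
        node = self.nodes[node_id]
        pedges = self._parents[node_id]
        if not pedges:
            return None
        if node.kind != "recombination":
            return pedges[0]
        want = "P" if site <= node.breakpoint else "S"
        for e in pedges:
            if e.side == want:
                return e
        raise ArgError("missing side", node_id)  # pragma: no cover

    def descendants_at(self, node_id: str, site: int) -> frozenset[str]:
        """Samples reachable downward from ``node_id`` in the site's tree."""
        out: set[str] = set()
        stack = [node_id]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            if node.kind == "leaf":
                out.add(node.sample_id)
                continue
            for e in self._children[nid]:
                child = self.nodes[e.child]
                if child.kind == "recombination":
                    if self.parent_edge_at(e.child, site) is not e:
                        continue
                stack.append(e.child)
        return frozenset(out)


def local_tree(arg: Arg, site: int) -> LocalTree:
    """Marginal genealogy at ``site``.

    Follows the prefix parent at each recombination node iff
    ``site <= breakpoint``, contracts unary nodes, and roots the tree at the
    most recent node ancestral to the whole sample at this site (which may
    lie below the grand MRCA of the ARG).
    """
    start, end = arg.sequence_span
    if not (start <= site < end):
        raise ArgError(f"site {site} outside span [{start},{end})")
    parent: dict[str, str | None] = {}
    for nid in arg.nodes:
        e = arg.parent_edge_at(nid, site)
        parent[nid] = e.parent if e is not None else None
    desc: dict[str, set[str]] = {nid: set() for nid in arg.nodes}
    for leaf in arg.leaves:
        sid = arg.nodes[leaf].sample_id
        nid: str | None = leaf
        while nid is not None:
            desc[nid].add(sid)
            nid = parent[nid]
    all_samples = set(arg.samples)
    full = [nid for nid in arg.nodes if desc[nid] == all_samples]
    # the most recent common ancestor is the full node none of whose
    # site-tree children is itself full
    kids: dict[str, list[str]] = {nid: [] for nid in arg.nodes}
    for nid, p in parent.items():
        if p is not None and desc[nid]:
            kids[p].append(nid)
    root = None
    for nid in full:
        if not any(desc[c] == all_samples for c in kids[nid]):
            root = nid
            break
    if root is None:  # pragma: no cover
        raise ArgError("no marginal root found")

    def splice(nid: str) -> str:
        while arg.nodes[nid].kind != "leaf":
            effective = [c for c in kids[nid] if desc[c]]
            if len(effective) != 1:
                break
            nid = effective[0]
        return nid

    children: dict[str, tuple[str, ...]] = {}
    leaf_samples: dict[str, str] = {}
    stack = [splice(root)]
    root = stack[0]
    while stack:
        nid = stack.pop()
        node = arg.nodes[nid]
        if node.kind == "leaf":
            leaf_samples[nid] = node.sample_id
            continue
        cs = tuple(sorted(splice(c) for c in kids[nid] if desc[c]))
        children[nid] = cs
        stack.extend(cs)
    return LocalTree(root, children, leaf_samples, interval=(start, end))


def marginal_trees(arg: Arg) -> list[tuple[tuple[int, int], LocalTree]]:
    """Ordered ``(interval, tree)`` pairs partitioning the sequence span.

    Interval boundaries are exactly the breakpoints that change the
    marginal genealogy; breakpoints with no topological effect are merged
    into their neighbours.
    """
    start, end = arg.sequence_span
    cuts = sorted({b + 1 for b in arg.breakpoints if start < b + 1 < end})
    bounds = [start] + cuts + [end]
    out: list[tuple[tuple[int, int], LocalTree]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        tree = local_tree(arg, a)
        if out and out[-1][1] == tree:
            prev_iv, prev_tree = out.pop()
            a = prev_iv[0]
            tree = prev_tree
        tree.interval = (a, b)
        out.append(((a, b), tree))
    return out


# ---------------------------------------------------------------------------
# kwarg-style dot dialect reader
# ---------------------------------------------------------------------------

_NODE_RE = re.compile(r"^\s*\"?([\w.+-]+)\"?\s*\[(.*)\]\s*;?\s*$")
_EDGE_RE = re.compile(r"^\s*\"?([\w.+-]+)\"?\s*->\s*\"?([\w.+-]+)\"?\s*(?:\[(.*)\])?\s*;?\s*$")
_ATTR_RE = re.compile(r"(\w+)\s*=\s*(\"[^\"]*\"|[\w.+-]+)")
_GRAPH_ATTR_RE = re.compile(r"^\s*(\w+)\s*=\s*(\"[^\"]*\"|[\w.+-]+)\s*;?\s*$")


def _attrs(text: str | None) -> dict[str, str]:
    if not text:
        return {}
    return {k: v.strip('"') for k, v in _ATTR_RE.findall(text)}


def parse_kwarg_dot(text: str) -> Arg:
    """Read an ARG from the kwarg-style dot dialect.

    The reader is deliberately tolerant about where information lives:

    * a node is a recombination vertex if it is drawn as an ellipse
      (``shape=ellipse``), carries a ``breakpoint`` attribute, or ends up
      with two parent edges labeled ``P`` and ``S``; its breakpoint is the
      ``breakpoint`` attribute or the integer in its label/name;
    * edge ``P``/``S`` sides come from a ``side`` attribute or from a
      leading ``P``/``S`` token in the edge label;
    * edge mutation lists come from a ``mutations`` attribute or from the
      remaining integers in the edge label;
    * edges may point child-to-parent or parent-to-child; the orientation
      is auto-detected from which direction yields a single sink.

    All coordinates are 1-based inclusive in the file and converted to the
    internal 0-based half-open convention.
    """
    node_attrs: dict[str, dict[str, str]] = {}
    raw_edges: list[tuple[str, str, dict[str, str]]] = []
    graph_attrs: dict[str, str] = {}
    # normalize: drop the digraph header/braces, one statement per line
    body = re.sub(r"^\s*(?:strict\s+)?(?:di)?graph\b[^{]*\{", "", text,
                  flags=re.S).rsplit("}", 1)[0]
    statements = []
    for line in body.splitlines():
        depth = 0
        cur = []
        for ch in line:
            if ch == "[":
                depth += 1
            elif ch == "]":
                depth -= 1
            if ch == ";" and depth == 0:
                statements.append("".join(cur))
                cur = []
            else:
                cur.append(ch)
        statements.append("".join(cur))
    for line in statements:
        stripped = line.strip()
        if not stripped or stripped.startswith(("//", "#")):
            continue
        m = _EDGE_RE.match(line)
        if m:
            raw_edges.append((m.group(1), m.group(2), _attrs(m.group(3))))
            continue
        m = _NODE_RE.match(line)
        if m:
            node_attrs.setdefault(m.group(1), {}).update(_attrs(m.group(2)))
            continue
        m = _GRAPH_ATTR_RE.match(stripped)
        if m:
            graph_attrs[m.group(1)] = m.group(2).strip('"')
    if not raw_edges:
        raise ArgError("no edges found in dot input")
    names = set(node_attrs)
    for a, b, _ in raw_edges:
        names.update((a, b))
    # orientation: child->parent means exactly one sink (the grand MRCA)
    out_deg = {n: 0 for n in names}
    in_deg = {n: 0 for n in names}
    for a, b, _ in raw_edges:
        out_deg[a] += 1
        in_deg[b] += 1
    sinks = sum(1 for n in names if out_deg[n] == 0)
    sources = sum(1 for n in names if in_deg[n] == 0)
    flip = sinks != 1 and sources == 1
    edges_cp = [((b, a, at) if flip else (a, b, at)) for a, b, at in raw_edges]

    parents: dict[str, list[tuple[str, dict[str, str]]]] = {n: [] for n in names}
    children: dict[str, list[str]] = {n: [] for n in names}
    for c, p, at in edges_cp:
        parents[c].append((p, at))
        children[p].append(c)

    def label_ints(s: str) -> list[int]:
        return [int(tok) for tok in re.findall(r"\d+", s)]

    def edge_side(at: dict[str, str]) -> str | None:
        if "side" in at:
            return at["side"].upper()
        lab = at.get("label", "")
        m = re.match(r"\s*([PpSs])\b", lab)
        return m.group(1).upper() if m else None

    arg_nodes: list[ArgNode] = []
    arg_edges: list[ArgEdge] = []
    max_coord = 0
    for n in sorted(names):
        at = node_attrs.get(n, {})
        label = at.get("label", n)
        pedges = parents[n]
        sides = sorted(filter(None, (edge_side(a) for _, a in pedges)))
        is_rec = (at.get("shape", "").lower() == "ellipse"
                  or "breakpoint" in at
                  or at.get("type", "").lower() == "recombination"
                  or (len(pedges) == 2 and sides == ["P", "S"]))
        if is_rec:
            if len(pedges) != 2 or sides != ["P", "S"]:
                raise ArgError("recombination node needs one P and one S parent", n)
            if "breakpoint" in at:
                coord = int(at["breakpoint"])
            else:
                ints = label_ints(label) or label_ints(n)
                if not ints:
                    raise ArgError("recombination node without breakpoint", n)
                coord = ints[0]
            max_coord = max(max_coord, coord)
            arg_nodes.append(ArgNode(n, "recombination", breakpoint=coord - 1))
        elif not children[n]:
            arg_nodes.append(ArgNode(n, "leaf", sample_id=at.get("sample", label)))
        else:
            if len(pedges) > 1:
                raise ArgError("coalescence node with multiple parents", n)
            arg_nodes.append(ArgNode(n, "coalescence"))
    node_kind = {nd.id: nd.kind for nd in arg_nodes}
    for c, p, at in edges_cp:
        if "mutations" in at:
            muts = label_ints(at["mutations"])
        else:
            lab = at.get("label", "")
            lab = re.sub(r"^\s*[PpSs]\b[:,]?", "", lab)
            muts = label_ints(lab)
        if muts:
            max_coord = max(max_coord, max(muts))
        side = edge_side(at)
        if side and node_kind[c] != "recombination":
            raise ArgError("P/S side label on a non-recombination child", c)
        if node_kind[c] != "recombination":
            side = None
        arg_edges.append(ArgEdge(c, p, side=side,
                                 mutations=tuple(m - 1 for m in muts)))
    if "span" in graph_attrs:
        a, b = re.findall(r"\d+", graph_attrs["span"])[:2]
        span = (int(a) - 1, int(b))
    else:
        span = (0, max_coord + 1)
    return Arg(arg_nodes, arg_edges, span)


# ---------------------------------------------------------------------------
# internal tabular format (bit-exact round trip)
# ---------------------------------------------------------------------------

def write_arg(arg: Arg, path_or_file) -> None:
    """Write the internal tabular ARG format (one edge per line)."""
    close = False
    fh = path_or_file
    if not hasattr(fh, "write"):
        fh = open(fh, "w")
        close = True
    try:
        fh.write("# argscan ARG v1\n")
        fh.write(f"# span {arg.sequence_span[0]} {arg.sequence_span[1]}\n")
        fh.write("# samples " + " ".join(arg.samples) + "\n")
        for nid in sorted(arg.nodes):
            n = arg.nodes[nid]
            extra = ""
            if n.kind == "recombination":
                extra = f" breakpoint={n.breakpoint}"
            elif n.kind == "leaf":
                extra = f" sample={n.sample_id}"
            fh.write(f"# node {nid} {n.kind}{extra}\n")
        for e in sorted(arg.edges, key=lambda e: (e.child, e.parent, e.side or "")):
            muts = ",".join(map(str, e.mutations)) or "."
            fh.write(f"{e.child}\t{e.parent}\t{e.side or '.'}\t{muts}\n")
    finally:
        if close:
            fh.close()


def read_arg(path_or_file) -> Arg:
    """Read the internal tabular ARG format written by :func:`write_arg`."""
    close = False
    fh = path_or_file
    if not hasattr(fh, "read"):
        fh = open(fh)
        close = True
    try:
        span = None
        samples: list[str] | None = None
        nodes: list[ArgNode] = []
        edges: list[ArgEdge] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                toks = line[1:].split()
                if not toks:
                    continue
                if toks[0] == "span":
                    span = (int(toks[1]), int(toks[2]))
                elif toks[0] == "samples":
                    samples = toks[1:]
                elif toks[0] == "node":
                    nid, kind = toks[1], toks[2]
                    kw: dict = {}
                    for t in toks[3:]:
                        k, v = t.split("=", 1)
                        kw[k] = int(v) if k == "breakpoint" else v
                    nodes.append(ArgNode(nid, kind,
                                         breakpoint=kw.get("breakpoint"),
                                         sample_id=kw.get("sample")))
                continue
            child, parent, side, muts = line.split("\t")
            edges.append(ArgEdge(
                child, parent,
                side=None if side == "." else side,
                mutations=() if muts == "." else tuple(map(int, muts.split(",")))))
        if span is None:
            raise ArgError("missing span header")
        return Arg(nodes, edges, span, samples=samples)
    finally:
        if close:
            fh.close()
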
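"""Shared fixtures: hand-built ARGs, population maps, small simulations."""

import pytest

from argscan.arg import Arg, ArgEdge, ArgNode, PopulationMap

# A synthetic stand-in for a kwarg-style dot file (the published per-gene
# reconstructions are not shipped here): seven haplotypes from five yeast
# populations, two recombination vertices at 1-based breakpoints 91000 and
# 94864, arranged so the wine/European triple forms an outgroup exactly
# downstream of position 94864.  Coordinates are 1-based inclusive, span
# 90001..96000; one mutation is annotated at site 95102.
SYNTHETIC_DOT = """
digraph G {
  span = "90001:96000";
  we1 [label="we1"];
  we2 [label="we2"];
  we3 [label="we3"];
  na1 [label="na1"];
  sk1 [label="sk1"];
  wa1 [label="wa1"];
  my1 [label="my1"];
  R1 [shape=ellipse, label="94864"];
  R2 [shape=ellipse, label="91000"];
  we1 -> c1;
  we2 -> c1;
  c1 -> c2;
  we3 -> c2;
  c2 -> R1;
  R1 -> c3 [label="P"];
  R1 -> r [label="S 95102"];
  na1 -> c3;
  c3 -> c4;
  sk1 -> c4;
  wa1 -> R2;
  R2 -> c5 [label="P"];
  R2 -> c7 [label="S"];
  my1 -> c5;
  c4 -> c6;
  c5 -> c6;
  c6 -> c7;
  c7 -> r;
}
"""


@pytest.fixture(scope="session")
def synthetic_dot_text():
    return SYNTHETIC_DOT


@pytest.fixture(scope="session")
def yeast_popmap():
    return PopulationMap.from_pairs([
        ("we1", "WE"), ("we2", "WE"), ("we3", "WE"),
        ("na1", "NA"), ("sk1", "SK"), ("wa1", "WA"), ("my1", "MY"),
    ])


def three_leaf_arg(breakpoint: int = 49, span=(0, 100)) -> Arg:
    """Three leaves, one recombination on leaf c's lineage.

    Prefix side: ((a, c), b); suffix side: ((a, b), c) — the recombinant
    lineage c re-attaches at the root across the breakpoint.
    """
    nodes = [
        ArgNode("a", "leaf", sample_id="a"),
        ArgNode("b", "leaf", sample_id="b"),
        ArgNode("c", "leaf", sample_id="c"),
        ArgNode("R", "recombination", breakpoint=breakpoint),
        ArgNode("x", "coalescence"),
        ArgNode("y", "coalescence"),
        ArgNode("root", "coalescence"),
    ]
    edges = [
        ArgEdge("c", "R"),
        ArgEdge("R", "x", side="P"),
        ArgEdge("R", "root", side="S"),
        ArgEdge("a", "x"),
        ArgEdge("x", "y"),
        ArgEdge("b", "y"),
        ArgEdge("y", "root"),
    ]
    return Arg(nodes, edges, span)


@pytest.fixture
def toy_arg():
    return three_leaf_arg()


@pytest.fixture(scope="session")
def no_recomb_arg():
    """Balanced four-leaf genealogy without recombination."""
    nodes = [ArgNode(s, "leaf", sample_id=s) for s in "abcd"] + [
        ArgNode("u", "coalescence"),
        ArgNode("v", "coalescence"),
        ArgNode("root", "coalescence"),
    ]
    edges = [ArgEdge("a", "u"), ArgEdge("b", "u"),
             ArgEdge("c", "v"), ArgEdge("d", "v"),
             ArgEdge("u", "root", mutations=(10, 20)),
             ArgEdge("v", "root")]
    return Arg(nodes, edges, (0, 100))
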
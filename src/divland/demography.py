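"""Dated species trees with per-branch effective sizes.

The tree is the backbone of every other module: branches carry lengths in
generations and diploid effective population sizes, tips carry sample
counts.  Landscape statistics (within-population diversity, between-
population divergence) are anchored to tree nodes via the most recent
common ancestor (MRCA) of their taxa, and the phylogenetic distance
``dT`` between two statistics is the path length, in generations, between
their anchor nodes.  For two diversities of sister populations that split
``T`` generations ago, ``dT = 2T``; for a diversity of population W
against a divergence whose MRCA sits ``T_anc`` generations back,
``dT = 2*T_anc - T_W_node`` — e.g. ``dT(pi_W, d_XY) = 2*T_VWXY - T_XY``
on a four-taxon tree.

Serialization is Newick for the topology and branch lengths plus a
sidecar tab-delimited table mapping branch names to effective sizes and
tips to sample counts, because Newick has no standard Ne annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "SpeciesTree",
    "StatDescriptor",
    "diversity",
    "divergence",
    "mrca",
    "phylo_distance",
    "shares_branches",
    "coalesce_before_split",
    "great_apes_tree",
]


class TreeError(ValueError):
    """Invalid tree structure or unknown population name."""


@dataclass
class _Node:
    name: str
    parent: str | None
    length: float  # generations on the edge above this node (0 for root)
    ne: float  # diploid Ne of the edge above (root: ancestral population)
    children: list[str] = field(default_factory=list)
    samples: int | None = None  # diploid sample count, tips only
    time: float = 0.0  # generations before present


class SpeciesTree:
    """Rooted, ultrametric (in time) species tree.

    Parameters
    ----------
    nodes
        Mapping of node name to ``(parent, length, ne, samples)``; the
        root has ``parent=None`` and ``length=0``.  Convenience
        constructors :meth:`from_newick` and :meth:`from_files` are the
        usual entry points.
    """

    def __init__(self, nodes: Mapping[str, tuple[str | None, float, float, int | None]]):
        self._nodes: dict[str, _Node] = {}
        root = None
        for name, (parent, length, ne, samples) in nodes.items():
            if length < 0:
                raise TreeError(f"negative branch length on {name!r}")
            if ne <= 0:
                raise TreeError(f"non-positive Ne on {name!r}")
            self._nodes[name] = _Node(name, parent, float(length), float(ne), samples=samples)
            if parent is None:
                if root is not None:
                    raise TreeError("multiple roots")
                root = name
        if root is None:
            raise TreeError("no root node")
        self.root = root
        for n in self._nodes.values():
            if n.parent is not None:
                if n.parent not in self._nodes:
                    raise TreeError(f"unknown parent {n.parent!r} of {n.name!r}")
                self._nodes[n.parent].children.append(n.name)
        self._set_times()
        # reachability
        seen = set()
        stack = [self.root]
        while stack:
            x = stack.pop()
            seen.add(x)
            stack.extend(self._nodes[x].children)
        if seen != set(self._nodes):
            raise TreeError("nodes unreachable from root")

    def _set_times(self) -> None:
        # tips at time 0; node time = max over tips below of summed lengths
        def depth(name: str) -> float:
            n = self._nodes[name]
            if not n.children:
                return 0.0
            ds = [depth(c) + self._nodes[c].length for c in n.children]
            if max(ds) - min(ds) > 1e-6 * max(max(ds), 1.0):
                raise TreeError(f"tree not ultrametric below {name!r}: {ds}")
            return max(ds)

        for name in self._nodes:
            self._nodes[name].time = depth(name)

    # -- basic accessors ------------------------------------------------
    @property
    def tips(self) -> list[str]:
        return [n.name for n in self._nodes.values() if not n.children]

    @property
    def node_names(self) -> list[str]:
        return list(self._nodes)

    def is_tip(self, name: str) -> bool:
        return not self._nodes[name].children

    def children(self, name: str) -> list[str]:
        return list(self._nodes[name].children)

    def parent(self, name: str) -> str | None:
        return self._nodes[name].parent

    def branch_length(self, name: str) -> float:
        return self._nodes[name].length

    def ne(self, name: str) -> float:
        """Diploid Ne of the branch above ``name`` (ancestral Ne at the root)."""
        return self._nodes[name].ne

    def samples(self, name: str) -> int:
        n = self._nodes[name]
        if n.samples is None:
            raise TreeError(f"{name!r} has no sample count")
        return n.samples

    def sample_counts(self) -> dict[str, int]:
        return {t: self.samples(t) for t in self.tips if self._nodes[t].samples is not None}

    def node_time(self, name: str) -> float:
        """Generations before present of a node."""
        try:
            return self._nodes[name].time
        except KeyError:
            raise TreeError(f"unknown node {name!r}") from None

    def path_to_root(self, name: str) -> list[str]:
        if name not in self._nodes:
            raise TreeError(f"unknown node {name!r}")
        out = [name]
        while (p := self._nodes[out[-1]].parent) is not None:
            out.append(p)
        return out

    def split_time(self, a: str, b: str) -> float:
        """Generations before present of the MRCA of two tips."""
        return self.node_time(self.mrca({a, b}))

    # -- MRCA and distances ---------------------------------------------
    def mrca(self, pops: Iterable[str]) -> str:
        pops = list(pops)
        if not pops:
            raise TreeError("mrca of empty set")
        paths = [self.path_to_root(p) for p in pops]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # lowest = first common node walking up from any member
        for node in paths[0]:
            if node in common:
                return node
        raise TreeError("no common ancestor")  # pragma: no cover

    def distance(self, a: str, b: str) -> float:
        """Path length in generations between two nodes."""
        if a == b:
            return 0.0
        ta, tb, tm = self.node_time(a), self.node_time(b), self.node_time(self.mrca({a, b}))
        return (tm - ta) + (tm - tb)

    # -- serialization ---------------------------------------------------
    @classmethod
    def from_newick(
        cls,
        newick: str,
        ne: Mapping[str, float],
        samples: Mapping[str, int] | None = None,
        generation_time: float = 1.0,
    ) -> "SpeciesTree":
        """Build from a Newick string plus per-branch Ne (and tip sample counts).

        ``generation_time`` divides the Newick branch lengths, for trees
        whose lengths are in years rather than generations.
        """
        t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        nodes: dict[str, tuple[str | None, float, float, int | None]] = {}
        counter = [0]

        def name_of(nd) -> str:
            if nd.taxon is not None and nd.taxon.label:
                return nd.taxon.label.replace(" ", "_")
            if nd.label:
                return nd.label
            counter[0] += 1
            nd.label = f"node{counter[0]}"
            return nd.label

        for nd in t.preorder_node_iter():
            name = name_of(nd)
            parent = name_of(nd.parent_node) if nd.parent_node is not None else None
            length = (nd.edge.length or 0.0) / generation_time
            if name not in ne:
                raise TreeError(f"no Ne for branch {name!r}")
            samp = None
            if nd.is_leaf() and samples is not None:
                samp = samples.get(name)
            nodes[name] = (parent, length, float(ne[name]), samp)
        return cls(nodes)

    @classmethod
    def from_files(cls, newick_path: str, params_path: str, generation_time: float = 1.0) -> "SpeciesTree":
        """Read Newick file + branch-parameter TSV (columns: branch, ne, samples)."""
        with open(newick_path) as fh:
            newick = fh.read()
        df = pd.read_csv(params_path, sep="\t")
        ne = dict(zip(df["branch"], df["ne"]))
        samples = {
            b: int(s)
            for b, s in zip(df["branch"], df["samples"])
            if pd.notna(s) and str(s) not in ("", "NA")
        }
        return cls.from_newick(newick, ne, samples, generation_time=generation_time)

    def to_newick(self) -> str:
        def rec(name: str) -> str:
            n = self._nodes[name]
            if not n.children:
                core = name
            else:
                core = "(" + ",".join(rec(c) for c in n.children) + ")" + name
            if n.parent is None:
                return core
            return f"{core}:{n.length:g}"

        return rec(self.root) + ";"

    def to_files(self, newick_path: str, params_path: str) -> None:
        with open(newick_path, "w") as fh:
            fh.write(self.to_newick() + "\n")
        rows = []
        for name in sorted(self._nodes):
            n = self._nodes[name]
            rows.append(
                {"branch": name, "ne": n.ne, "samples": n.samples if n.samples is not None else ""}
            )
        pd.DataFrame(rows).to_csv(params_path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({len(self.tips)} tips, root={self.root!r})"


@dataclass(frozen=True)
class StatDescriptor:
    """Label of a landscape statistic: diversity of one population or
    divergence of an unordered pair."""

    kind: str  # "diversity" | "divergence"
    taxa: frozenset

    def __post_init__(self):
        if self.kind not in ("diversity", "divergence"):
            raise ValueError(f"bad kind {self.kind!r}")
        n = len(self.taxa)
        if self.kind == "diversity" and n != 1:
            raise ValueError("diversity takes exactly one population")
        if self.kind == "divergence" and n != 2:
            raise ValueError("divergence takes two distinct populations")

    def validate(self, tree: SpeciesTree) -> None:
        for t in self.taxa:
            if t not in tree.node_names or not tree.is_tip(t):
                raise TreeError(f"{t!r} is not a tip of the tree")

    @property
    def label(self) -> str:
        if self.kind == "diversity":
            return f"pi:{next(iter(self.taxa))}"
        return "dxy:" + "|".join(sorted(self.taxa))

    @classmethod
    def from_label(cls, label: str) -> "StatDescriptor":
        kind, _, taxa = label.partition(":")
        if kind == "pi":
            return diversity(taxa)
        if kind == "dxy":
            return divergence(*taxa.split("|"))
        raise ValueError(f"bad descriptor label {label!r}")


def diversity(pop: str) -> StatDescriptor:
    return StatDescriptor("diversity", frozenset([pop]))


def divergence(a: str, b: str) -> StatDescriptor:
    if a == b:
        raise ValueError("divergence requires two distinct populations")
    return StatDescriptor("divergence", frozenset([a, b]))


def mrca(tree: SpeciesTree, pops: Iterable[str]) -> str:
    """Lowest node ancestral to all ``pops``; a single tip is its own MRCA."""
    pops = list(pops)
    for p in pops:
        if p not in tree.node_names:
            raise TreeError(f"unknown population {p!r}")
    return tree.mrca(pops)


def _anchor(tree: SpeciesTree, d: StatDescriptor) -> str:
    d.validate(tree)
    return tree.mrca(d.taxa)


def phylo_distance(tree: SpeciesTree, a: StatDescriptor, b: StatDescriptor) -> float:
    """Phylogenetic distance dT (generations) between two statistics.

    The distance between the MRCA nodes anchoring each statistic,
    measured along the tree.  Symmetric; zero when both statistics
    anchor to the same node.
    """
    return tree.distance(_anchor(tree, a), _anchor(tree, b))


def _edge_set(tree: SpeciesTree, d: StatDescriptor) -> frozenset:
    """Defining edges of a statistic.

    A divergence is defined by the edges on the tip-to-tip path through
    its MRCA; a diversity by the terminal edge of its tip.  Edges are
    identified by their child node's name.
    """
    d.validate(tree)
    if d.kind == "diversity":
        return frozenset(d.taxa)
    a, b = sorted(d.taxa)
    anc = tree.mrca({a, b})
    edges = set()
    for tip in (a, b):
        x = tip
        while x != anc:
            edges.add(x)
            x = tree.parent(x)
    return frozenset(edges)


def shares_branches(tree: SpeciesTree, a: StatDescriptor, b: StatDescriptor) -> bool:
    """True iff the defining edge sets of the two statistics intersect.

    Divergences may share branches by definition irrespective of split
    times, which makes dT a poor predictor of their correlation; such
    pairs are flagged so they can be excluded from dT-based analyses.
    """
    return bool(_edge_set(tree, a) & _edge_set(tree, b))


def coalesce_before_split(T: float, Ne: float) -> float:
    """Probability two lineages coalesce within ``T`` generations in a
    population of diploid size ``Ne``: ``1 - exp(-T / (2 Ne))``."""
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    if T < 0:
        raise ValueError("T must be non-negative")
    return -math.expm1(-T / (2.0 * Ne))


#: Printed diploid sample counts of the ten study populations.
GREAT_APES_SAMPLES = {
    "human": 9,
    "bonobo": 13,
    "nc_chimp": 10,
    "eastern_chimp": 6,
    "central_chimp": 4,
    "western_chimp": 4,
    "eastern_gorilla": 3,
    "western_gorilla": 27,
    "sumatran_orang": 5,
    "bornean_orang": 5,
}

_GREAT_APES_NEWICK = (
    "(((human:240000,(bonobo:80000,"
    "((western_chimp:10000,nc_chimp:10000)wn_chimp:10000,"
    "(central_chimp:4000,eastern_chimp:4000)ce_chimp:16000)chimp:60000)"
    "pan:160000)homo_pan:80000,"
    "(eastern_gorilla:8000,western_gorilla:8000)gorilla:312000)african_apes:160000,"
    "(sumatran_orang:16000,bornean_orang:16000)orang:464000)great_apes;"
)

# Branch Ne: only the root (great apes ancestor, 125,089) and the human
# branch (7,672) are published for the simulated demographic model; the
# rest are stylized, literature-plausible values and fully configurable.
_GREAT_APES_NE = {
    "great_apes": 125_089,
    "african_apes": 80_000,
    "homo_pan": 60_000,
    "human": 7_672,
    "pan": 30_000,
    "bonobo": 6_000,
    "chimp": 25_000,
    "wn_chimp": 20_000,
    "ce_chimp": 30_000,
    "western_chimp": 6_000,
    "nc_chimp": 15_000,
    "central_chimp": 30_000,
    "eastern_chimp": 10_000,
    "gorilla": 20_000,
    "eastern_gorilla": 3_000,
    "western_gorilla": 25_000,
    "orang": 20_000,
    "sumatran_orang": 25_000,
    "bornean_orang": 15_000,
}


def great_apes_tree() -> SpeciesTree:
    """Default ten-population great-apes demographic model.

    Topology and split times (generations, 25-year generations): orangutans
    split 480k generations ago (~12 Myr, the age of the clade), gorillas
    320k, chimps 240k; within-genus splits are recent.  Tips carry the
    published sample counts.
    """
    return SpeciesTree.from_newick(_GREAT_APES_NEWICK, _GREAT_APES_NE, GREAT_APES_SAMPLES)
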
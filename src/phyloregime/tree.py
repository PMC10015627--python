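"""Rooted phylogenies with branch lengths, Newick I/O, and tree surgeries.

The tree model is deliberately small: nodes are integer-indexed records
holding a parent pointer, a branch length to the parent, and an optional
label. Polytomies are first-class; branch lengths of zero are permitted
everywhere (grafted strains, resolved polytomies) and downstream likelihood
code treats them without special cases.

Parsing goes through dendropy; emission is a local writer so that
``write(read(s))`` round-trips labels and lengths to 12 significant digits.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "Phylogeny",
    "PathSegment",
    "read_newick",
    "write_newick",
    "graft_tips_as_polytomy",
    "resolve_polytomies",
    "make_ultrametric",
    "root_to_tip_segments",
]


@dataclass
class Node:
    id: int
    label: Optional[str]
    parent: Optional[int]
    length: float  # branch length to parent; 0.0 for the root
    children: list[int] = field(default_factory=list)


class Phylogeny:
    """A rooted tree: exactly one root, unique tip labels, lengths >= 0."""

    def __init__(self, nodes: Sequence[Node], root: int):
        self.nodes: list[Node] = list(nodes)
        self.root: int = root
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        roots = [n.id for n in self.nodes if n.parent is None]
        if roots != [self.root]:
            raise ValueError(f"expected exactly one root {self.root}, found {roots}")
        for n in self.nodes:
            if n.length < 0:
                raise ValueError(f"negative branch length on node {n.id}")
            if n.parent is not None and n.id not in self.nodes[n.parent].children:
                raise ValueError(f"inconsistent parent/child link at node {n.id}")
        labels = [n.label for n in self.nodes if not n.children]
        if any(l is None for l in labels):
            raise ValueError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        # connectivity/acyclicity: walking to the root must terminate
        for n in self.nodes:
            seen, cur = set(), n.id
            while cur is not None:
                if cur in seen:
                    raise ValueError("cycle detected")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            [replace(n, children=list(n.children)) for n in self.nodes], self.root
        )

    # -- basic queries ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes if not n.children)

    def tips(self) -> list[Node]:
        return [n for n in self.nodes if not n.children]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]  # type: ignore[misc]

    def tip_id(self, label: str) -> int:
        for n in self.tips():
            if n.label == label:
                return n.id
        raise KeyError(f"unknown taxon {label!r}")

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.nodes)

    def postorder(self) -> Iterator[Node]:
        out: list[int] = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.nodes[i].children)
        for i in reversed(out):
            yield self.nodes[i]

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            i = stack.pop()
            yield self.nodes[i]
            stack.extend(reversed(self.nodes[i].children))

    def depths(self) -> dict[int, float]:
        """Distance from the root to each node."""
        d: dict[int, float] = {}
        for n in self.preorder():
            d[n.id] = 0.0 if n.parent is None else d[n.parent] + n.length
        return d

    def height(self) -> float:
        d = self.depths()
        return max(d[t.id] for t in self.tips())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.depths()
        vals = [d[t.id] for t in self.tips()]
        return max(vals) - min(vals) <= tol

    def path_to_root(self, node_id: int) -> list[int]:
        """Node ids from ``node_id`` up to and including the root."""
        path, cur = [], node_id
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path

    def mrca(self, i: int, j: int) -> int:
        anc = set(self.path_to_root(i))
        for k in self.path_to_root(j):
            if k in anc:
                return k
        raise RuntimeError("disconnected tree")  # pragma: no cover

    def patristic_distance(self, a: str, b: str) -> float:
        d = self.depths()
        i, j = self.tip_id(a), self.tip_id(b)
        m = self.mrca(i, j)
        return d[i] + d[j] - 2 * d[m]

    def summary(self) -> dict:
        return {
            "n_tips": self.n_tips,
            "height": self.height(),
            "ultrametric": self.is_ultrametric(),
            "binary": self.is_binary(),
        }


# -- Newick I/O ---------------------------------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (quoted labels and polytomies allowed).

    Missing branch lengths default to 0 with a warning; duplicate tip
    labels raise.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy reports line/column in its message
        raise ValueError(f"Newick parse error: {exc}") from exc

    nodes: list[Node] = []
    index: dict[int, int] = {}
    missing = 0
    for dnode in dtree.preorder_node_iter():
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is not None:
                missing += 1
            length = 0.0
        parent = index[id(dnode.parent_node)] if dnode.parent_node is not None else None
        nid = len(nodes)
        index[id(dnode)] = nid
        nodes.append(Node(nid, label, parent, float(length)))
        if parent is not None:
            nodes[parent].children.append(nid)
    if missing:
        warnings.warn(f"{missing} branch length(s) missing; defaulted to 0")
    return Phylogeny(nodes, 0)


_SAFE_LABEL = re.compile(r"^[^\s()\[\]{}:;,\"']+$")


def _fmt_label(label: Optional[str]) -> str:
    if label is None:
        return ""
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Phylogeny) -> str:
    def rec(i: int) -> str:
        n = tree.nodes[i]
        inner = ""
        if n.children:
            inner = "(" + ",".join(rec(c) for c in n.children) + ")"
        s = inner + _fmt_label(n.label)
        if n.parent is not None:
            s += ":" + format(n.length, ".12g")
        return s

    return rec(tree.root) + ";"


# -- surgeries ----------------------------------------------------------


def graft_tips_as_polytomy(
    tree: Phylogeny,
    at: str,
    new_tips: Sequence[str],
    length: float = 0.0,
    original_length: float = 0.0,
) -> Phylogeny:
    """Turn tip ``at`` into an internal node carrying itself plus ``new_tips``.

    Mirrors adding conspecific strains to a species tip as a polytomy. The
    new tips hang on branches of ``length``; the original taxon is
    retained as a child at ``original_length`` (default 0, so all
    pre-existing patristic distances are unchanged).
    """
    existing = set(tree.tip_labels())
    if at not in existing:
        raise KeyError(f"unknown taxon {at!r}")
    dups = [t for t in new_tips if t in existing or list(new_tips).count(t) > 1]
    if dups:
        raise ValueError(f"duplicate new tip label(s): {sorted(set(dups))}")
    out = tree.copy()
    hub = out.nodes[out.tip_id(at)]
    hub_label, hub.label = hub.label, None
    for lab, blen in [(hub_label, original_length)] + [(t, length) for t in new_tips]:
        nid = len(out.nodes)
        out.nodes.append(Node(nid, lab, hub.id, float(blen)))
        hub.children.append(nid)
    return Phylogeny(out.nodes, out.root)


def resolve_polytomies(tree: Phylogeny) -> Phylogeny:
    """Make the tree strictly bifurcating with zero-length inserted branches.

    Children are combined left-to-right in input order, so the result is
    deterministic and trait covariances are unchanged.
    """
    out = tree.copy()
    for nid in [n.id for n in out.nodes]:
        node = out.nodes[nid]
        while len(node.children) > 2:
            # pull off the last two children under a new zero-length node
            b = node.children.pop()
            a = node.children.pop()
            fresh = Node(len(out.nodes), None, node.id, 0.0, [a, b])
            out.nodes.append(fresh)
            out.nodes[a].parent = fresh.id
            out.nodes[b].parent = fresh.id
            node.children.append(fresh.id)
    return Phylogeny(out.nodes, out.root)


def make_ultrametric(tree: Phylogeny, method: str = "extend") -> Phylogeny:
    """Equalize root-to-tip depths by extending terminal branches to the max.

    Deterministic and order-independent; no branch is ever shortened and
    only terminal branches change.
    """
    if method != "extend":
        raise ValueError(f"unknown method {method!r}")
    if not tree.is_binary():
        raise ValueError("make_ultrametric requires a binary tree; resolve polytomies first")
    out = tree.copy()
    d = out.depths()
    h = max(d[t.id] for t in out.tips())
    for t in out.tips():
        t.length += h - d[t.id]
    return Phylogeny(out.nodes, out.root)


# -- regime paintings and root-to-tip path decomposition ----------------


@dataclass
class PathSegment:
    """A constant-regime stretch of a root-to-tip path.

    Depths are measured from the root; contiguous segments along a path sum
    to the tip depth. Feeds the OU expectation weights.
    """

    branch: int  # child-node id identifying the branch
    start: float
    end: float
    state: Optional[int] = None

    @property
    def length(self) -> float:
        return self.end - self.start


def root_to_tip_segments(tree: Phylogeny, painting, tip: str) -> list[PathSegment]:
    """Decompose the root-to-tip path into per-branch constant-regime segments."""
    tid = tree.tip_id(tip)
    depths = tree.depths()
    path = tree.path_to_root(tid)[:-1]  # exclude root: one entry per branch
    segs = []
    for nid in reversed(path):
        n = tree.nodes[nid]
        state = painting.branch_state(nid) if painting is not None else None
        if painting is not None and state is None:
            raise KeyError(f"branch above node {nid} is not painted")
        segs.append(PathSegment(nid, depths[n.parent], depths[nid], state))
    return segs
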
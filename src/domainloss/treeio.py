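"""Dated rooted species trees and per-domain presence patterns.

The tree is the substrate for every loss computation downstream: Dollo
reconstruction, the loss-rate likelihood, the false-positive search and the
random-placement screen all need fast clade queries over thousands of
presence patterns.  Newick parsing and writing go through dendropy; in
memory the tree is a flat postorder array with one integer bitmask of
descendant tips per node, so that clade membership, MRCA and "maximal
absent subtree" queries are single integer operations.

An *edge* is identified by its child node index.  The root's edge is a
virtual zero-length stem, which makes origin-edge assignment total: a
domain present in species spanning the root "arose" on the stem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesTree",
    "PresencePattern",
    "TreeError",
    "read_tree",
    "write_tree",
    "read_presence",
    "write_presence",
    "mrca_edge",
]


class TreeError(ValueError):
    """Raised for malformed trees or presence data."""


class SpeciesTree:
    """Rooted dated phylogeny with branch lengths in My.

    Nodes are indexed 0..n_nodes-1 in postorder (root last).  ``parent[i]``
    is the parent index (-1 for the root), ``length[i]`` the length of the
    edge above node ``i`` (0.0 for the root's virtual stem) and
    ``tip_mask[i]`` a bitmask over tip indices of the tips below ``i``.

    Parameters
    ----------
    parent, length, children, labels
        Flat postorder arrays as produced by :func:`read_tree`; not normally
        constructed by hand.
    """

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        children: Sequence[Sequence[int]],
        labels: Sequence[str | None],
    ):
        self.parent = list(parent)
        self.length = list(length)
        self.children = [list(c) for c in children]
        self.labels = list(labels)
        self.n_nodes = len(parent)
        self.root = self.n_nodes - 1
        if self.parent[self.root] != -1:
            raise TreeError("last node in postorder must be the root")

        self.tip_indices: list[int] = [
            i for i in range(self.n_nodes) if not self.children[i]
        ]
        if len(self.tip_indices) < 2:
            raise TreeError("tree must have at least 2 tips")
        self.tip_names: list[str] = []
        self._tip_bit: dict[str, int] = {}
        self.tip_mask = [0] * self.n_nodes
        for bit, i in enumerate(self.tip_indices):
            name = self.labels[i]
            if not name:
                raise TreeError(f"unnamed tip at node index {i}")
            if name in self._tip_bit:
                raise TreeError(f"duplicate tip name: {name!r}")
            self._tip_bit[name] = bit
            self.tip_names.append(name)
            self.tip_mask[i] = 1 << bit
        for i in range(self.n_nodes):  # postorder: children precede parents
            for c in self.children[i]:
                self.tip_mask[i] |= self.tip_mask[c]

        for i in range(self.n_nodes - 1):
            if self.length[i] < 0:
                raise TreeError(f"negative edge length at node {self.node_repr(i)}")
        # virtual stem
        self.length[self.root] = 0.0
        self.all_tips_mask = self.tip_mask[self.root]

    # -- basic queries -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def tips_to_mask(self, tips: Iterable[str]) -> int:
        """Bitmask for a collection of tip names; unknown names raise."""
        mask = 0
        bad = []
        for t in tips:
            b = self._tip_bit.get(t)
            if b is None:
                bad.append(t)
            else:
                mask |= 1 << b
        if bad:
            raise TreeError(f"species not in tree: {sorted(bad)}")
        return mask

    def mask_to_tips(self, mask: int) -> set[str]:
        return {name for name, b in self._tip_bit.items() if mask >> b & 1}

    def node_repr(self, i: int) -> str:
        lbl = self.labels[i]
        return lbl if lbl else f"node{i}"

    def total_length(self) -> float:
        """Sum of all real edge lengths (excludes the virtual stem)."""
        return sum(self.length[i] for i in range(self.n_nodes) if i != self.root)

    def mrca(self, mask: int) -> int:
        """Node index of the most recent common ancestor of the masked tips."""
        if mask == 0:
            raise TreeError("mrca of an empty species set is undefined")
        if mask & ~self.all_tips_mask:
            raise TreeError("mask contains bits outside the tree")
        # start at any tip in the mask and walk rootward
        bit = (mask & -mask).bit_length() - 1
        node = self.tip_indices[bit]
        while self.tip_mask[node] & mask != mask:
            node = self.parent[node]
        return node

    def subtree_nodes(self, node: int) -> list[int]:
        """All nodes strictly below ``node`` plus ``node`` itself, preorder."""
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        parts: list[str] = [""] * self.n_nodes
        for i in range(self.n_nodes):  # postorder: children done first
            if self.children[i]:
                inner = ",".join(parts[c] for c in self.children[i])
                lbl = self.labels[i] or ""
                parts[i] = f"({inner}){lbl}"
            else:
                parts[i] = self.labels[i]
            if i != self.root:
                parts[i] += f":{self.length[i]:.10g}"
        return parts[self.root] + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<SpeciesTree {self.n_tips} tips, depth sum {self.total_length():.3g} My>"


@dataclass
class PresencePattern:
    """Per-domain presence with the evidence class of each species.

    ``coding`` holds species whose presence comes from annotated coding
    sequence (the set P_C); ``intergenic`` holds species found only by an
    intergenic six-frame scan (P_i).  The two sets are disjoint; a species
    observed in both evidence classes counts as coding.
    """

    pfam_id: str
    coding: frozenset[str] = field(default_factory=frozenset)
    intergenic: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.coding = frozenset(self.coding)
        self.intergenic = frozenset(self.intergenic) - self.coding
        if not self.coding | self.intergenic:
            raise TreeError(f"{self.pfam_id}: presence pattern is empty")

    @property
    def present(self) -> frozenset[str]:
        return self.coding | self.intergenic


def _from_dendropy(dtree: dendropy.Tree) -> SpeciesTree:
    nodes = list(dtree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent, length, children, labels = [], [], [], []
    for i, n in enumerate(nodes):
        par = n.parent_node
        parent.append(index[id(par)] if par is not None else -1)
        if par is not None:
            if n.edge.length is None:
                name = n.taxon.label if n.taxon else (n.label or f"internal node {i}")
                raise TreeError(f"edge above {name!r} has no branch length")
            length.append(float(n.edge.length))
        else:
            length.append(0.0)
        children.append([index[id(c)] for c in n.child_nodes()])
        labels.append(n.taxon.label if n.taxon else n.label)
    return SpeciesTree(parent, length, children, labels)


def read_tree(path_or_string: str | Path) -> SpeciesTree:
    """Read a dated rooted tree from a newick file or literal newick string.

    Branch lengths (in My) are required on every non-root edge; trees
    explicitly annotated as unrooted (``[&U]``) are rejected.  Polytomies
    are accepted as-is.
    """
    src = str(path_or_string)
    if src.lstrip().startswith("(") or src.rstrip().endswith(";"):
        data, kind = src, "string"
    else:
        data, kind = Path(src).read_text(), "file"
    if "[&U]" in data or "[&u]" in data:
        raise TreeError("tree is annotated as unrooted; a rooted tree is required")
    try:
        dtree = dendropy.Tree.get(
            data=data,
            schema="newick",
            rooting="default-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        msg = str(exc)
        if "uplicate" in msg or "ultiple" in msg:
            raise TreeError(f"duplicate tip name: {msg}") from exc
        raise TreeError(f"cannot parse newick: {msg}") from exc
    tree = _from_dendropy(dtree)
    logger.debug("read %d-tip tree from %s", tree.n_tips, kind)
    return tree


def write_tree(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def mrca_edge(tree: SpeciesTree, tips: Iterable[str]) -> int:
    """Edge above the MRCA of ``tips`` (edge = child-node index).

    If the MRCA is the root, the returned edge is the root's virtual
    zero-length stem.
    """
    return tree.mrca(tree.tips_to_mask(tips))


def read_presence(path: str | Path, tree: SpeciesTree) -> list[PresencePattern]:
    """Read a presence TSV (columns pfam_id, species, evidence).

    ``evidence`` must be ``coding`` or ``intergenic``.  Duplicate rows are
    deduplicated with a warning; a species listed with both evidence classes
    collapses to coding.  Species absent from the tree raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pfam_id", "species", "evidence"}
    if not required.issubset(df.columns):
        raise TreeError(f"presence TSV must have columns {sorted(required)}")
    bad_ev = set(df["evidence"]) - {"coding", "intergenic"}
    if bad_ev:
        raise TreeError(f"unknown evidence classes: {sorted(bad_ev)}")
    unknown = set(df["species"]) - set(tree.tip_names)
    if unknown:
        raise TreeError(f"species not in tree: {sorted(unknown)}")
    n0 = len(df)
    df = df.drop_duplicates()
    if len(df) < n0:
        logger.warning("presence TSV: dropped %d duplicate rows", n0 - len(df))
    patterns = []
    for pfam_id, grp in df.groupby("pfam_id", sort=True):
        coding = set(grp.loc[grp["evidence"] == "coding", "species"])
        intergenic = set(grp.loc[grp["evidence"] == "intergenic", "species"]) - coding
        patterns.append(PresencePattern(str(pfam_id), frozenset(coding), frozenset(intergenic)))
    return patterns


def write_presence(patterns: Iterable[PresencePattern], path: str | Path) -> None:
    rows = []
    for p in patterns:
        rows += [(p.pfam_id, s, "coding") for s in sorted(p.coding)]
        rows += [(p.pfam_id, s, "intergenic") for s in sorted(p.intergenic)]
    pd.DataFrame(rows, columns=["pfam_id", "species", "evidence"]).to_csv(
        path, sep="\t", index=False
    )
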
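"""Dollo-parsimony reconstruction of domain origin and losses.

Under Dollo parsimony a domain arises exactly once, on the branch basal to
the smallest monophyletic clade containing every species that has it, and
is subsequently only lost.  The minimal explanation of a presence pattern
places one loss on the basal edge of each maximal subtree (within the
origin clade) that contains no present species; every other edge in the
clade is a retention edge, on which at least one copy survived.

Loss edges are indexed ``j`` and retention edges ``k`` in the loss-rate
likelihood; the origin edge itself is neither (the domain arises partway
along it, so it is not a retention interval of known length, and it cannot
be a loss).
"""

from __future__ import annotations

from dataclasses import dataclass

from .treeio import SpeciesTree, TreeError

__all__ = ["DolloReconstruction", "dollo_reconstruct", "parsimony_init_rate"]


@dataclass(frozen=True)
class DolloReconstruction:
    """Origin edge, loss edges (index j) and retention edges (index k)."""

    pfam_id: str
    origin_edge: int
    loss_edges: tuple[int, ...]
    retention_edges: tuple[int, ...]
    loss_lengths: tuple[float, ...]  # t_j, My
    retention_length: float          # sum of t_k, My

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def dollo_reconstruct(
    tree: SpeciesTree, present: int | frozenset | set, pfam_id: str = ""
) -> DolloReconstruction:
    """Reconstruct origin and minimal losses for a presence pattern.

    Parameters
    ----------
    tree
        The dated species tree.
    present
        Present species, either as a set of tip names or as a tip bitmask.
    """
    mask = present if isinstance(present, int) else tree.tips_to_mask(present)
    if mask == 0:
        raise TreeError("cannot reconstruct an empty presence pattern")
    origin = tree.mrca(mask)

    loss_edges: list[int] = []
    loss_lengths: list[float] = []
    retention_edges: list[int] = []
    retention_length = 0.0
    # preorder walk inside the origin clade; a loss edge prunes its subtree
    stack = list(tree.children[origin])
    while stack:
        v = stack.pop()
        if tree.tip_mask[v] & mask:
            retention_edges.append(v)
            retention_length += tree.length[v]
            stack.extend(tree.children[v])
        else:
            loss_edges.append(v)
            loss_lengths.append(tree.length[v])
    return DolloReconstruction(
        pfam_id=pfam_id,
        origin_edge=origin,
        loss_edges=tuple(loss_edges),
        retention_edges=tuple(retention_edges),
        loss_lengths=tuple(loss_lengths),
        retention_length=retention_length,
    )


def parsimony_init_rate(
    recon: DolloReconstruction, denominator: str = "retention"
) -> float:
    """Parsimony initialization of the loss rate, per My.

    ``denominator="retention"`` divides the loss count by the summed length
    of retention edges (the unshaded branches); ``"total"`` divides by the
    full branch length of the origin clade (retention plus loss edges).
    Returns 0.0 exactly when there are no losses.
    """
    if recon.n_losses == 0:
        return 0.0
    if denominator == "retention":
        denom = recon.retention_length
    elif denominator == "total":
        denom = recon.retention_length + sum(recon.loss_lengths)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValueError("cannot initialize a loss rate on zero branch length")
    return recon.n_losses / denom
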
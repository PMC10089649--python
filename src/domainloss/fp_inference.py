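"""Joint inference of false-positive presences and loss rates.

Annotated domain presences can be spurious (annotation error, contamination
or horizontal transfer).  Two prior probabilities are carried: ``f_c``,
that a coding-evidence presence is false, and ``f_i``, that an
intergenic-scan-only presence is false.  For one domain, the joint
likelihood of designating species sets F_C and F_i as false is the
loss-rate likelihood refit on the retained species times the Bernoulli
prior terms:

    L = L_loss(lambda_hat) * f_c^|F_C| (1-f_c)^|P_C - F_C|
                           * f_i^|F_i| (1-f_i)^|P_i - F_i|

The flip sets are searched greedily at the granularity of maximal
monophyletic all-present clades (flips of a clade to false, and flips of
previously-falsified clades back to true), accepting the single best
improving move until none improves.  An outer empirical-Bayes loop then
re-estimates the priors from the pooled flip counts across all domains and
repeats until the priors stabilize.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .dollo import dollo_reconstruct
from .loss_ml import LossFit, mle_loss_rate
from .treeio import PresencePattern, SpeciesTree

logger = logging.getLogger(__name__)

__all__ = [
    "FPModel",
    "FlipState",
    "presence_clades",
    "joint_loglik",
    "greedy_flip_search",
    "eb_loop",
]

PRIOR_FLOOR = 1e-9
_IMPROVE_EPS = 1e-9


@dataclass(frozen=True)
class FPModel:
    """The two class priors of the false-positive model."""

    f_c: float = 1e-6
    f_i: float = 0.2
    iteration: int = 0

    def __post_init__(self):
        if not (0 < self.f_c < 1 and 0 < self.f_i < 1):
            raise ValueError("priors must lie strictly in (0, 1)")


@dataclass
class FlipState:
    """Flip assignment and refit loss rate for one domain."""

    pfam_id: str
    flipped_coding: frozenset[str]
    flipped_intergenic: frozenset[str]
    fit: LossFit
    joint_loglik: float


def presence_clades(tree: SpeciesTree, present: int | frozenset | set) -> list[int]:
    """Maximal monophyletic all-present clades, as tip bitmasks.

    Partition of the present species: each returned clade is the tip set of
    the deepest node whose entire tip set is present.  Sparse patterns
    mostly decompose into singletons.
    """
    mask = present if isinstance(present, int) else tree.tips_to_mask(present)
    clades: list[int] = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        tm = tree.tip_mask[v]
        overlap = tm & mask
        if not overlap:
            continue
        if overlap == tm:
            clades.append(tm)
        else:
            stack.extend(tree.children[v])
    return clades


def _log(p: float) -> float:
    return math.log(p)


def _joint_from_masks(
    tree: SpeciesTree,
    pc: int,
    pi: int,
    fc: int,
    fi: int,
    model: FPModel,
    pfam_id: str = "",
) -> tuple[float, LossFit | None]:
    retained = (pc | pi) & ~(fc | fi)
    if retained == 0:
        return -math.inf, None
    fit = mle_loss_rate(dollo_reconstruct(tree, retained, pfam_id))
    jl = (
        fit.loglik
        + fc.bit_count() * _log(model.f_c)
        + (pc & ~fc).bit_count() * _log(1 - model.f_c)
        + fi.bit_count() * _log(model.f_i)
        + (pi & ~fi).bit_count() * _log(1 - model.f_i)
    )
    return jl, fit


def joint_loglik(
    pattern: PresencePattern,
    flipped_coding: frozenset[str] | set[str],
    flipped_intergenic: frozenset[str] | set[str],
    model: FPModel,
    tree: SpeciesTree,
) -> float:
    """Joint log likelihood of a flip assignment (loss term refit by ML)."""
    if not set(flipped_coding) <= pattern.coding:
        raise ValueError("flipped coding species must be a subset of P_C")
    if not set(flipped_intergenic) <= pattern.intergenic:
        raise ValueError("flipped intergenic species must be a subset of P_i")
    jl, _ = _joint_from_masks(
        tree,
        tree.tips_to_mask(pattern.coding),
        tree.tips_to_mask(pattern.intergenic),
        tree.tips_to_mask(flipped_coding),
        tree.tips_to_mask(flipped_intergenic),
        model,
        pattern.pfam_id,
    )
    return jl


def _clade_sort_key(tree: SpeciesTree, clade: int) -> tuple[int, str]:
    # determinism: smallest clade first, then lexicographic by species name
    return clade.bit_count(), min(tree.mask_to_tips(clade))


def greedy_flip_search(
    pattern: PresencePattern, model: FPModel, tree: SpeciesTree
) -> FlipState:
    """Hill-climb over clade flips for one domain.

    Proposes falsifying each maximal all-present clade of the retained
    species, and (after the first acceptance) restoring each maximal clade
    of the falsified species; accepts the single move with the largest
    joint-log-likelihood gain until no move improves.  A move that would
    leave the domain with no presence is forbidden.  Ties break toward the
    smallest clade, then the lexicographically first species.
    """
    pc = tree.tips_to_mask(pattern.coding)
    pi = tree.tips_to_mask(pattern.intergenic)
    fc = fi = 0
    current, fit = _joint_from_masks(tree, pc, pi, fc, fi, model, pattern.pfam_id)

    for _round in range(4 * tree.n_tips + 4):  # safety bound; converges long before
        retained = (pc | pi) & ~(fc | fi)
        moves: list[tuple[int, str]] = []  # (clade, kind)
        for clade in presence_clades(tree, retained):
            if retained & ~clade:  # never empty the domain
                moves.append((clade, "off"))
        flipped = fc | fi
        if flipped:
            for clade in presence_clades(tree, flipped):
                moves.append((clade, "on"))

        best = None
        for clade, kind in moves:
            if kind == "off":
                nfc, nfi = fc | (clade & pc), fi | (clade & pi)
            else:
                nfc, nfi = fc & ~clade, fi & ~clade
            jl, f = _joint_from_masks(tree, pc, pi, nfc, nfi, model, pattern.pfam_id)
            if jl <= current + _IMPROVE_EPS:
                continue
            key = (-jl, *_clade_sort_key(tree, clade))
            if best is None or key < best[0]:
                best = (key, nfc, nfi, jl, f)
        if best is None:
            break
        _, fc, fi, current, fit = best
    else:  # pragma: no cover
        logger.warning("%s: flip search hit the iteration bound", pattern.pfam_id)

    return FlipState(
        pfam_id=pattern.pfam_id,
        flipped_coding=frozenset(tree.mask_to_tips(fc)),
        flipped_intergenic=frozenset(tree.mask_to_tips(fi)),
        fit=fit,
        joint_loglik=current,
    )


def eb_loop(
    patterns: list[PresencePattern],
    tree: SpeciesTree,
    init: FPModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[FPModel, list[FlipState], list[LossFit]]:
    """Recursive empirical-Bayes estimation of the false-positive priors.

    Alternates the per-domain greedy flip search with the prior update

        f_c = sum|F_C| / sum|P_C|,   f_i = sum|F_i| / sum|P_i|

    (species counts, floored at 1e-9 so logs stay finite), stopping when
    both priors move by less than ``tol`` or after ``max_iter`` rounds.
    """
    if not patterns:
        raise ValueError("eb_loop needs at least one presence pattern")
    model = init if init is not None else FPModel()
    n_pc = sum(len(p.coding) for p in patterns)
    n_pi = sum(len(p.intergenic) for p in patterns)
    flips: list[FlipState] = []
    for it in range(1, max_iter + 1):
        flips = [greedy_flip_search(p, model, tree) for p in patterns]
        n_fc = sum(len(f.flipped_coding) for f in flips)
        n_fi = sum(len(f.flipped_intergenic) for f in flips)
        new_fc = max(n_fc / n_pc, PRIOR_FLOOR) if n_pc else model.f_c
        new_fi = max(n_fi / n_pi, PRIOR_FLOOR) if n_pi else model.f_i
        new_fc, new_fi = min(new_fc, 1 - PRIOR_FLOOR), min(new_fi, 1 - PRIOR_FLOOR)
        moved = max(abs(new_fc - model.f_c), abs(new_fi - model.f_i))
        model = FPModel(new_fc, new_fi, iteration=it)
        logger.info("EB iteration %d: f_c=%.3g f_i=%.3g", it, new_fc, new_fi)
        if moved < tol:
            break
    fits = [f.fit for f in flips]
    return model, flips, fits
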
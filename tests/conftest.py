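"""Shared fixtures: small hand-built trees and independent oracles.

The oracles here deliberately take a different computational route from the
package (set-cover enumeration instead of tree pruning, dense grid search
instead of Newton iteration) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from domainloss.treeio import SpeciesTree, read_tree


@pytest.fixture
def tree4() -> SpeciesTree:
    """Symmetric 4-tip tree, all edges length 1."""
    return read_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def tree6() -> SpeciesTree:
    """6-tip tree with unequal branch lengths."""
    return read_tree("(((A:10,B:10):30,(C:25,D:25):15):60,(E:70,F:70):30);")


@pytest.fixture(scope="session")
def oracle_trees() -> list[SpeciesTree]:
    """Enumerated fixture set of small trees (4-8 tips) for exhaustive
    oracles: balanced, caterpillar, polytomous and zero-length cases."""
    newicks = [
        "((A:1,B:1):1,(C:1,D:1):1);",
        "((A:2,B:1):3,C:4,(D:1,E:2):1);",                      # polytomy
        "(((A:1,B:2):1,C:3):2,(D:1,(E:1,F:1):2):1);",
        "((((A:1,B:1):1,C:2):1,D:3):1,E:4);",                  # caterpillar 5
        "(((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5);",          # caterpillar 6
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);",  # balanced 8
        "((((A:1,B:3):2,(C:1,D:1):1):1,(E:2,F:2):3):1,(G:4,H:2):2);",
        "((A:0,B:1):1,(C:1,(D:1,E:1):0):1);",                  # zero-length edges
    ]
    return [read_tree(s) for s in newicks]


def dollo_losses_oracle(tree: SpeciesTree, present: set[str]) -> int:
    """Exhaustive minimum-loss count under single origin, by set cover.

    Finds the MRCA as the smallest-clade node containing all present tips
    (by scanning every node), then searches subsets of candidate loss
    edges (edges in the clade whose tip sets avoid all present species) in
    increasing size until the absent tips of the clade are covered.
    """
    pmask = tree.tips_to_mask(present)
    origin = min(
        (v for v in range(tree.n_nodes) if tree.tip_mask[v] & pmask == pmask),
        key=lambda v: bin(tree.tip_mask[v]).count("1"),
    )
    clade_tips = tree.tip_mask[origin]
    absent = clade_tips & ~pmask
    if absent == 0:
        return 0
    in_clade = [v for v in tree.subtree_nodes(origin) if v != origin]
    candidates = [v for v in in_clade if tree.tip_mask[v] & pmask == 0]
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            cover = 0
            for v in combo:
                cover |= tree.tip_mask[v]
            if cover & absent == absent:
                return size
    raise AssertionError("set cover failed; malformed tree")


def grid_mle_oracle(recon, lam_hi: float = 10.0, n_grid: int = 4000) -> float:
    """Dense log-grid maximizer of the loss likelihood, with golden-ratio
    refinement of the bracketing interval; independent of Newton."""
    from domainloss.loss_ml import loglik

    grid = np.geomspace(1e-8, lam_hi, n_grid)
    vals = np.array([loglik(recon, g) for g in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    gr = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    for _ in range(200):
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        if loglik(recon, c) > loglik(recon, d):
            b = d
        else:
            a = c
        if b - a < 1e-14 * b:
            break
    return (a + b) / 2


def random_subsets(tree: SpeciesTree, rng: np.random.Generator, k: int):
    """k random nonempty presence subsets of the tree's tips."""
    out = []
    names = tree.tip_names
    for _ in range(k):
        n = int(rng.integers(1, len(names) + 1))
        out.append(set(rng.choice(names, size=n, replace=False)))
    return out
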
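"""Synthetic trees, presence patterns and sequences for the full pipeline.

Nothing here is downloaded: the generator emulates the study conditions so
every downstream stage can be exercised and validated against known truth.

* a pure-birth (Yule) dated ultrametric tree, scaled to a chosen depth;
* per-domain traits: an ISD-like disorder value on [0, 1] (Beta-distributed,
  mean near 0.2) and a hydrophobic-clustering value centred on 1;
* presence patterns from a single origin (placed by domain age) followed by
  Poisson total losses along branches, with per-branch loss probability
  1 - exp(-t * lambda) and a trait-dependent rate: a V on the log-rate
  scale with its minimum at the trait optimum, so the generated rates echo
  the observed magnitudes (median near 0.0009 losses/My);
* planted false positives at class-specific rates, scaled so the expected
  fraction of presences that are false matches the configured f_c and f_i
  (the quantities the empirical-Bayes loop estimates);
* amino-acid sequences whose hydrophobic placement is tuned from uniform
  (clustering 1) toward runs (clustered) or stratified spacing
  (interspersed).

Truth tables record per-domain rates, origins, loss counts, redraw counts
and every planted false positive, so recovery can be asserted without any
external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .treeio import PresencePattern, SpeciesTree, read_tree

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "make_tree", "node_ages", "rate_from_trait",
           "sample_traits", "sample_young_traits", "make_presence",
           "make_sequences", "simulate_dataset", "realized_fp_fractions"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic data set.

    Defaults echo the observed magnitudes: 64 tips over 800 My, disorder
    optimum 0.18 with log-rate slopes -2.0 / 3.86 around it, a minimal
    rate giving a median loss rate near 0.0009/My, and false-positive
    fractions 2.1e-4 (coding) and 0.031 (intergenic-only).
    """

    n_tips: int = 64
    tree_depth: float = 800.0        # My, root age
    n_pfams: int = 500
    # traits
    isd_alpha: float = 2.0           # Beta shape: mean 0.2, like observed ISD
    isd_beta: float = 8.0
    young_isd_alpha: float = 4.0     # birth distribution of young domains:
    young_isd_beta: float = 6.0      # disordered (mean 0.4), later pruned
    clustering_mean: float = 1.0
    clustering_sd: float = 0.25
    # trait -> rate map (V on the natural-log rate scale)
    breakpoint: float = 0.18
    slope_left: float = -2.0         # log-rate per trait unit below optimum
    slope_right: float = 3.86        # above optimum
    rate_min: float = 7e-4           # losses/My at the optimum
    rate_floor: float = 1e-6
    # presence generation
    age_min: float = 20.0            # My, youngest possible origin
    p_intergenic_true: float = 0.1   # true presence found only by the scan
    f_c: float = 2.1e-4              # fraction of coding presences false
    f_i: float = 0.031               # fraction of intergenic presences false
    # sequences
    seq_length: int = 120
    hydrophobic_fraction: float = 0.3
    instances_per_pfam: int = 3
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_tree(config: SimConfig, rng: np.random.Generator | None = None) -> SpeciesTree:
    """Seeded pure-birth dated tree with ``n_tips`` tips and root age
    ``tree_depth`` My (ultrametric)."""
    if config.n_tips < 4:
        raise ValueError("need at least 4 tips")
    rng = rng if rng is not None else config.rng()
    # forward-time Yule process: split a random active lineage at each event
    next_id = [0]

    def new_node(t):
        next_id[0] += 1
        return {"time": t, "children": [], "name": None}

    root = new_node(0.0)
    active = []
    for _ in range(2):
        c = new_node(0.0)
        root["children"].append(c)
        active.append(c)
    t = 0.0
    while len(active) < config.n_tips:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node = active[i]
        node["time"] = t
        kids = [new_node(t), new_node(t)]
        node["children"] = kids
        active[i] = kids[0]
        active.append(kids[1])
    t_end = t + rng.exponential(1.0 / len(active))
    width = len(str(config.n_tips))
    for k, node in enumerate(active):
        node["time"] = t_end
        node["name"] = f"s{k + 1:0{width}d}"
    scale = config.tree_depth / t_end

    def newick(node, parent_time):
        length = (node["time"] - parent_time) * scale
        if node["children"]:
            inner = ",".join(newick(c, node["time"]) for c in node["children"])
            return f"({inner}):{length:.10g}"
        return f"{node['name']}:{length:.10g}"

    inner = ",".join(newick(c, 0.0) for c in root["children"])
    return read_tree(f"({inner});")


def node_ages(tree: SpeciesTree) -> np.ndarray:
    """Age (My before present) of each node of an ultrametric tree."""
    ages = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):  # postorder: children first
        if tree.children[v]:
            c = tree.children[v][0]
            ages[v] = ages[c] + tree.length[c]
    return ages


def rate_from_trait(traits, config: SimConfig) -> np.ndarray:
    """True loss rate for a trait value: V on the log-rate scale."""
    x = np.asarray(traits, dtype=float)
    d = x - config.breakpoint
    log_rate = np.log(config.rate_min) + np.where(
        d < 0, config.slope_left * d, config.slope_right * d
    )
    return np.maximum(np.exp(log_rate), config.rate_floor)


def sample_traits(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-domain ISD, clustering, age and a mean instance count."""
    n = config.n_pfams
    isd = rng.beta(config.isd_alpha, config.isd_beta, size=n)
    clustering = np.maximum(
        rng.normal(config.clustering_mean, config.clustering_sd, size=n), 0.0
    )
    ages = rng.uniform(config.age_min, config.tree_depth, size=n)
    mean_instances = np.exp(rng.normal(1.0, 0.8, size=n))
    width = len(str(n))
    return pd.DataFrame({
        "pfam_id": [f"PF{i + 1:0{width}d}" for i in range(n)],
        "isd": isd,
        "clustering": clustering,
        "age": ages,
        "mean_instances": mean_instances,
    })


def sample_young_traits(config: SimConfig, rng: np.random.Generator,
                        n: int = 2000) -> np.ndarray:
    """ISD values of a young cohort: the birth distribution, before
    differential retention has pruned the disordered end."""
    return rng.beta(config.young_isd_alpha, config.young_isd_beta, size=n)


def _origin_for_age(tree: SpeciesTree, ages: np.ndarray, age: float) -> int:
    """Oldest edge whose start time (parent-node age) <= age; ties by index."""
    best, best_start = tree.root, -1.0
    if age >= ages[tree.root]:
        return tree.root  # virtual stem
    for v in range(tree.n_nodes - 1):
        start = ages[tree.parent[v]]
        if start <= age and start > best_start:
            best, best_start = v, start
    return best


def _drop_losses(tree: SpeciesTree, origin: int, lam: float,
                 rng: np.random.Generator) -> tuple[int, int]:
    """One realization of Poisson losses below ``origin``; returns
    (present tip mask, number of loss events)."""
    mask = 0
    n_loss = 0
    stack = list(tree.children[origin])
    if not stack:  # origin is a tip
        return tree.tip_mask[origin], 0
    while stack:
        v = stack.pop()
        if rng.random() < -np.expm1(-tree.length[v] * lam):
            n_loss += 1
            continue
        if tree.children[v]:
            stack.extend(tree.children[v])
        else:
            mask |= tree.tip_mask[v]
    return mask, n_loss


def make_presence(
    tree: SpeciesTree,
    traits: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    max_redraws: int = 10000,
) -> tuple[list[PresencePattern], dict[str, pd.DataFrame]]:
    """Generate presence patterns with planted false positives.

    Each domain originates on the edge matching its age and loses whole
    subtrees with per-branch probability 1 - exp(-t*lambda).  Domains
    surviving in no species are redrawn (conditioning on survival, as
    observation does); redraw counts are kept in the truth table.  False
    positives are planted among absent species with per-species
    probabilities scaled so the expected fraction of presences that are
    false matches ``config.f_c`` / ``config.f_i``.
    """
    rng = rng if rng is not None else config.rng()
    ages = node_ages(tree)
    patterns: list[PresencePattern] = []
    pfam_rows = []
    fp_rows = []
    rates = rate_from_trait(traits["isd"].to_numpy(), config)
    for row, lam in zip(traits.itertuples(index=False), rates):
        origin = _origin_for_age(tree, ages, row.age)
        n_redraws = 0
        mask, n_loss = _drop_losses(tree, origin, lam, rng)
        while mask == 0:
            n_redraws += 1
            if n_redraws > max_redraws:
                raise RuntimeError(
                    f"{row.pfam_id}: no surviving species after "
                    f"{max_redraws} redraws (rate {lam:.3g}/My)"
                )
            mask, n_loss = _drop_losses(tree, origin, lam, rng)
        if n_redraws:
            logger.debug("%s: redrawn %d time(s)", row.pfam_id, n_redraws)

        true_species = sorted(tree.mask_to_tips(mask))
        is_intergenic = rng.random(len(true_species)) < config.p_intergenic_true
        coding = {s for s, ig in zip(true_species, is_intergenic) if not ig}
        intergenic = {s for s, ig in zip(true_species, is_intergenic) if ig}
        for s in true_species:
            fp_rows.append({
                "pfam_id": row.pfam_id, "species": s,
                "evidence": "intergenic" if s in intergenic else "coding",
                "is_false": False,
            })

        absent = sorted(set(tree.tip_names) - set(true_species))
        if absent:
            n_abs = len(absent)
            q_c = min(1.0, config.f_c / (1 - config.f_c) * len(coding) / n_abs)
            q_i = min(1.0, config.f_i / (1 - config.f_i) * len(intergenic) / n_abs)
            u = rng.random(n_abs)
            for s, uu in zip(absent, u):
                if uu < q_c:
                    coding.add(s)
                    fp_rows.append({"pfam_id": row.pfam_id, "species": s,
                                    "evidence": "coding", "is_false": True})
                elif uu < q_c + q_i:
                    intergenic.add(s)
                    fp_rows.append({"pfam_id": row.pfam_id, "species": s,
                                    "evidence": "intergenic", "is_false": True})

        patterns.append(PresencePattern(row.pfam_id, frozenset(coding),
                                        frozenset(intergenic)))
        pfam_rows.append({
            "pfam_id": row.pfam_id, "age": row.age, "isd": row.isd,
            "clustering": row.clustering, "true_lambda": float(lam),
            "origin_edge": origin, "n_loss_events": n_loss,
            "n_redraws": n_redraws, "n_present_true": len(true_species),
        })
    truth = {"pfams": pd.DataFrame(pfam_rows), "presence": pd.DataFrame(fp_rows)}
    return patterns, truth


# -- sequences -------------------------------------------------------------

_HYDRO = "LIVFMW"
_OTHER = "ACDEGHKNPQRSTY"


def _place_positions(L: int, m: int, target: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Choose m hydrophobic positions in 0..L-1 with tunable clumping."""
    if target == 1.0:
        return rng.choice(L, size=m, replace=False)
    if target > 1.0:
        # runs of expected length `target`; merging of runs only clusters more
        taken = np.zeros(L, dtype=bool)
        placed = 0
        while placed < m:
            run = 1 + rng.poisson(target - 1.0)
            start = int(rng.integers(L))
            for k in range(start, min(start + run, L)):
                if not taken[k]:
                    taken[k] = True
                    placed += 1
                    if placed == m:
                        break
        return np.flatnonzero(taken)
    # target < 1: stratified placement, jitter width shrinking with target
    spacing = L / m
    ideal = (np.arange(m) + 0.5) * spacing
    jitter = rng.uniform(-0.5, 0.5, size=m) * spacing * target
    pos = np.clip(np.round(ideal + jitter).astype(int), 0, L - 1)
    pos = np.unique(pos)
    while len(pos) < m:  # collisions: fill uniformly at random
        extra = rng.choice(np.setdiff1d(np.arange(L), pos),
                           size=m - len(pos), replace=False)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def make_sequences(
    traits: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> list[tuple[str, str]]:
    """(header, sequence) pairs whose hydrophobic arrangement tracks each
    domain's clustering target monotonically.

    Headers follow ``pfamid|species|instance_n``.  The hydrophobic count
    is binomial with the configured fraction; zero fraction is infeasible.
    """
    if config.hydrophobic_fraction <= 0:
        raise ValueError("hydrophobic fraction must be positive")
    if config.hydrophobic_fraction >= 1:
        raise ValueError("hydrophobic fraction must be below 1")
    rng = rng if rng is not None else config.rng()
    L = config.seq_length
    out = []
    for row in traits.itertuples(index=False):
        target = float(row.clustering)
        if target < 0:
            raise ValueError(f"{row.pfam_id}: negative clustering target")
        for k in range(config.instances_per_pfam):
            m = rng.binomial(L, config.hydrophobic_fraction)
            m = max(1, min(m, L - 1))
            pos = _place_positions(L, m, target, rng)
            seq = rng.choice(list(_OTHER), size=L)
            seq[pos] = rng.choice(list(_HYDRO), size=len(pos))
            out.append((f"{row.pfam_id}|sp{k + 1}|instance_{k + 1}",
                        "".join(seq)))
    return out


def simulate_dataset(config: SimConfig, outdir: str | Path | None = None):
    """Generate the full synthetic data set (and optionally write it).

    Returns (tree, traits, patterns, truth, sequences).  When ``outdir``
    is given, writes tree.nwk, presence.tsv, traits.tsv, instances.fasta
    and truth/*.tsv.
    """
    rng = config.rng()
    tree = make_tree(config, rng)
    traits = sample_traits(config, rng)
    patterns, truth = make_presence(tree, traits, config, rng)
    sequences = make_sequences(traits, config, rng)
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        from .treeio import write_presence, write_tree
        write_tree(tree, outdir / "tree.nwk")
        write_presence(patterns, outdir / "presence.tsv")
        traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)
        with open(outdir / "instances.fasta", "w") as fh:
            for header, seq in sequences:
                fh.write(f">{header}\n{seq}\n")
        for name, df in truth.items():
            df.to_csv(outdir / "truth" / f"{name}.tsv", sep="\t", index=False)
    return tree, traits, patterns, truth, sequences


def realized_fp_fractions(truth: dict[str, pd.DataFrame]) -> tuple[float, float]:
    """Realized (f_c, f_i): the fraction of presences of each evidence
    class that are planted false positives."""
    pres = truth["presence"]
    out = []
    for ev in ("coding", "intergenic"):
        sub = pres[pres["evidence"] == ev]
        out.append(float(sub["is_false"].mean()) if len(sub) else 0.0)
    return out[0], out[1]
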
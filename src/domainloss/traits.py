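"""Hydrophobic clustering and intrinsic structural disorder (ISD) per domain.

Clustering is a normalized index of dispersion of the six most hydrophobic
amino acids (Leu, Ile, Val, Phe, Met, Trp) counted in non-overlapping
blocks of six consecutive residues.  When the sequence length is not a
multiple of six, the statistic is averaged over the six possible reading
frames, truncating incomplete tail blocks.  The raw dispersion is divided
by its expectation under uniformly random placement of the same number of
hydrophobic residues along the same length, so a score of 1 means random
arrangement, above 1 clustered, below 1 interspersed.

The null expectation has a closed form.  Condition on the number ``s`` of
hydrophobic residues falling inside a frame's window of ``n = 6B``
positions: block counts are then multivariate hypergeometric, their mean
is exactly s/B, and

    E[ var_pop(counts) / mean(counts) | s ] = ((n-6)/(n-1)) * (1 - s/n).

The per-frame null averages this over s ~ Hypergeom(L, m, n) conditional
on s >= 1.  A permutation null (shuffling the hydrophobicity mask) is
available as an independent cross-check.

ISD values are consumed as precomputed per-residue scores in [0, 1]
(disorder prediction itself is upstream): an instance's score is the mean
over its residues and a domain's score the unweighted mean over all its
instances in the data set, so species contributing more instances weigh
more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "HYDROPHOBIC",
    "InstanceSequence",
    "PfamTraits",
    "hydrophobic_mask",
    "frame_dispersion",
    "null_dispersion",
    "clustering_score",
    "pfam_clustering",
    "pfam_isd",
    "read_instances",
    "aggregate_isd",
    "compute_traits_table",
]

HYDROPHOBIC = frozenset("LIVFMW")
MIN_LEN = 6  # instances shorter than this are skipped


@dataclass(frozen=True)
class InstanceSequence:
    pfam_id: str
    species: str
    aa_sequence: str


@dataclass
class PfamTraits:
    """Per-domain trait summary used by the trend analyses."""

    pfam_id: str
    isd: float              # mean disorder, [0, 1]
    clustering: float       # dimensionless, >= 0
    age: float = np.nan     # My
    mean_instances: float = np.nan  # instances/genome


def hydrophobic_mask(seq: str, hydrophobic: frozenset = HYDROPHOBIC) -> np.ndarray:
    """0/1 vector marking the hydrophobic residues of ``seq``.

    Case-insensitive; nonstandard letters count as non-hydrophobic.
    """
    if not seq:
        raise ValueError("empty sequence")
    return np.array([1 if c in hydrophobic else 0 for c in seq.upper()],
                    dtype=np.int64)


def frame_dispersion(mask: np.ndarray, frame: int) -> float:
    """var/mean of block-of-6 hydrophobic counts for one reading frame.

    Drops ``frame`` leading positions and the incomplete tail block.
    Population variance; returns NaN (undefined) when the window holds no
    hydrophobic residues.  Raises if no complete block remains.
    """
    if not 0 <= frame <= 5:
        raise ValueError("frame must be in 0..5")
    mask = np.asarray(mask)
    n_blocks = (len(mask) - frame) // 6
    if n_blocks < 1:
        raise ValueError(f"no complete block of 6 at frame {frame}")
    window = mask[frame : frame + 6 * n_blocks]
    counts = window.reshape(n_blocks, 6).sum(axis=1)
    mean = counts.mean()
    if mean == 0:
        return np.nan
    return float(counts.var() / mean)  # population variance


@lru_cache(maxsize=65536)
def null_dispersion(length: int, n_hydro: int, frame: int) -> float:
    """Closed-form null expectation of :func:`frame_dispersion`.

    Expectation under uniformly random placement of ``n_hydro`` ones in a
    mask of ``length`` positions, conditional on the frame window holding
    at least one.
    """
    n_blocks = (length - frame) // 6
    if n_blocks < 1:
        raise ValueError(f"no complete block of 6 at frame {frame}")
    n = 6 * n_blocks
    if n_blocks == 1 or n_hydro == 0:
        return 0.0 if n_hydro else np.nan
    p0 = hypergeom.pmf(0, length, n_hydro, n)
    if p0 >= 1.0:
        return np.nan
    e_s = n * n_hydro / length / (1.0 - p0)
    return float((n - 6) / (n - 1) * (1.0 - e_s / n))


def _frame_average(mask: np.ndarray) -> float:
    """Mean dispersion over the usable frames; NaN if none is informative."""
    vals = []
    for f in range(6):
        if (len(mask) - f) // 6 < 1:
            continue  # short tail: frame dropped
        d = frame_dispersion(mask, f)
        if np.isfinite(d):
            vals.append(d)
    return float(np.mean(vals)) if vals else np.nan


def clustering_score(
    seq: str,
    null: str = "closed_form",
    nperm: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Normalized hydrophobic clustering of one amino-acid sequence.

    Mean over reading frames of the block dispersion, divided by the null
    expectation of the same frame average for random placement given the
    sequence's length and hydrophobic count.  Returns NaN (undefined) for
    sequences with no hydrophobic residues or too short to hold two blocks
    in any frame.

    Parameters
    ----------
    null
        ``"closed_form"`` (default, deterministic) or ``"permute"`` (Monte
        Carlo over ``nperm`` shuffles of the mask; needs ``rng``).
    """
    if len(seq) < MIN_LEN:
        raise ValueError(f"sequence shorter than {MIN_LEN} residues")
    mask = hydrophobic_mask(seq)
    m = int(mask.sum())
    if m == 0:
        return np.nan
    observed = _frame_average(mask)
    if not np.isfinite(observed):
        return np.nan

    if null == "closed_form":
        expect = [
            null_dispersion(len(mask), m, f)
            for f in range(6)
            if (len(mask) - f) // 6 >= 1
        ]
        null_mean = float(np.nanmean(expect))
    elif null == "permute":
        rng = rng if rng is not None else np.random.default_rng()
        sims = np.empty(nperm)
        shuffled = mask.copy()
        for i in range(nperm):
            rng.shuffle(shuffled)
            sims[i] = _frame_average(shuffled)
        null_mean = float(np.nanmean(sims))
    else:
        raise ValueError(f"unknown null {null!r}")

    if not null_mean > 0:
        return np.nan  # degenerate geometry (e.g. every frame a single block)
    return observed / null_mean


def pfam_clustering(instances: Iterable[InstanceSequence], **kwargs) -> float:
    """Unweighted mean clustering over all scorable instances of one domain.

    Instances shorter than 6 residues, or with no hydrophobic residues, are
    skipped with a warning; raises if nothing is scorable.
    """
    scores = []
    for inst in instances:
        if len(inst.aa_sequence) < MIN_LEN:
            logger.warning(
                "%s/%s: instance of length %d skipped (< %d)",
                inst.pfam_id, inst.species, len(inst.aa_sequence), MIN_LEN,
            )
            continue
        s = clustering_score(inst.aa_sequence, **kwargs)
        if np.isfinite(s):
            scores.append(s)
        else:
            logger.warning(
                "%s/%s: clustering undefined (no usable hydrophobics)",
                inst.pfam_id, inst.species,
            )
    if not scores:
        raise ValueError("no scorable instances for this domain")
    return float(np.mean(scores))


def pfam_isd(instance_residue_scores: Sequence[Sequence[float]]) -> float:
    """Mean ISD of a domain from per-instance per-residue disorder scores.

    Each instance's score is the mean over its residues; the domain score
    is the mean over instances.  Scores outside [0, 1] raise.
    """
    means = []
    for scores in instance_residue_scores:
        arr = np.asarray(scores, dtype=float)
        if arr.size == 0:
            raise ValueError("instance with no residue scores")
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("disorder scores must lie in [0, 1]")
        means.append(arr.mean())
    if not means:
        raise ValueError("no instances")
    return float(np.mean(means))


# -- I/O helpers -----------------------------------------------------------

def read_instances(path: str | Path) -> list[InstanceSequence]:
    """Read instance sequences from FASTA with ``>pfamid|species|instance_n``
    headers."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise ValueError(f"malformed FASTA header {rec.id!r}")
        out.append(InstanceSequence(parts[0], parts[1], str(rec.seq)))
    return out


def aggregate_isd(disorder: pd.DataFrame) -> pd.Series:
    """Per-domain mean ISD from a long table of per-residue scores.

    Expects columns pfam_id, species, instance, score (a position column is
    allowed and ignored).
    """
    if np.any((disorder["score"] < 0) | (disorder["score"] > 1)):
        raise ValueError("disorder scores must lie in [0, 1]")
    inst = disorder.groupby(["pfam_id", "species", "instance"])["score"].mean()
    return inst.groupby("pfam_id").mean().rename("isd")


def compute_traits_table(
    instances: Iterable[InstanceSequence], disorder: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-domain traits table (pfam_id, clustering, n_instances[, isd])."""
    by_pfam: dict[str, list[InstanceSequence]] = {}
    for inst in instances:
        by_pfam.setdefault(inst.pfam_id, []).append(inst)
    rows = []
    for pfam_id in sorted(by_pfam):
        try:
            c = pfam_clustering(by_pfam[pfam_id])
        except ValueError:
            logger.warning("%s: dropped (no scorable instances)", pfam_id)
            continue
        rows.append({"pfam_id": pfam_id, "clustering": c,
                     "n_instances": len(by_pfam[pfam_id])})
    df = pd.DataFrame(rows)
    if disorder is not None and len(df):
        df = df.merge(aggregate_isd(disorder).reset_index(), on="pfam_id", how="left")
    return df
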
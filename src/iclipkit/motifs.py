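"""Pentamer z-score analysis of sequence around crosslink sites.

For each 5-mer, the observed occurrence (overlapping counts summed over
strand-aware flanking windows) is compared with its occurrence in
randomized control sequence sets:

    z = (observed - mean over control sets) / sd over control sets

Controls are per-window mononucleotide shuffles, so each control window
preserves the original window's base composition exactly.  A
dinucleotide-preserving shuffle is available as an option.  Genotype
contrast ranks pentamers by the difference of their z-scores between two
libraries.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

K = 5
PENTAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=K)]


def extract_flanks(
    events: pd.DataFrame,
    sequences: dict[str, str],
    half_width: int = 30,
) -> list[str]:
    """Strand-aware windows of 2*half_width + 1 nt around crosslink sites.

    Minus-strand windows are reverse-complemented.  Windows that would
    run past a sequence end are dropped (and logged).
    """
    windows: list[str] = []
    dropped = 0
    for row in events.itertuples():
        seq = sequences.get(row.chrom)
        if seq is None:
            raise KeyError(f"no sequence for {row.chrom!r}")
        pos = int(row.position)
        if pos < 0 or pos >= len(seq):
            raise IndexError(f"event at {pos} beyond {row.chrom} bounds")
        lo, hi = pos - half_width, pos + half_width + 1
        if lo < 0 or hi > len(seq):
            dropped += 1
            continue
        win = seq[lo:hi]
        if row.strand == "-":
            win = str(Seq(win).reverse_complement())
        windows.append(win)
    if dropped:
        logger.info("dropped %d truncated windows at sequence ends", dropped)
    return windows


def _count_kmers(windows: list[str]) -> np.ndarray:
    """Overlapping 5-mer occurrences summed over windows (length-1024)."""
    idx = {p: i for i, p in enumerate(PENTAMERS)}
    out = np.zeros(len(PENTAMERS), dtype=np.int64)
    for w in windows:
        for i in range(len(w) - K + 1):
            j = idx.get(w[i : i + K])
            if j is not None:  # skip k-mers with non-ACGT characters
                out[j] += 1
    return out


def _shuffle_window(w: str, rng: np.random.Generator, dinucleotide: bool) -> str:
    if not dinucleotide:
        return "".join(rng.permutation(list(w)))
    # simple dinucleotide-preserving shuffle: permute non-overlapping pairs
    pairs = [w[i : i + 2] for i in range(0, len(w) - 1, 2)]
    tail = w[len(pairs) * 2 :]
    return "".join(rng.permutation(pairs)) + tail


def shuffled_controls(
    windows: list[str],
    n_random: int,
    seed: int = 0,
    dinucleotide: bool = False,
) -> list[list[str]]:
    """``n_random`` randomized control sets, one shuffle per window each."""
    rng = np.random.default_rng([8, seed])
    return [
        [_shuffle_window(w, rng, dinucleotide) for w in windows]
        for _ in range(n_random)
    ]


def zscores_from_controls(obs: np.ndarray, ctrl_counts: np.ndarray) -> np.ndarray:
    """z = (obs - control mean) / control sd per k-mer.

    A zero control sd yields z = 0 when the observation equals the mean
    and a +/-inf sentinel otherwise.
    """
    mean = ctrl_counts.mean(axis=0)
    sd = ctrl_counts.std(axis=0, ddof=0)
    z = np.zeros(len(obs), dtype=float)
    nonzero = sd > 0
    z[nonzero] = (obs[nonzero] - mean[nonzero]) / sd[nonzero]
    degen = ~nonzero & (obs != mean)
    z[degen] = np.where(obs[degen] > mean[degen], np.inf, -np.inf)
    return z


def pentamer_zscores(
    windows: list[str],
    n_random: int = 100,
    seed: int = 0,
    dinucleotide: bool = False,
) -> pd.DataFrame:
    """Z-score table over all 1024 pentamers, sorted by z descending.

    When the control sd is zero the z-score is 0 if the observation
    equals the control mean and +/-inf otherwise (flagged sentinel).
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    if not windows:
        raise ValueError("empty window set")
    obs = _count_kmers(windows)
    controls = shuffled_controls(windows, n_random, seed=seed, dinucleotide=dinucleotide)
    ctrl_counts = np.stack([_count_kmers(c) for c in controls])
    mean = ctrl_counts.mean(axis=0)
    sd = ctrl_counts.std(axis=0, ddof=0)
    z = zscores_from_controls(obs, ctrl_counts)

    table = pd.DataFrame(
        {"pentamer": PENTAMERS, "obs": obs, "mean": mean, "sd": sd, "z": z}
    )
    return table.sort_values("z", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def significant_site_events(events: pd.DataFrame, clusters: pd.DataFrame) -> pd.DataFrame:
    """Restrict events to those inside significant cluster windows.

    ``clusters`` is a per-cluster table with gene_id/window_start/
    window_end columns (as returned by ``genotype_occupancy``).  By
    default the z-score evaluation uses these cluster sites rather than
    every crosslink site.
    """
    if clusters.empty:
        return events.iloc[0:0]
    keep = np.zeros(len(events), dtype=bool)
    pos = events["position"].to_numpy()
    for row in clusters.itertuples():
        keep |= (pos >= row.window_start) & (pos < row.window_end)
    return events[keep]


def genotype_contrast(z_a: pd.DataFrame, z_b: pd.DataFrame) -> pd.DataFrame:
    """Delta-z = z_a - z_b per pentamer, ranked descending.

    Typically ``z_a`` is the wildtype table and ``z_b`` the null
    (background) genotype, so high delta-z marks binding-specific
    sequence preference.
    """
    a = z_a.set_index("pentamer")["z"]
    b = z_b.set_index("pentamer")["z"]
    if set(a.index) != set(b.index):
        raise ValueError("pentamer universes differ between tables")
    dz = (a - b.reindex(a.index)).rename("delta_z")
    out = dz.sort_values(ascending=False, kind="mergesort").reset_index()
    return out
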
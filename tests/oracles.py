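"""Independent reference computations used to check the pipeline.

Everything here is deliberately written with explicit loops and exact
arithmetic, not by calling the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

ALL_PENTAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=5)]


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by explicit enumeration."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return acc


def fisher_two_sided_exact(table) -> Fraction:
    """Two-sided Fisher exact p via conditional point probabilities.

    Enumerates every 2x2 table with the observed margins and sums the
    probabilities of tables no more likely than the observed one.
    Exact rational arithmetic throughout.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return Fraction(1)

    # integer numerators of the conditional pmf (common denominator C(n, c1))
    def weight(x: int) -> int:
        return math.comb(r1, x) * math.comb(r2, c1 - x)

    w_obs = weight(a)
    total = sum(
        w for w in (weight(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1))
        if w <= w_obs
    )
    return Fraction(total, math.comb(n, c1))


def pentamer_table_bruteforce(windows, controls):
    """(obs, mean, sd, z) per pentamer by explicit loops.

    ``controls`` is a list of control window sets (the same randomized
    sequences the implementation used).  sd is the population standard
    deviation; sd == 0 gives z = 0 when obs equals the mean and an
    infinite sentinel otherwise.
    """

    def count_all(seqs):
        out = {}
        for p in ALL_PENTAMERS:
            c = 0
            for s in seqs:
                for i in range(len(s) - 4):
                    if s[i : i + 5] == p:
                        c += 1
            out[p] = c
        return out

    obs = count_all(windows)
    per_control = [count_all(cset) for cset in controls]
    table = {}
    for p in ALL_PENTAMERS:
        vals = [pc[p] for pc in per_control]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        sd = math.sqrt(var)
        if sd > 0:
            z = (obs[p] - mean) / sd
        elif obs[p] == mean:
            z = 0.0
        else:
            z = math.inf if obs[p] > mean else -math.inf
        table[p] = (obs[p], mean, sd, z)
    return table


def anova_two_way_hand(cells: dict[tuple[int, int], list[float]]):
    """Balanced two-way fixed-effects ANOVA worked from sums of squares.

    ``cells[(i, j)]`` holds replicate values for factor-A level i and
    factor-B level j.  Returns (F_A, F_B, F_interaction).
    """
    levels_a = sorted({i for i, _ in cells})
    levels_b = sorted({j for _, j in cells})
    r = len(next(iter(cells.values())))
    all_vals = [v for vs in cells.values() for v in vs]
    n = len(all_vals)
    grand = sum(all_vals) / n

    mean_cell = {ij: sum(vs) / len(vs) for ij, vs in cells.items()}
    mean_a = {
        i: sum(mean_cell[(i, j)] for j in levels_b) / len(levels_b) for i in levels_a
    }
    mean_b = {
        j: sum(mean_cell[(i, j)] for i in levels_a) / len(levels_a) for j in levels_b
    }

    ss_a = r * len(levels_b) * sum((mean_a[i] - grand) ** 2 for i in levels_a)
    ss_b = r * len(levels_a) * sum((mean_b[j] - grand) ** 2 for j in levels_b)
    ss_ab = r * sum(
        (mean_cell[(i, j)] - mean_a[i] - mean_b[j] + grand) ** 2
        for i in levels_a
        for j in levels_b
    )
    ss_err = sum(
        (v - mean_cell[ij]) ** 2 for ij, vs in cells.items() for v in vs
    )
    df_err = n - len(levels_a) * len(levels_b)
    ms_err = ss_err / df_err
    df_a, df_b = len(levels_a) - 1, len(levels_b) - 1
    df_ab = df_a * df_b
    return (ss_a / df_a / ms_err, ss_b / df_b / ms_err, ss_ab / df_ab / ms_err)


def recount_bed_3utr_fraction(bed_path, ann_path, targets) -> float:
    """Fraction of target-gene reads whose crosslink lies in a 3'UTR.

    Parses the emitted BED and annotation TSV with plain string
    handling, independent of the package's readers.
    """
    utr3, spans = {}, {}
    with open(ann_path) as fh:
        fh.readline()  # chrom_len line
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            gid, strand = f[col["gene_id"]], f[col["strand"]]
            s, e = int(f[col["start"]]), int(f[col["end"]])
            if gid.endswith("_nc"):
                continue
            if f[col["seg_type"]] == "3UTR":
                utr3[gid] = (s, e, strand)
            lo, hi, st = spans.get(gid, (s, e, strand))
            spans[gid] = (min(lo, s), max(hi, e), strand)

    targets = set(targets)
    in_target, in_utr3 = 0, 0
    with open(bed_path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            start, strand = int(f[1]), f[5]
            xl = start - 1 if strand == "+" else start + 1
            for gid in targets:
                lo, hi, st = spans[gid]
                if st == strand and lo <= xl < hi:
                    in_target += 1
                    us, ue, _ = utr3[gid]
                    if us <= xl < ue:
                        in_utr3 += 1
                    break
    return in_utr3 / in_target if in_target else float("nan")
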
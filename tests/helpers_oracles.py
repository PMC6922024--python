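"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately naive re-derivations (exhaustive enumeration, direct
per-locus recounts, textbook variance components coded with scalar loops) so
they stay independent of the library's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# ROH: exhaustive interval enumeration
# ---------------------------------------------------------------------------


def roh_intervals_brute(
    dosage_row: np.ndarray,
    pos: np.ndarray,
    max_het: int,
    max_missing: int,
    min_snps: int,
    min_length_bp: int,
) -> list[tuple[int, int]]:
    """All qualifying (start_idx, end_idx) runs on one chromosome, resolved
    exactly as documented: enumerate every interval, keep the valid ones,
    drop any strictly contained in another valid interval, then greedily
    select left-to-right (ties toward the longer run)."""
    m = len(dosage_row)
    valid = []
    for a in range(m):
        if dosage_row[a] not in (0, 2):
            continue
        for b in range(a, m):
            if dosage_row[b] not in (0, 2):
                continue
            window = dosage_row[a : b + 1]
            n_het = int(np.sum(window == 1))
            n_mis = int(np.sum(window == MISSING))
            if n_het > max_het or n_mis > max_missing:
                continue
            if (b - a + 1) < min_snps:
                continue
            if (pos[b] - pos[a]) < min_length_bp:
                continue
            valid.append((a, b))
    maximal = [
        (a, b)
        for (a, b) in valid
        if not any((a2 <= a and b2 >= b and (a2, b2) != (a, b)) for a2, b2 in valid)
    ]
    maximal.sort(key=lambda ab: (ab[0], -(ab[1] - ab[0])))
    chosen: list[tuple[int, int]] = []
    last_end = -1
    for a, b in maximal:
        if a <= last_end:
            continue
        chosen.append((a, b))
        last_end = b
    return chosen


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components, scalar re-derivation
# ---------------------------------------------------------------------------


def wc_theta_brute(
    dosage_a: np.ndarray, dosage_b: np.ndarray
) -> float:
    """Two-population multilocus theta from per-locus a, b, c, scalar math."""
    r = 2
    sum_a = 0.0
    sum_abc = 0.0
    n_loci = dosage_a.shape[1]
    for j in range(n_loci):
        stats = []
        for d in (dosage_a[:, j], dosage_b[:, j]):
            calls = d[d != MISSING]
            if len(calls) < 2:
                stats = None
                break
            n = float(len(calls))
            p = float(np.sum(calls)) / (2.0 * n)
            h = float(np.sum(calls == 1)) / n
            stats.append((n, p, h))
        if stats is None:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        if (p1 == p2) and (p1 in (0.0, 1.0)):
            continue  # monomorphic across both
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / r - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


# ---------------------------------------------------------------------------
# misc direct recounts
# ---------------------------------------------------------------------------


def ibs_distance_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Allele-sharing distance between two dosage vectors, per-locus loop."""
    shared = 0
    loci = 0
    for xv, yv in zip(x, y):
        if xv == MISSING or yv == MISSING:
            continue
        loci += 1
        shared += 2 - abs(int(xv) - int(yv))
    return 1.0 - shared / (2.0 * loci)


def rarefied_richness_brute(allele_counts: list[int], g: int) -> float:
    """Hypergeometric rarefaction from integer allele copy counts."""
    total = sum(allele_counts)
    out = 0.0
    for na in allele_counts:
        if na == 0:
            continue
        out += 1.0 - math.comb(total - na, g) / math.comb(total, g)
    return out


def r2_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over jointly non-missing entries."""
    ok = (x != MISSING) & (y != MISSING)
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)
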
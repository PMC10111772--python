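"""Independent oracle implementations used by the acceptance suite.

Everything here is written as direct, explicit evaluation of the published
formulas (python loops, scalar arithmetic), deliberately sharing no code with
the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

from founderpop.roh import ROHParams
from founderpop.variant_store import MISSING


def brute_force_roh(positions, genotypes, params=ROHParams()):
    """Exhaustive window enumeration ROH scanner on one chromosome.

    Maintains explicit sliding het/missing counters, rates every SNP by the
    homozygous fraction of the windows containing it, then applies the run
    constraints one by one.
    """
    n = len(positions)
    w = params.window_snp
    if n < w:
        return []
    hom_windows = []
    n_het = sum(1 for g in genotypes[:w] if g == 1)
    n_mis = sum(1 for g in genotypes[:w] if g == MISSING)
    for start in range(n - w + 1):
        if start > 0:
            left, right = int(genotypes[start - 1]), int(genotypes[start + w - 1])
            n_het += int(right == 1) - int(left == 1)
            n_mis += int(right == MISSING) - int(left == MISSING)
        hom_windows.append(n_het <= params.window_het
                           and n_mis <= params.window_missing)
    prefix = [0]
    for flag in hom_windows:
        prefix.append(prefix[-1] + flag)
    passing = []
    for t in range(n):
        lo = max(t - w + 1, 0)
        hi = min(t, n - w)
        hits = prefix[hi + 1] - prefix[lo]
        passing.append(hits / (hi - lo + 1) >= params.window_hit_threshold)
    segments, run = [], []
    for t in range(n):
        if not passing[t]:
            if run:
                segments.append(run)
                run = []
            continue
        if run and positions[t] - positions[run[-1]] > params.max_gap_kb * 1000:
            segments.append(run)
            run = []
        run.append(t)
    if run:
        segments.append(run)
    out = []
    for seg in segments:
        length = positions[seg[-1]] - positions[seg[0]] + 1
        if len(seg) < params.min_snp or length < params.min_kb * 1000:
            continue
        if length / len(seg) > params.density_kb * 1000:
            continue
        out.append((int(positions[seg[0]]), int(positions[seg[-1]]),
                    len(seg), int(length)))
    return out


def random_roh_chromosome(rng, n_snps):
    """Random genotypes over one chromosome with a planted homozygous tract."""
    pos = np.sort(rng.choice(np.arange(1, n_snps * 4000), n_snps, replace=False))
    g = rng.choice([0, 1, 2, MISSING], size=n_snps,
                   p=[0.35, 0.35, 0.25, 0.05]).astype(np.int8)
    if n_snps > 600:
        start = int(rng.integers(100, n_snps - 500))
        width = int(rng.integers(150, 450))
        g[start:start + width] = rng.choice([0, 2], size=width)
    return pos, g


# ------------------------------------------------------- direct formula oracles

def pi_direct(dosages):
    """Per-site nucleotide diversity summed over sites, by explicit pair
    counting of allele copies."""
    total = 0.0
    for site in zip(*dosages):
        copies = []
        for d in site:
            if d != MISSING:
                copies.extend([1] * d + [0] * (2 - d))
        n = len(copies)
        if n < 2:
            continue
        diff = 0
        for i in range(n):
            for j in range(i + 1, n):
                diff += copies[i] != copies[j]
        total += diff / (n * (n - 1) / 2)
    return total


def theta_w_direct(dosages):
    """Watterson's theta numerator: sum over segregating sites of 1/a_n."""
    total = 0.0
    for site in zip(*dosages):
        called = [d for d in site if d != MISSING]
        n = 2 * len(called)
        j = sum(called)
        if n >= 2 and 0 < j < n:
            total += 1.0 / sum(1.0 / i for i in range(1, n))
    return total


def p_distance_direct(a, b):
    num = den = 0
    for x, y in zip(a, b):
        if x == MISSING or y == MISSING:
            continue
        num += abs(x - y) / 2.0
        den += 1
    return num / den if den else float("nan")


def wc84_fst_direct(dos_a, dos_b):
    """Weir & Cockerham 1984 weighted FST by scalar per-site accumulation."""
    sum_a = sum_abc = 0.0
    r = 2
    for sa, sb in zip(zip(*dos_a), zip(*dos_b)):
        stats = []
        for site in (sa, sb):
            called = [d for d in site if d != MISSING]
            if not called:
                break
            n = len(called)
            p = sum(called) / (2 * n)
            h = sum(1 for d in called if d == 1) / n
            stats.append((n, p, h))
        if len(stats) < 2:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                         / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc if sum_abc else float("nan")


def _freq(site):
    called = [d for d in site if d != MISSING]
    return sum(called) / (2 * len(called)) if called else float("nan")


def d_statistic_direct(dos1, dos2, dos3, dos4):
    """ABBA-BABA D from derived frequencies, scalar accumulation."""
    num = den = 0.0
    for s1, s2, s3, s4 in zip(zip(*dos1), zip(*dos2), zip(*dos3), zip(*dos4)):
        p1, p2, p3, p4 = _freq(s1), _freq(s2), _freq(s3), _freq(s4)
        if any(np.isnan(p) for p in (p1, p2, p3, p4)):
            continue
        abba = (1 - p1) * p2 * p3 * (1 - p4)
        baba = p1 * (1 - p2) * p3 * (1 - p4)
        num += abba - baba
        den += abba + baba
    return num / den if den else float("nan")


def f4_direct(dos_w, dos_x, dos_y, dos_z):
    total = 0.0
    for sw, sx, sy, sz in zip(zip(*dos_w), zip(*dos_x), zip(*dos_y), zip(*dos_z)):
        pw, px, py, pz = _freq(sw), _freq(sx), _freq(sy), _freq(sz)
        if any(np.isnan(p) for p in (pw, px, py, pz)):
            continue
        total += (pw - px) * (py - pz)
    return total


def rxy_direct(dos_x, dos_y):
    lxy = lyx = 0.0
    for sx, sy in zip(zip(*dos_x), zip(*dos_y)):
        dx, dy = _freq(sx), _freq(sy)
        if np.isnan(dx) or np.isnan(dy):
            continue
        lxy += dx * (1 - dy)
        lyx += dy * (1 - dx)
    return lxy / lyx if lyx else float("nan")
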
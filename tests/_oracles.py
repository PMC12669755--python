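"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by direct enumeration / explicit
loops, staying independent of the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


# -- target calling ---------------------------------------------------------

def call_targets_oracle(experiment, condition, min_rpm, min_fc, pseudocount):
    """Per-gene, per-replicate literal evaluation of the target rule."""
    design = experiment.design
    sizes = experiment.library_sizes
    pairs = {}
    for lib, row in design.iterrows():
        if row["condition"] != condition:
            continue
        pairs.setdefault(row["replicate"], {})[row["role"]] = lib
    called = set()
    for gene in experiment.counts.index:
        ok = True
        for rep, libs in pairs.items():
            ip = experiment.counts.loc[gene, libs["IP"]] / sizes[libs["IP"]] * 1e6
            inp = experiment.counts.loc[gene, libs["input"]] / sizes[libs["input"]] * 1e6
            fc = (ip + pseudocount) / (inp + pseudocount)
            if not (ip >= min_rpm and fc >= min_fc):
                ok = False
                break
        if ok:
            called.add(gene)
    return called


# -- metagene binning -------------------------------------------------------

def metagene_oracle(coverage, targets, library_size, n_bins=100):
    """Per-position accumulation with explicit loops."""
    targets = sorted(set(targets))
    per_gene = []
    for g in targets:
        counts = coverage.per_gene[g]
        L = len(counts)
        sums = [0.0] * n_bins
        npos = [0] * n_bins
        for p in range(L):
            b = (p * n_bins) // L
            sums[b] += counts[p] * 1e6 / library_size
            npos[b] += 1
        per_gene.append(
            [sums[b] / npos[b] if npos[b] else 0.0 for b in range(n_bins)]
        )
    return np.mean(np.array(per_gene), axis=0)


# -- Fisher / BH ------------------------------------------------------------

def fisher_pvec_oracle(U, a, b):
    """Exact two-sided p for every admissible overlap, integer weights.

    Enumerates the hypergeometric support with exact binomial
    coefficients; the two-sided p for overlap k sums the probabilities
    of all tables no more probable than the observed one.
    """
    lo, hi = max(0, a + b - U), min(a, b)
    ks = list(range(lo, hi + 1))
    w = [math.comb(a, k) * math.comb(U - a, b - k) for k in ks]
    tot = math.comb(U, b)
    return ks, [sum(x for x in w if x <= wk) / tot for wk in w]


def bh_oracle(pvals):
    """Benjamini-Hochberg from its step-up definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.array(adj)


# -- dipeptide segment scan -------------------------------------------------

def build_sf_table(l_min, l_max, background_freq):
    """sf[L][c] = P(X >= c), X ~ Binomial(L, f), for L in [l_min, l_max]."""
    table = {}
    for L in range(l_min, l_max + 1):
        counts = np.arange(0, L + 1)
        table[L] = stats.binom.sf(counts - 1, L, background_freq)
    return table


def find_segments_oracle(seq, focus, p_max, l_min, l_max, sf_table):
    """All-window enumeration, merge, min-p trim — explicit loops."""
    n = len(seq)
    cands = []
    for L in range(l_min, min(l_max, n) + 1):
        for s in range(0, n - L + 1):
            c = seq[s : s + L].count(focus)
            if sf_table[L][c] <= p_max:
                cands.append((s, s + L))
    if not cands:
        return []
    cands.sort()
    regions = []
    cs, ce = cands[0]
    for s, e in cands[1:]:
        if s < ce:
            ce = max(ce, e)
        else:
            regions.append((cs, ce))
            cs, ce = s, e
    regions.append((cs, ce))
    out = []
    for rs, re_ in regions:
        best = None
        for L in range(l_min, min(l_max, re_ - rs) + 1):
            for s in range(rs, re_ - L + 1):
                c = seq[s : s + L].count(focus)
                key = (float(sf_table[L][c]), -L, s)
                if best is None or key < best:
                    best = key
        p, negL, s = best
        out.append((s, s - negL, p))
    return sorted(out)


def binom_sf_exact(c, n, p_float):
    """Upper-tail P(X >= c) by exact rational summation.

    The success probability is taken as the exact rational value of the
    float, so the comparison with floating-point implementations is
    apples to apples.
    """
    from fractions import Fraction

    p = Fraction(p_float)
    q = 1 - p
    total = Fraction(0)
    for k in range(c, n + 1):
        total += math.comb(n, k) * p**k * q ** (n - k)
    return float(total)


# -- imaging ----------------------------------------------------------------

def partition_ratio_pixel_loop(query, granule_mask, cytoplasm_mask):
    """Per-plane ratio via explicit pixel loops."""
    ratios = []
    nz, ny, nx = query.shape
    for z in range(nz):
        gsum = gcnt = csum = ccnt = 0.0
        for y in range(ny):
            for x in range(nx):
                if granule_mask[z, y, x]:
                    gsum += query[z, y, x]
                    gcnt += 1
                elif cytoplasm_mask[z, y, x]:
                    csum += query[z, y, x]
                    ccnt += 1
        if gcnt and ccnt and csum:
            ratios.append((gsum / gcnt) / (csum / ccnt))
    return ratios


def digital_sphere_voxels(center, r_sq, shape):
    """Enumerate lattice voxels with squared distance <= r_sq."""
    voxels = []
    cz, cy, cx = center
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r_sq:
                    voxels.append((z, y, x))
    return voxels
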
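"""Independent literal-formula oracles used by the test suite.

Everything here is written as direct per-site / per-pair enumeration of the
textbook definitions, deliberately sharing no code with the package
implementations it checks.
"""

import numpy as np


# ---------------------------------------------------------------------------
# f-statistics (per-site loops over frequency arrays)


def f2_oracle(a, b, na, nb):
    vals = []
    for i in range(len(a)):
        if na[i] >= 2 and nb[i] >= 2:
            vals.append((a[i] - b[i]) ** 2
                        - a[i] * (1 - a[i]) / (na[i] - 1)
                        - b[i] * (1 - b[i]) / (nb[i] - 1))
    return sum(vals) / len(vals)


def f3_oracle(c, a, b, nc, na, nb, corrected=True):
    vals = []
    for i in range(len(c)):
        if nc[i] >= (2 if corrected else 1) and na[i] >= 1 and nb[i] >= 1:
            v = (c[i] - a[i]) * (c[i] - b[i])
            if corrected:
                v -= c[i] * (1 - c[i]) / (nc[i] - 1)
            vals.append(v)
    return sum(vals) / len(vals)


def f4_oracle(a, b, c, d, ns):
    vals = []
    for i in range(len(a)):
        if all(n[i] >= 1 for n in ns):
            vals.append((a[i] - b[i]) * (c[i] - d[i]))
    return sum(vals) / len(vals)


def d_oracle(p1, p2, p3, p4, ns):
    num = den = 0.0
    for i in range(len(p1)):
        if all(n[i] >= 1 for n in ns):
            abba = (1 - p1[i]) * p2[i] * p3[i] * (1 - p4[i])
            baba = p1[i] * (1 - p2[i]) * p3[i] * (1 - p4[i])
            num += abba - baba
            den += abba + baba
    return num / den


# ---------------------------------------------------------------------------
# EHH by pairwise enumeration


def ehh_oracle(alleles, focal, carriers, x):
    """EHH at site x: fraction of carrier pairs identical (and fully called)
    over every site between focal and x inclusive."""
    lo, hi = min(focal, x), max(focal, x)
    n = len(carriers)
    ident = 0
    for i in range(n):
        for j in range(i + 1, n):
            hi_, hj_ = alleles[lo:hi + 1, carriers[i]], alleles[lo:hi + 1, carriers[j]]
            if (hi_ >= 0).all() and (hj_ >= 0).all() and (hi_ == hj_).all():
                ident += 1
    return ident / (n * (n - 1) / 2)


def ihh_oracle(alleles, pos, focal, carriers, chrom_lo, chrom_hi,
               cutoff=0.05, pos_bp=None, max_gap_bp=None,
               max_steps=None, max_extend_bp=None):
    """Trapezoid-integrated EHH with the same stopping rules as the
    implementation, evaluated by brute-force pair enumeration.
    Returns (ihh, truncated)."""
    total = 0.0
    truncated = False
    for direction in (-1, 1):
        prev_pos, prev_ehh = pos[focal], 1.0
        s = focal
        steps = 0
        while True:
            nxt = s + direction
            if nxt < chrom_lo or nxt > chrom_hi:
                truncated |= prev_ehh > cutoff
                break
            if max_gap_bp is not None and \
                    abs(int(pos_bp[nxt]) - int(pos_bp[s])) > max_gap_bp:
                truncated |= prev_ehh > cutoff
                break
            if max_extend_bp is not None and \
                    abs(int(pos_bp[nxt]) - int(pos_bp[focal])) > max_extend_bp:
                break
            s = nxt
            e = ehh_oracle(alleles, focal, carriers, s)
            total += 0.5 * (prev_ehh + e) * abs(pos[s] - prev_pos)
            prev_pos, prev_ehh = pos[s], e
            if e <= cutoff or e == 0.0:
                break
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
    return total, truncated


# ---------------------------------------------------------------------------
# Garud H, Tajima's D, Hudson FST


def garud_oracle(hap_strings):
    """H statistics from a list of hashable haplotype identities."""
    from collections import Counter

    counts = Counter(hap_strings)
    p = sorted((c / len(hap_strings) for c in counts.values()), reverse=True)
    h1 = sum(x ** 2 for x in p)
    p1 = p[0]
    p2 = p[1] if len(p) > 1 else 0.0
    h12 = h1 + 2 * p1 * p2
    h2 = h1 - p1 ** 2
    return h1, h12, h2, h2 / h1


def tajima_oracle(alleles):
    """Tajima's D from a complete (no-missing) site × haplotype matrix,
    literal textbook constants."""
    S_sites, n = alleles.shape
    seg = []
    for s in range(S_sites):
        d = int(alleles[s].sum())
        if 0 < d < n:
            seg.append(s)
    S = len(seg)
    if S == 0 or n < 3:
        return np.nan
    # mean pairwise differences
    pi = 0.0
    npairs = n * (n - 1) / 2
    for i in range(n):
        for j in range(i + 1, n):
            pi += int((alleles[seg][:, i] != alleles[seg][:, j]).sum())
    pi /= npairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def hudson_oracle(p_a, p_b, n_a, n_b):
    """Ratio-of-averages Hudson FST over usable sites."""
    num = den = 0.0
    for i in range(len(p_a)):
        if n_a[i] >= 2 and n_b[i] >= 2:
            num += ((p_a[i] - p_b[i]) ** 2
                    - p_a[i] * (1 - p_a[i]) / (n_a[i] - 1)
                    - p_b[i] * (1 - p_b[i]) / (n_b[i] - 1))
            den += p_a[i] * (1 - p_b[i]) + p_b[i] * (1 - p_a[i])
    return num / den
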
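"""Allele-frequency f-statistics with weighted block-jackknife errors.

Implements the Patterson-style drift statistics used to dissect multi-wave
colonization: f2 (pairwise drift, small-sample corrected), f3 in both its
admixture form (significantly negative ⇒ the test group is admixed between
relatives of the two references) and outgroup form (shared drift between two
groups relative to an outgroup), f4 and the ABBA-BABA D-statistic for gene
flow, and a rank-0 multi-wave test: whether two groups relate to a set of
outgroups through a single shared ancestry wave (all f4(L1, L2; R_base, R_j)
jointly zero).

Standard errors come from a weighted delete-one block jackknife over
contiguous genomic blocks (Busing-style weights proportional to per-block
usable-site counts), which is robust to linkage disequilibrium.

Sign convention: D = Σ(ABBA − BABA) / Σ(ABBA + BABA) with
ABBA = (1−p1)·p2·p3·(1−p4); a single site with (p1..p4) = (0,1,1,0) gives
D = +1. Under the configuration (sister, test; focal, outgroup) an excess of
allele sharing between *test* and *focal* drives D negative, matching the
field's Z < −3 reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GroupFrequencies


@dataclass
class FStatResult:
    """One f-statistic with its jackknife error."""
    name: str
    config: tuple
    value: float
    se: float
    z: float
    n_blocks: int
    n_sites_used: int

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se > 0:
            assert abs(abs(self.z) * self.se - abs(self.value)) < 1e-9 * max(
                1.0, abs(self.value))


@dataclass
class RankTestResult:
    """Rank-0 (single ancestry wave) chi-square test."""
    left: tuple
    right_base: str
    right: tuple
    f4_vector: np.ndarray
    covariance: np.ndarray
    chi2: float
    dof: int
    p_value: float
    used_pseudoinverse: bool


# ---------------------------------------------------------------------------
# Weighted block jackknife


def weighted_jackknife(total_num: float, total_den: float,
                       block_num: np.ndarray, block_den: np.ndarray,
                       block_weight: np.ndarray):
    """Weighted delete-one-block jackknife for a ratio statistic
    est = total_num / total_den.

    Block weights are usable-site counts; with equal weights this reduces
    algebraically to the standard delete-1 jackknife variance.
    Returns (estimate, se).
    """
    keep = block_weight > 0
    bn, bd, m = block_num[keep], block_den[keep], block_weight[keep].astype(float)
    g = len(m)
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks")
    est = total_num / total_den
    loo = (total_num - bn) / (total_den - bd)
    n = m.sum()
    h = n / m
    theta_j = g * est - ((1.0 - m / n) * loo).sum()
    tau = h * est - (h - 1.0) * loo
    var = float((((tau - theta_j) ** 2) / (h - 1.0)).sum() / g)
    return est, np.sqrt(max(var, 0.0))


def _persite_jackknife(name, config, num, den, weight, blocks):
    """Assemble an FStatResult from per-site numerator/denominator arrays.

    ``num``/``den`` are zero at unused sites; ``weight`` is the usable-site
    indicator used for block weighting.
    """
    block_num = np.array([num[a:b].sum() for a, b in blocks])
    block_den = np.array([den[a:b].sum() for a, b in blocks])
    block_w = np.array([weight[a:b].sum() for a, b in blocks])
    n_used = int(weight.sum())
    if n_used == 0:
        raise ValueError(f"{name}: no usable sites")
    est, se = weighted_jackknife(num.sum(), den.sum(),
                                 block_num, block_den, block_w)
    z = est / se if se > 0 else (0.0 if est == 0 else np.inf * np.sign(est))
    return FStatResult(name, config, float(est), float(se), float(z),
                       int((block_w > 0).sum()), n_used)


# ---------------------------------------------------------------------------
# Per-site kernels


def _freqs(freqs: GroupFrequencies, *groups):
    ps = [freqs.freq(g) for g in groups]
    ns = [freqs.count(g) for g in groups]
    return ps, ns


def f2_sites(freqs: GroupFrequencies, A: str, B: str):
    """Per-site unbiased f2 contributions and the usable mask (n >= 2)."""
    (a, b), (na, nb) = _freqs(freqs, A, B)
    mask = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = ((a - b) ** 2
               - a * (1 - a) / (na - 1)
               - b * (1 - b) / (nb - 1))
    return np.where(mask, val, 0.0), mask


def f3_sites(freqs: GroupFrequencies, C: str, A: str, B: str,
             corrected: bool = True):
    """Per-site f3(C; A, B) contributions: (c−a)(c−b), optionally with the
    small-sample correction c(1−c)/(n_C − 1)."""
    (c, a, b), (nc, na, nb) = _freqs(freqs, C, A, B)
    mask = (nc >= (2 if corrected else 1)) & (na >= 1) & (nb >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = (c - a) * (c - b)
        if corrected:
            val = val - c * (1 - c) / (nc - 1)
    return np.where(mask, val, 0.0), mask


def f4_sites(freqs: GroupFrequencies, A: str, B: str, C: str, D: str):
    (a, b, c, d), ns = _freqs(freqs, A, B, C, D)
    mask = np.ones(len(a), dtype=bool)
    for n in ns:
        mask &= n >= 1
    val = (a - b) * (c - d)
    return np.where(mask, np.nan_to_num(val), 0.0), mask


def dstat_sites(freqs: GroupFrequencies, P1: str, P2: str, P3: str, P4: str):
    """Per-site ABBA and BABA weights for the D-statistic."""
    (p1, p2, p3, p4), ns = _freqs(freqs, P1, P2, P3, P4)
    mask = np.ones(len(p1), dtype=bool)
    for n in ns:
        mask &= n >= 1
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    abba = np.where(mask, np.nan_to_num(abba), 0.0)
    baba = np.where(mask, np.nan_to_num(baba), 0.0)
    return abba, baba, mask


# ---------------------------------------------------------------------------
# Public statistics


def f2(freqs: GroupFrequencies, A: str, B: str, blocks) -> FStatResult:
    num, mask = f2_sites(freqs, A, B)
    w = mask.astype(float)
    return _persite_jackknife("f2", (A, B), num, w, w, blocks)


def f3(freqs: GroupFrequencies, C: str, A: str, B: str, blocks,
       corrected: bool = True) -> FStatResult:
    """f3(C; A, B). With C an outgroup this is the shared-drift (outgroup-f3)
    statistic; with C the test population a significantly negative value
    (Z < −3 by the usual convention) indicates admixture."""
    num, mask = f3_sites(freqs, C, A, B, corrected=corrected)
    w = mask.astype(float)
    name = "f3_corrected" if corrected else "f3"
    return _persite_jackknife(name, (C, A, B), num, w, w, blocks)


def f4(freqs: GroupFrequencies, A: str, B: str, C: str, D: str,
       blocks) -> FStatResult:
    num, mask = f4_sites(freqs, A, B, C, D)
    w = mask.astype(float)
    return _persite_jackknife("f4", (A, B, C, D), num, w, w, blocks)


def d_stat(freqs: GroupFrequencies, P1: str, P2: str, P3: str, P4: str,
           blocks) -> FStatResult:
    abba, baba, mask = dstat_sites(freqs, P1, P2, P3, P4)
    den = abba + baba
    if den.sum() == 0:
        raise ValueError("D-statistic: no informative (ABBA/BABA) sites")
    informative = (den > 0).astype(float)
    return _persite_jackknife("D", (P1, P2, P3, P4), abba - baba, den,
                              informative, blocks)


def qpwave_rank0(freqs: GroupFrequencies, left, right, blocks) -> RankTestResult:
    """Test whether the two *left* groups are consistent with a single shared
    ancestry wave relative to the *right* outgroups.

    Builds v_j = f4(L1, L2; R_base, R_j) for each non-base right group,
    estimates the covariance of v by a delete-one block jackknife, and tests
    v = 0 with a Hotelling-style chi-square (dof = len(v)). Because the
    covariance comes from a finite number g of blocks, the p-value uses the
    exact Hotelling T² small-sample distribution,
    chi2 · (g − m) / (m (g − 1)) ~ F(m, g − m), which converges to the
    chi-square upper tail as g grows. Rejection means the left groups drew
    ancestry from distinct waves. This implements only the rank-0
    hypothesis, not the full rank ladder of likelihood-based
    implementations.
    """
    L1, L2 = left
    base, rest = right[0], list(right[1:])
    if len(rest) < 2:
        raise ValueError("need at least 2 right groups beyond the base")

    nums, dens = [], []
    for rj in rest:
        num, mask = f4_sites(freqs, L1, L2, base, rj)
        nums.append(num)
        dens.append(mask.astype(float))
    nums = np.vstack(nums)          # (m, S)
    dens = np.vstack(dens)

    tot_n = nums.sum(axis=1)
    tot_d = dens.sum(axis=1)
    v = tot_n / tot_d

    bn = np.stack([nums[:, a:b].sum(axis=1) for a, b in blocks], axis=1)
    bd = np.stack([dens[:, a:b].sum(axis=1) for a, b in blocks], axis=1)
    nonempty = bd.sum(axis=0) > 0
    bn, bd = bn[:, nonempty], bd[:, nonempty]
    g = bn.shape[1]
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks")
    loo = (tot_n[:, None] - bn) / (tot_d[:, None] - bd)   # (m, g)
    center = loo.mean(axis=1, keepdims=True)
    dev = loo - center
    cov = (g - 1) / g * dev @ dev.T

    used_pinv = False
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        used_pinv = True
        inv = np.linalg.pinv(cov)
    else:
        inv = np.linalg.inv(cov)
    chi2 = float(v @ inv @ v)
    dof = len(v)
    if g > dof:
        f_stat = chi2 * (g - dof) / (dof * (g - 1))
        p = float(stats.f.sf(f_stat, dof, g - dof))
    else:  # too few blocks for the T² correction; fall back to chi-square
        p = float(stats.chi2.sf(chi2, dof))
    return RankTestResult((L1, L2), base, tuple(rest), v, cov, chi2, dof, p,
                          used_pinv)


def shared_drift_matrix(freqs: GroupFrequencies, targets, references,
                        outgroup: str, blocks):
    """Outgroup-f3 of every target against every reference, as a tidy
    DataFrame with a per-target rank (1 = most shared drift)."""
    import pandas as pd

    rows = []
    for t in targets:
        for r in references:
            res = f3(freqs, outgroup, t, r, blocks, corrected=True)
            rows.append((t, r, res.value, res.se, res.z,
                         res.n_blocks, res.n_sites_used))
    out = pd.DataFrame(rows, columns=["target", "reference", "f3", "se", "z",
                                      "n_blocks", "n_sites"])
    out["rank"] = out.groupby("target")["f3"].rank(ascending=False,
                                                   method="first").astype(int)
    return out
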
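"""Haplotype-homozygosity and differentiation scans for recent selection.

* EHH: the probability that two randomly drawn carrier haplotypes are
  identical over the interval from a focal SNP out to a flanking site.
* iHS: log-ratio of the EHH integrals (over genetic distance) on the
  ancestral vs derived background; unusually long derived haplotypes at
  intermediate frequency signal an ongoing sweep. Sign convention
  ln(iHH_ancestral / iHH_derived): a sweeping derived allele gives negative
  unstandardized scores; downstream reporting uses |iHS|.
* nSL: the same construction with haplotype length measured in number of
  segregating sites, hence robust to recombination- and mutation-rate
  variation and needing no genetic map.
* XP-EHH: log-ratio of all-haplotype EHH integrals between two populations,
  integrated over a shared span, detecting sweeps differentiating them.
* Garud H1/H12/H2/H1: haplotype-frequency-spectrum statistics in SNP windows
  separating hard (one sweeping haplotype: high H12, low H2/H1) from soft
  sweeps (several: lower H12, high H2/H1).
* Tajima's D in bp windows, and Hudson FST with individual-label permutation
  significance.

Scores are standardized within derived-frequency bins and converted to
two-sided empirical p-values genome-wide (rank-based, +1 smoothing).

Missing data: a haplotype with a missing call breaks homozygosity from that
site outward (EHH walks treat it as a permanent singleton); haplotype-window
statistics drop haplotypes containing missing calls; Tajima windows use
complete-case sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypeMatrix

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05
MAX_GAP_BP = 200_000
MIN_MAF = 0.05
MAX_EXTEND_BP = 1_000_000     # iHS/XP-EHH integration cap (physical)
MAX_EXTEND_SNPS = 100         # nSL integration cap (segregating sites)


# ---------------------------------------------------------------------------
# EHH core


def ehh_decay(matrix: HaplotypeMatrix, focal: int, carriers: np.ndarray,
              cutoff: float = EHH_CUTOFF, max_gap_bp: int = MAX_GAP_BP):
    """EHH decay curve for a carrier class around a focal site.

    Returns a DataFrame (site, pos_bp, pos_cM, direction, ehh) including the
    focal site (ehh = 1), walking outward in both directions until
    ehh <= cutoff, a chromosome end, or an inter-SNP gap above ``max_gap_bp``
    (the latter two set the ``truncated`` attribute).
    """
    if len(carriers) < 2:
        raise ValueError("EHH undefined for fewer than 2 carriers")
    rows = [(focal, int(matrix.pos_bp[focal]), float(matrix.pos_cM[focal]),
             0, 1.0)]
    truncated = False
    for direction in (-1, 1):
        sites, ehhs, trunc = _walk(matrix, focal, carriers, direction,
                                   cutoff, max_gap_bp)
        truncated |= trunc
        for s, e in zip(sites, ehhs):
            rows.append((int(s), int(matrix.pos_bp[s]),
                         float(matrix.pos_cM[s]), direction, float(e)))
    out = pd.DataFrame(rows, columns=["site", "pos_bp", "pos_cM",
                                      "direction", "ehh"])
    out.attrs["truncated"] = truncated
    return out.sort_values("site").reset_index(drop=True)


def _walk(matrix: HaplotypeMatrix, focal: int, carriers: np.ndarray,
          direction: int, cutoff: float, max_gap_bp: int | None,
          max_steps: int | None = None, max_extend_bp: int | None = None,
          span: tuple | None = None):
    """Walk outward from focal; returns (sites, ehh values, truncated).

    Haplotypes are grouped by their allele string over the walked interval;
    EHH(x) = identical-pair fraction among the carriers (fixed denominator:
    all carrier pairs). A missing call removes a haplotype from all further
    pairs; haplotypes that become singletons stop being tracked (they can
    never pair again). ``truncated`` is True when the walk hits the
    chromosome end or a gap above ``max_gap_bp`` while EHH is still above
    the cutoff; stopping at ``max_steps`` sites or ``max_extend_bp`` from
    the focal position is a configured integration cap, not a truncation.
    """
    al = matrix.alleles
    pos_bp = matrix.pos_bp
    if span is None:
        on = np.flatnonzero(matrix.chrom == matrix.chrom[focal])
        lo, hi = int(on[0]), int(on[-1])
    else:
        lo, hi = span
    n = len(carriers)
    npairs = n * (n - 1) / 2.0
    active = np.arange(n)
    gid = np.zeros(n, dtype=np.int64)
    sites, ehhs = [], []
    s = focal
    ehh = 1.0
    while True:
        nxt = s + direction
        if nxt < lo or nxt > hi:
            return sites, ehhs, ehh > cutoff
        if max_gap_bp is not None and \
                abs(int(pos_bp[nxt]) - int(pos_bp[s])) > max_gap_bp:
            return sites, ehhs, ehh > cutoff
        if max_extend_bp is not None and \
                abs(int(pos_bp[nxt]) - int(pos_bp[focal])) > max_extend_bp:
            return sites, ehhs, False
        s = nxt
        if len(active):
            a = al[s, carriers[active]]
            keep = a >= 0
            if not keep.all():
                active, gid, a = active[keep], gid[keep], a[keep]
            key = gid * 2 + a
            _, inv, counts = np.unique(key, return_inverse=True,
                                       return_counts=True)
            paired = counts[inv] >= 2
            active = active[paired]
            gid = inv[paired]
            c2 = counts[counts >= 2]
            ehh = float((c2 * (c2 - 1)).sum() / 2.0 / npairs)
        else:
            ehh = 0.0
        sites.append(s)
        ehhs.append(ehh)
        if ehh <= cutoff or ehh == 0.0:
            return sites, ehhs, False
        if max_steps is not None and len(sites) >= max_steps:
            return sites, ehhs, False


def _ihh(matrix: HaplotypeMatrix, focal: int, carriers: np.ndarray,
         pos: np.ndarray, cutoff: float, max_gap_bp: int | None,
         max_steps: int | None = None, max_extend_bp: int | None = None,
         span: tuple | None = None):
    """Integrated EHH (trapezoid over ``pos`` units, both directions);
    returns (ihh, truncated)."""
    total = 0.0
    truncated = False
    for direction in (-1, 1):
        sites, ehhs, trunc = _walk(matrix, focal, carriers, direction,
                                   cutoff, max_gap_bp, max_steps,
                                   max_extend_bp, span)
        truncated |= trunc
        prev_pos, prev_ehh = pos[focal], 1.0
        for s, e in zip(sites, ehhs):
            total += 0.5 * (prev_ehh + e) * abs(pos[s] - prev_pos)
            prev_pos, prev_ehh = pos[s], e
    return total, truncated


# ---------------------------------------------------------------------------
# iHS / nSL / XP-EHH


@dataclass
class ScanResult:
    """Per-SNP scan table plus standardization metadata."""
    table: pd.DataFrame
    statistic: str

    def ok(self) -> pd.DataFrame:
        return self.table[self.table["flag"] == "ok"]


def _class_scan(matrix: HaplotypeMatrix, pos_units: np.ndarray,
                statistic: str, min_maf: float, cutoff: float,
                max_gap_bp: int | None,
                columns: np.ndarray | None = None,
                max_steps: int | None = None,
                max_extend_bp: int | None = None) -> ScanResult:
    """Shared iHS/nSL driver: per SNP, integrate EHH separately over the
    ancestral- and derived-carrier classes and take ln(iHH_A / iHH_D)."""
    cols = np.arange(matrix.n_haplotypes) if columns is None else np.asarray(columns)
    sub = matrix.alleles[:, cols]
    nonmiss = (sub >= 0).sum(axis=1)
    der = (sub == 1).sum(axis=1)
    spans = {}
    for c in matrix.chromosomes():
        on = np.flatnonzero(matrix.chrom == c)
        spans[c] = (int(on[0]), int(on[-1]))
    rows = []
    for s in range(matrix.n_sites):
        if nonmiss[s] == 0:
            continue
        span = spans[matrix.chrom[s]]
        freq = der[s] / nonmiss[s]
        flag = "ok"
        score = np.nan
        ihh_a = ihh_d = np.nan
        if freq < min_maf or freq > 1 - min_maf:
            flag = "low_freq"
        else:
            dcar = cols[sub[s] == 1]
            acar = cols[sub[s] == 0]
            if len(dcar) < 2 or len(acar) < 2:
                flag = "few_carriers"
            else:
                ihh_a, ta = _ihh(matrix, s, acar, pos_units, cutoff,
                                 max_gap_bp, max_steps, max_extend_bp, span)
                ihh_d, td = _ihh(matrix, s, dcar, pos_units, cutoff,
                                 max_gap_bp, max_steps, max_extend_bp, span)
                if ta or td:
                    flag = "truncated"
                elif ihh_a <= 0 or ihh_d <= 0:
                    flag = "zero_ihh"
                else:
                    score = np.log(ihh_a / ihh_d)
        rows.append((matrix.chrom[s], int(matrix.pos_bp[s]), s, freq,
                     ihh_a, ihh_d, score, flag))
    table = pd.DataFrame(rows, columns=["chrom", "pos_bp", "site",
                                        "freq_derived", "ihh_a", "ihh_d",
                                        "score", "flag"])
    n_excl = int((table["flag"] != "ok").sum())
    if n_excl:
        logger.info("%s: excluded %d / %d SNPs (%s)", statistic, n_excl,
                    len(table),
                    dict(table.loc[table.flag != "ok", "flag"].value_counts()))
    return ScanResult(table, statistic)


def ihs(matrix: HaplotypeMatrix, min_maf: float = MIN_MAF,
        cutoff: float = EHH_CUTOFF, max_gap_bp: int = MAX_GAP_BP,
        columns: np.ndarray | None = None,
        max_extend_bp: int = MAX_EXTEND_BP) -> ScanResult:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived), EHH integrated
    over centiMorgans (requires genetic positions); integration is capped at
    ``max_extend_bp`` either side of the focal SNP (relevant in selfers,
    where haplotype homozygosity can plateau)."""
    return _class_scan(matrix, matrix.pos_cM, "ihs", min_maf, cutoff,
                       max_gap_bp, columns, max_extend_bp=max_extend_bp)


def nsl(matrix: HaplotypeMatrix, min_maf: float = MIN_MAF,
        cutoff: float = EHH_CUTOFF,
        columns: np.ndarray | None = None,
        max_extend_snps: int = MAX_EXTEND_SNPS) -> ScanResult:
    """nSL: like iHS but haplotype length is counted in segregating sites
    (unit distance between consecutive SNPs); no genetic map needed and no
    physical gap rule; integration capped at ``max_extend_snps`` per side."""
    pos_units = np.empty(matrix.n_sites)
    for c in matrix.chromosomes():
        m = matrix.chrom == c
        pos_units[m] = np.arange(int(m.sum()), dtype=float)
    return _class_scan(matrix, pos_units, "nsl", min_maf, cutoff, None,
                       columns, max_steps=max_extend_snps)


def xpehh(matrix: HaplotypeMatrix, cols_a: np.ndarray, cols_b: np.ndarray,
          cutoff: float = EHH_CUTOFF, max_gap_bp: int = MAX_GAP_BP,
          min_haplotypes: int = 10,
          max_extend_bp: int = MAX_EXTEND_BP) -> ScanResult:
    """Cross-population EHH: per SNP, ln(iHH_A / iHH_B) over all haplotypes
    of each population (allele-agnostic), both integrated over the same span
    — out to where the pooled EHH drops below the cutoff (or the extension
    cap)."""
    cols_a = np.asarray(cols_a)
    cols_b = np.asarray(cols_b)
    if len(cols_a) < min_haplotypes or len(cols_b) < min_haplotypes:
        raise ValueError(f"both populations need >= {min_haplotypes} haplotypes")
    pos = matrix.pos_cM
    pooled = np.concatenate([cols_a, cols_b])
    spans = {}
    for c in matrix.chromosomes():
        on = np.flatnonzero(matrix.chrom == c)
        spans[c] = (int(on[0]), int(on[-1]))
    rows = []
    for s in range(matrix.n_sites):
        chrom_span = spans[matrix.chrom[s]]
        total_a = total_b = 0.0
        truncated = False
        for direction in (-1, 1):
            psites, pehh, trunc = _walk(matrix, s, pooled, direction,
                                        cutoff, max_gap_bp,
                                        max_extend_bp=max_extend_bp,
                                        span=chrom_span)
            truncated |= trunc
            span = len(psites)
            asites, aehh, _ = _walk(matrix, s, cols_a, direction, -1.0,
                                    max_gap_bp, max_steps=span,
                                    span=chrom_span)
            bsites, behh, _ = _walk(matrix, s, cols_b, direction, -1.0,
                                    max_gap_bp, max_steps=span,
                                    span=chrom_span)
            for curve_sites, curve, acc in ((asites, aehh, "a"),
                                            (bsites, behh, "b")):
                prev_pos, prev_ehh = pos[s], 1.0
                t = 0.0
                for x, e in zip(curve_sites[:span], curve[:span]):
                    t += 0.5 * (prev_ehh + e) * abs(pos[x] - prev_pos)
                    prev_pos, prev_ehh = pos[x], e
                if acc == "a":
                    total_a += t
                else:
                    total_b += t
        flag = "ok"
        score = np.nan
        if truncated:
            flag = "truncated"
        elif total_a <= 0 or total_b <= 0:
            flag = "zero_ihh"
        else:
            score = np.log(total_a / total_b)
        sub = matrix.alleles[s]
        nm = (sub[pooled] >= 0).sum()
        freq = (sub[pooled] == 1).sum() / nm if nm else np.nan
        rows.append((matrix.chrom[s], int(matrix.pos_bp[s]), s, freq,
                     total_a, total_b, score, flag))
    table = pd.DataFrame(rows, columns=["chrom", "pos_bp", "site",
                                        "freq_derived", "ihh_a", "ihh_d",
                                        "score", "flag"])
    return ScanResult(table, "xpehh")


def standardize(result: ScanResult, n_bins: int = 50) -> ScanResult:
    """Standardize scores within derived-frequency bins and attach two-sided
    empirical p-values.

    Within each bin the mean is subtracted and the sd divided out; bins with
    fewer than 2 scores are merged into their neighbor (logged). Empirical
    p of SNP i is rank-based over all standardized scores:
    p_i = #{j : |z_j| >= |z_i|} / (N + 1).
    """
    t = result.table.copy()
    ok = (t["flag"] == "ok") & np.isfinite(t["score"])
    scores = t.loc[ok, "score"].to_numpy()
    freqs = t.loc[ok, "freq_derived"].to_numpy()
    z = np.full(len(t), np.nan)
    if len(scores) == 0:
        t["z"] = z
        t["p_empirical"] = np.nan
        return ScanResult(t, result.statistic)

    edges = np.linspace(freqs.min(), freqs.max() + 1e-12, n_bins + 1)
    bin_id = np.clip(np.digitize(freqs, edges) - 1, 0, n_bins - 1)
    # merge sparse bins into the previous non-empty one
    remap = np.arange(n_bins)
    counts = np.bincount(bin_id, minlength=n_bins)
    n_merged = 0
    for b in range(n_bins):
        if 0 < counts[b] < 2:
            tgt = b - 1
            while tgt >= 0 and counts[tgt] == 0:
                tgt -= 1
            if tgt < 0:
                tgt = b + 1
                while tgt < n_bins and counts[tgt] == 0:
                    tgt += 1
            if 0 <= tgt < n_bins:
                counts[tgt] += counts[b]
                counts[b] = 0
                remap[b] = tgt
                n_merged += 1
    if n_merged:
        logger.info("standardize: merged %d sparse bins", n_merged)
    bin_id = remap[bin_id]

    zz = np.full(len(scores), np.nan)
    flags = t["flag"].to_numpy(dtype=object)
    ok_idx = np.flatnonzero(ok.to_numpy())
    for b in np.unique(bin_id):
        m = bin_id == b
        sd = scores[m].std(ddof=0)
        if sd == 0:
            flags[ok_idx[m]] = "degenerate_bin"
            continue
        zz[m] = (scores[m] - scores[m].mean()) / sd
    z[ok_idx] = zz
    t["flag"] = flags
    t["z"] = z

    finite = np.isfinite(z)
    absz = np.abs(z[finite])
    order = np.argsort(absz)
    n = len(absz)
    # rank from the top: #{j: |z_j| >= |z_i|}
    ge = n - np.searchsorted(absz[order], absz, side="left")
    p = np.full(len(t), np.nan)
    p[finite] = ge / (n + 1.0)
    t["p_empirical"] = p
    return ScanResult(t, result.statistic)


# ---------------------------------------------------------------------------
# Windowed haplotype statistics


def garud_h(matrix: HaplotypeMatrix, window_snps: int = 500,
            step_snps: int = 10,
            columns: np.ndarray | None = None) -> pd.DataFrame:
    """Garud haplotype-frequency statistics in sliding SNP windows:
    H1 = Σ p_i², H12 = H1 + 2·p1·p2, H2 = H1 − p1²; reported with H2/H1.
    Haplotypes containing a missing call in the window are dropped there."""
    cols = np.arange(matrix.n_haplotypes) if columns is None else np.asarray(columns)
    rows = []
    for c in matrix.chromosomes():
        on = np.flatnonzero(matrix.chrom == c)
        for start in range(0, max(len(on) - window_snps + 1, 1), step_snps):
            w = on[start:start + window_snps]
            if len(w) < 2:
                continue
            sub = matrix.alleles[np.ix_(w, cols)]
            keep = (sub >= 0).all(axis=0)
            flag = "ok"
            h1 = h12 = h2 = ratio = np.nan
            if keep.sum() < 2:
                flag = "all_missing"
            else:
                haps = sub[:, keep]
                _, counts = np.unique(haps, axis=1, return_counts=True)
                p = np.sort(counts / counts.sum())[::-1]
                h1 = float((p ** 2).sum())
                p1 = p[0]
                p2 = p[1] if len(p) > 1 else 0.0
                h12 = h1 + 2 * p1 * p2
                h2 = h1 - p1 ** 2
                ratio = h2 / h1
            rows.append((c, int(matrix.pos_bp[w[0]]), int(matrix.pos_bp[w[-1]]),
                         len(w), h1, h12, h2, ratio, flag))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_snps", "h1", "h12", "h2",
                                       "h2_h1", "flag"])


def _tajima_constants(n: int):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajima_d(matrix: HaplotypeMatrix, window_bp: int = 50_000,
             step_bp: int = 5_000,
             columns: np.ndarray | None = None) -> pd.DataFrame:
    """Tajima's D in sliding physical windows (complete-case sites within
    the chosen haplotype set); windows without segregating sites or with
    fewer than 3 haplotypes are flagged undefined."""
    cols = np.arange(matrix.n_haplotypes) if columns is None else np.asarray(columns)
    n = len(cols)
    rows = []
    for c in matrix.chromosomes():
        on = np.flatnonzero(matrix.chrom == c)
        pos = matrix.pos_bp[on]
        last = int(pos.max())
        for start in range(1, last + 1, step_bp):
            end = start + window_bp - 1
            w = on[(pos >= start) & (pos <= end)]
            flag = "ok"
            d = np.nan
            S = 0
            if n < 3:
                flag = "few_haplotypes"
            elif len(w):
                sub = matrix.alleles[np.ix_(w, cols)]
                complete = (sub >= 0).all(axis=1)
                sub = sub[complete]
                der = (sub == 1).sum(axis=1)
                seg = (der > 0) & (der < n)
                S = int(seg.sum())
                if S == 0:
                    flag = "no_segregating"
                else:
                    dd = der[seg]
                    pi = float((2.0 * dd * (n - dd) / (n * (n - 1))).sum())
                    a1, e1, e2 = _tajima_constants(n)
                    d = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
            else:
                flag = "no_segregating"
            rows.append((c, start, min(end, last), S, d, flag))
            if end >= last:
                break
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_segregating", "tajima_d", "flag"])


# ---------------------------------------------------------------------------
# Hudson FST with permutation significance


def hudson_fst_sites(p_a, p_b, n_a, n_b):
    """Per-site Hudson numerator/denominator (ratio-of-averages form)."""
    mask = (n_a >= 2) & (n_b >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p_a - p_b) ** 2
               - p_a * (1 - p_a) / (n_a - 1)
               - p_b * (1 - p_b) / (n_b - 1))
        den = p_a * (1 - p_b) + p_b * (1 - p_a)
    return np.where(mask, num, 0.0), np.where(mask, den, 0.0), mask


def _group_freqs_for_cols(matrix: HaplotypeMatrix, cols: np.ndarray):
    sub = matrix.alleles[:, cols]
    n = (sub >= 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, (sub == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
    return p, n


def hudson_fst_windows(matrix: HaplotypeMatrix, inds_a, inds_b,
                       window_bp: int = 50_000) -> pd.DataFrame:
    """Windowed Hudson FST between two individual sets (ratio of sums; the
    estimator may be slightly negative and is never clamped here)."""
    cols_a = matrix.haplotypes_of(inds_a)
    cols_b = matrix.haplotypes_of(inds_b)
    p_a, n_a = _group_freqs_for_cols(matrix, cols_a)
    p_b, n_b = _group_freqs_for_cols(matrix, cols_b)
    num, den, mask = hudson_fst_sites(p_a, p_b, n_a, n_b)
    rows = []
    for c in matrix.chromosomes():
        on = np.flatnonzero(matrix.chrom == c)
        pos = matrix.pos_bp[on]
        last = int(pos.max())
        for start in range(1, last + 1, window_bp):
            end = start + window_bp - 1
            w = on[(pos >= start) & (pos <= end)]
            if len(w) == 0:
                continue
            dsum = den[w].sum()
            fst = num[w].sum() / dsum if dsum > 0 else np.nan
            rows.append((c, start, min(end, last), int(mask[w].sum()), fst))
            if end >= last:
                break
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_sites", "fst"])


def fst_permutation_test(matrix: HaplotypeMatrix, inds_a, inds_b,
                         rng: np.random.Generator, window_bp: int = 50_000,
                         n_perm: int = 1000) -> pd.DataFrame:
    """Permutation significance of windowed Hudson FST.

    Individual labels are permuted between the two sets (keeping sizes),
    preserving the within-individual haplotype pairing; per window
    p = (1 + #{perm FST >= observed}) / (n_perm + 1).
    """
    inds_a, inds_b = list(inds_a), list(inds_b)
    obs = hudson_fst_windows(matrix, inds_a, inds_b, window_bp)
    count_ge = np.zeros(len(obs))
    pool = np.asarray(inds_a + inds_b, dtype=object)
    for _ in range(n_perm):
        perm = rng.permutation(len(pool))
        pa = pool[perm[: len(inds_a)]]
        pb = pool[perm[len(inds_a):]]
        res = hudson_fst_windows(matrix, pa, pb, window_bp)
        count_ge += (res["fst"].to_numpy() >=
                     obs["fst"].to_numpy() - 1e-15).astype(float)
    out = obs.copy()
    out["p_perm"] = (1.0 + count_ge) / (n_perm + 1.0)
    return out
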
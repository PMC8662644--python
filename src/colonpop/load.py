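"""Mutational-load analysis: fixed-to-total derived-allele ratios.

For each group and mutation category (synonymous, nonsynonymous tolerated,
nonsynonymous deleterious, genome-wide), ϕ = n_fixed / n_total where a site
is *fixed* when its within-group derived frequency is exactly 1 (among
non-missing calls, with a minimum call count guarding single-sample
artifacts) and *total* counts every site where the group carries the derived
allele. Because admixture between diverged founders raises the effective
population size and lowers ϕ in every category, the deleterious and
tolerated ratios are scaled by a neutral baseline — the synonymous ratio
(Φ_cat = ϕ_cat / ϕ_syn) or, alternatively, the genome-wide ratio — so that a
specifically reduced Φ_deleterious isolates the purging of harmful variants.

Also provides tract-based ancestry proportion summaries (length-weighted)
and Welch's unequal-variance t-test for category comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AncestryTracts, GroupFrequencies, SiteAnnotation

LOAD_CATEGORIES = ("nonsyn_deleterious", "nonsyn_tolerated", "syn",
                   "genome_wide")


@dataclass
class PhiResult:
    group: str
    category: str
    n_fixed: int
    n_total: int

    @property
    def phi(self) -> float:
        return self.n_fixed / self.n_total if self.n_total > 0 else np.nan

    @property
    def defined(self) -> bool:
        return self.n_total > 0


def phi(freqs: GroupFrequencies, group: str, category: str,
        annotation: SiteAnnotation, min_n: int = 4) -> PhiResult:
    """Fixed-to-total derived-allele ratio for one group × category.

    Complete-case within the group: n_fixed counts sites with derived
    frequency exactly 1 and at least ``min_n`` non-missing calls; n_total
    counts sites with any derived allele observed.
    """
    sites = annotation.sites(category)
    p = freqs.freq(group)[sites]
    n = freqs.count(group)[sites]
    with np.errstate(invalid="ignore"):
        derived = (n > 0) & (p > 0)
        fixed = derived & (p == 1.0) & (n >= min_n)
    return PhiResult(group, category, int(fixed.sum()), int(derived.sum()))


def load_profile(freqs: GroupFrequencies, groups, annotation: SiteAnnotation,
                 min_n: int = 4) -> pd.DataFrame:
    """ϕ and both scaled Φ variants for every group × category."""
    rows = []
    for g in groups:
        res = {c: phi(freqs, g, c, annotation, min_n) for c in LOAD_CATEGORIES}
        phi_syn = res["syn"].phi
        phi_gw = res["genome_wide"].phi
        for c in LOAD_CATEGORIES:
            r = res[c]
            rows.append((g, c, r.n_fixed, r.n_total, r.phi,
                         scaled_phi(r.phi, phi_syn),
                         scaled_phi(r.phi, phi_gw)))
    return pd.DataFrame(rows, columns=["group", "category", "n_fixed",
                                       "n_total", "phi", "phi_scaled_syn",
                                       "phi_scaled_genome"])


def scaled_phi(phi_category: float, phi_scaler: float) -> float:
    """Φ = ϕ_category / ϕ_scaler (scaler is the synonymous or genome-wide
    ratio); NaN when the scaler is undefined or zero."""
    if not np.isfinite(phi_scaler) or phi_scaler <= 0:
        return np.nan
    if not np.isfinite(phi_category):
        return np.nan
    return phi_category / phi_scaler


# ---------------------------------------------------------------------------
# Ancestry proportions from tracts


def ancestry_proportions(tracts: AncestryTracts,
                         per: str = "individual") -> pd.DataFrame:
    """Length-weighted (bp) ancestry proportion per source.

    ``per`` = "haplotype" or "individual" (haplotype names are expected as
    '<individual>_h<k>'; anything without that suffix is its own individual).
    Proportions sum to 1 per unit.
    """
    t = tracts.table.copy()
    t["length"] = t["end"] - t["start"] + 1
    if per == "individual":
        t["unit"] = [h.rsplit("_h", 1)[0] for h in t["haplotype"]]
    elif per == "haplotype":
        t["unit"] = t["haplotype"]
    else:
        raise ValueError("per must be 'individual' or 'haplotype'")
    g = t.groupby(["unit", "source"])["length"].sum().unstack(fill_value=0)
    prop = g.div(g.sum(axis=1), axis=0)
    prop.index.name = per
    return prop


def region_ancestry(tracts: AncestryTracts, chrom: str, start: int, end: int,
                    per: str = "individual") -> pd.DataFrame:
    """Ancestry proportions restricted to the overlap with a 1-based
    inclusive region."""
    t = tracts.table
    t = t[t["chrom"] == chrom].copy()
    t["start"] = t["start"].clip(lower=start)
    t["end"] = t["end"].clip(upper=end)
    t = t[t["end"] >= t["start"]]
    if t.empty:
        raise ValueError(f"no tracts overlap {chrom}:{start}-{end}")
    return ancestry_proportions(AncestryTracts(t.reset_index(drop=True)), per)


def mean_nonfocal_ancestry(tracts: AncestryTracts, focal_source: str) -> pd.Series:
    """Per-individual proportion of ancestry NOT from the focal source."""
    prop = ancestry_proportions(tracts, per="individual")
    focal = prop[focal_source] if focal_source in prop.columns else 0.0
    return 1.0 - focal


# ---------------------------------------------------------------------------
# Welch's t


def welch_t(values_a, values_b):
    """Welch's unequal-variance two-sided t-test; returns (t, df, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
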
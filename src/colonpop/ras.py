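"""Rare-allele-sharing (RAS) attribution of colonist ancestry.

Rare derived alleles ascertained in a reference panel are, with high
probability, recent and geographically localized; when a colonist carries
one, the panel subcluster(s) carrying it point at the colonist's source.
Sites are ascertained by panel derived-allele count (default 2–20) and panel
missingness (< 10%); every ascertained allele a target carries adds weight to
the donor subclusters with at least one panel carrier.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .core import GroupAssignment, HaplotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class RasProfile:
    """Shared rare-allele counts per target × donor subcluster.

    ``counts`` are weighted (a multi-donor allele splits its unit weight
    equally among carrier subclusters), ``raw_counts`` give each carrier
    subcluster the full unit. ``share`` normalizes the weighted counts by
    the total number of ascertained rare alleles the target carries;
    ``share_per_donor_hap`` additionally divides by the donor panel
    haplotype count (both normalizations are reported because field
    pipelines differ on this point).
    """
    targets: list
    donors: list
    counts: np.ndarray               # (n_targets, n_donors) weighted
    raw_counts: np.ndarray           # (n_targets, n_donors) unweighted
    n_target_alleles: np.ndarray     # (n_targets,)
    ac_min: int
    ac_max: int
    max_missing: float

    @property
    def share(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_target_alleles[:, None] > 0,
                            self.counts / np.maximum(
                                self.n_target_alleles[:, None], 1), 0.0)

    def share_per_donor_hap(self, donor_sizes: np.ndarray) -> np.ndarray:
        return self.share / np.asarray(donor_sizes, dtype=float)[None, :]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        share = self.share
        for i, t in enumerate(self.targets):
            for j, d in enumerate(self.donors):
                rows.append((t, d, self.counts[i, j], self.raw_counts[i, j],
                             share[i, j]))
        return pd.DataFrame(rows, columns=["target", "donor", "weighted",
                                           "raw", "share"])

    def top_donor(self, target) -> str:
        i = self.targets.index(target)
        return self.donors[int(np.argmax(self.counts[i]))]


def ascertain_rare_sites(panel: HaplotypeMatrix, ac_min: int = 2,
                         ac_max: int = 20,
                         max_missing: float = 0.10) -> np.ndarray:
    """Site indices whose derived-allele count in the panel lies in
    [ac_min, ac_max] with panel missingness below ``max_missing``.

    The count is computed in the reference panel only; target carriers never
    enter the ascertainment.
    """
    al = panel.alleles
    ac = (al == 1).sum(axis=1)
    miss = (al < 0).mean(axis=1)
    keep = (ac >= ac_min) & (ac <= ac_max) & (miss < max_missing)
    sites = np.flatnonzero(keep)
    if len(sites) == 0:
        logger.warning("ascertain_rare_sites: no sites pass (ac %d-%d, "
                       "missingness < %.2f)", ac_min, ac_max, max_missing)
    return sites


def ras_counts(matrix: HaplotypeMatrix, target_individuals,
               panel_assignment: GroupAssignment, donor_level: str,
               ascertained: np.ndarray, ac_min: int = 2, ac_max: int = 20,
               max_missing: float = 0.10,
               per_target_individual: bool = False) -> RasProfile:
    """Count ascertained rare alleles shared between targets and each donor
    subcluster.

    ``matrix`` holds both panel and target haplotypes; the panel membership
    comes from ``panel_assignment`` (donor subclusters at ``donor_level``).
    Targets must be disjoint from the panel. For each ascertained site where
    a target carries ≥1 derived haplotype, each donor subcluster with ≥1
    panel carrier receives weight 1/(number of carrier subclusters)
    (weighted) and weight 1 (raw).
    """
    donors = panel_assignment.groups(donor_level)
    panel_inds: set = set()
    donor_cols = []
    for d in donors:
        members = panel_assignment.members(d, donor_level)
        panel_inds.update(members)
        donor_cols.append(matrix.haplotypes_of(members))

    overlap = set(target_individuals) & panel_inds
    if overlap:
        raise ValueError(f"targets overlap the reference panel: {sorted(overlap)[:5]}")

    sub = matrix.alleles[ascertained]                    # (S', H)
    carrier = np.stack([(sub[:, cols] == 1).any(axis=1)
                        for cols in donor_cols], axis=1)  # (S', n_donors)
    n_carrier = carrier.sum(axis=1)                      # carriers per site
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(n_carrier > 0, 1.0 / np.maximum(n_carrier, 1), 0.0)

    if per_target_individual:
        target_sets = [[t] for t in target_individuals]
        names = list(target_individuals)
    else:
        target_sets = [list(target_individuals)]
        names = ["target"]

    counts = np.zeros((len(target_sets), len(donors)))
    raw = np.zeros_like(counts)
    totals = np.zeros(len(target_sets))
    for i, tset in enumerate(target_sets):
        cols = matrix.haplotypes_of(tset)
        has = (sub[:, cols] == 1).any(axis=1)            # (S',)
        totals[i] = has.sum()
        counts[i] = (carrier * (has * w)[:, None]).sum(axis=0)
        raw[i] = (carrier * has[:, None]).sum(axis=0)
    return RasProfile(names, donors, counts, raw, totals,
                      ac_min, ac_max, max_missing)
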
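"""Core domain types and I/O shared by every analysis stage.

The central container is :class:`HaplotypeMatrix`: a site × haplotype matrix of
polarized binary alleles (0 ancestral, 1 derived, ``MISSING`` for no-calls)
with physical and genetic coordinates. Groups of individuals (the field's
*groups*, *subclusters*, *clusters* and *regions*, as produced by external
haplotype-sharing clustering) are consumed from a plain TSV table — they are
never inferred here.

Coordinate conventions: VCF and tract files are 1-based inclusive; internal
site indices are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

LEVELS = ("group", "subcluster", "cluster", "region")

CATEGORIES = ("syn", "nonsyn_tolerated", "nonsyn_deleterious", "other")


class FormatError(ValueError):
    """Malformed input file (missing GT field, unsorted positions, ...)."""


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes at polarized biallelic sites.

    Parameters
    ----------
    alleles
        int8 array of shape (n_sites, n_haplotypes); entries 0 (ancestral),
        1 (derived) or -1 (missing).
    chrom
        per-site chromosome id (object array of str).
    pos_bp
        per-site physical position, 1-based, strictly increasing within a
        chromosome.
    pos_cM
        per-site genetic position in centiMorgans, non-decreasing within a
        chromosome.
    sample_ids
        per-haplotype individual label (a diploid contributes two haplotypes
        with the same label unless collapsed).
    """

    alleles: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cM: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cM = np.asarray(self.pos_cM, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (sites × haplotypes)")
        s, h = self.alleles.shape
        for name, arr, n in (
            ("chrom", self.chrom, s),
            ("pos_bp", self.pos_bp, s),
            ("pos_cM", self.pos_cM, s),
            ("sample_ids", self.sample_ids, h),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n}")
        bad = ~np.isin(self.alleles, (-1, 0, 1))
        if bad.any():
            raise ValueError("alleles must be in {0, 1, -1}")
        for c in self.chromosomes():
            m = self.chrom == c
            if not np.all(np.diff(self.pos_bp[m]) > 0):
                raise FormatError(f"positions not strictly increasing on {c}")
            if not np.all(np.diff(self.pos_cM[m]) >= -1e-12):
                raise FormatError(f"genetic positions decrease on {c}")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def individuals(self) -> list:
        seen: dict = {}
        for s in self.sample_ids:
            seen.setdefault(s, None)
        return list(seen)

    def haplotypes_of(self, individuals: Iterable[str]) -> np.ndarray:
        """Column indices of all haplotypes belonging to *individuals*."""
        wanted = set(individuals)
        return np.flatnonzero([s in wanted for s in self.sample_ids])

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles[idx], self.chrom[idx], self.pos_bp[idx],
            self.pos_cM[idx], self.sample_ids,
        )

    def take_haplotypes(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles[:, idx], self.chrom, self.pos_bp,
            self.pos_cM, self.sample_ids[idx],
        )


@dataclass
class GroupAssignment:
    """Individual → label mapping at each hierarchy level.

    Backed by a DataFrame with an ``individual`` column plus one column per
    level present (``group``, ``subcluster``, ``cluster``, ``region``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "individual" not in self.table.columns:
            raise FormatError("group table needs an 'individual' column")
        if self.table["individual"].duplicated().any():
            raise FormatError("duplicate individuals in group table")
        self.table = self.table.set_index("individual", drop=False)

    def levels(self) -> list:
        return [l for l in LEVELS if l in self.table.columns]

    def groups(self, level: str = "group") -> list:
        if level not in self.table.columns:
            raise KeyError(f"level {level!r} not in assignment")
        return list(dict.fromkeys(self.table[level].dropna()))

    def members(self, label: str, level: str = "group") -> list:
        m = self.table[self.table[level] == label]
        if m.empty:
            raise KeyError(f"empty or unknown {level} {label!r}")
        return list(m["individual"])


@dataclass
class GroupFrequencies:
    """Per-site derived-allele frequency and observed allele count per group.

    ``p`` is NaN where a group has no non-missing calls (``n`` = 0); sites and
    genomic coordinates are carried along so block construction and windowed
    statistics can reuse them.
    """

    groups: list
    p: np.ndarray          # (n_sites, n_groups), NaN where n == 0
    n: np.ndarray          # (n_sites, n_groups) int
    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.groups)}
        with np.errstate(invalid="ignore"):
            ok = self.n > 0
            if np.any((self.p[ok] < -1e-12) | (self.p[ok] > 1 + 1e-12)):
                raise ValueError("frequencies outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.p.shape[0]

    def col(self, group: str) -> int:
        try:
            return self._index[group]
        except KeyError:
            raise KeyError(f"unknown group {group!r}") from None

    def freq(self, group: str) -> np.ndarray:
        return self.p[:, self.col(group)]

    def count(self, group: str) -> np.ndarray:
        return self.n[:, self.col(group)]


@dataclass
class SiteAnnotation:
    """Per-site mutation category (synonymous / tolerated / deleterious)."""

    category: np.ndarray               # object array of CATEGORIES entries
    score: np.ndarray | None = None    # optional raw score in [0, 1]

    def __post_init__(self) -> None:
        self.category = np.asarray(self.category, dtype=object)
        bad = ~np.isin(self.category, CATEGORIES)
        if bad.any():
            raise ValueError(f"unknown categories: {set(self.category[bad])}")
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=float)
            has = np.isfinite(self.score)
            deleterious = self.category == "nonsyn_deleterious"
            tolerated = self.category == "nonsyn_tolerated"
            # score bands: deleterious 0–0.05, tolerated 0.05–1
            if np.any(has & deleterious & (self.score > 0.05)):
                raise ValueError("deleterious site with score > 0.05")
            if np.any(has & tolerated & (self.score < 0.05)):
                raise ValueError("tolerated site with score < 0.05")

    def sites(self, category: str) -> np.ndarray:
        if category == "genome_wide":
            return np.arange(len(self.category))
        return np.flatnonzero(self.category == category)


@dataclass
class AncestryTracts:
    """Local-ancestry tracts per haplotype (1-based inclusive bp intervals)."""

    table: pd.DataFrame  # haplotype, chrom, start, end, source

    REQUIRED = ("haplotype", "chrom", "start", "end", "source")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"tract table missing columns {missing}")
        t = self.table
        if (t["end"] < t["start"]).any():
            raise ValueError("tract with end < start")
        for (hap, chrom), sub in t.groupby(["haplotype", "chrom"], sort=False):
            s = sub.sort_values("start")
            if (s["start"].values[1:] <= s["end"].values[:-1]).any():
                raise ValueError(f"overlapping tracts for {hap} on {chrom}")

    def haplotypes(self) -> list:
        return list(dict.fromkeys(self.table["haplotype"]))

    def sources(self) -> list:
        return sorted(set(self.table["source"]))


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str, haploidize_policy: str = "all") -> HaplotypeMatrix:
    """Read a phased biallelic-SNP VCF into a :class:`HaplotypeMatrix`.

    ``haploidize_policy``:

    * ``"all"`` — every diploid contributes both haplotypes (phased GT split).
    * ``"collapse_homozygous"`` — every diploid contributes a single
      haplotype; heterozygous genotypes become missing (appropriate for a
      highly selfing organism where residual heterozygosity is rare and
      typically reflects either true outcrossing or genotyping error).

    Multiallelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    if haploidize_policy not in ("all", "collapse_homozygous"):
        raise ValueError(f"unknown haploidize_policy {haploidize_policy!r}")

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    rows, chroms, poss = [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gts = v.genotypes  # [[a0, a1, phased], ...]
        if gts is None:
            raise FormatError(f"record without GT at {v.CHROM}:{v.POS}")
        row = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1] if len(g) > 2 else g[0]
            row[2 * i] = a0 if a0 >= 0 else MISSING
            row[2 * i + 1] = a1 if a1 >= 0 else MISSING
        rows.append(row)
        chroms.append(v.CHROM)
        poss.append(v.POS)
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic records", n_multi)
    if not rows:
        raise FormatError(f"no usable biallelic records in {path}")

    alleles = np.vstack(rows)
    chrom = np.asarray(chroms, dtype=object)
    pos = np.asarray(poss, dtype=np.int64)
    for c in dict.fromkeys(chroms):
        m = chrom == c
        if not np.all(np.diff(pos[m]) > 0):
            raise FormatError(f"unsorted or duplicated positions on {c}")

    sample_ids = np.repeat(samples, 2).astype(object)
    if haploidize_policy == "collapse_homozygous":
        h0 = alleles[:, 0::2]
        h1 = alleles[:, 1::2]
        het = (h0 != h1) & (h0 >= 0) & (h1 >= 0)
        collapsed = np.where(h0 == h1, h0, MISSING)
        collapsed[(h0 < 0) | (h1 < 0)] = MISSING
        if het.any():
            logger.info(
                "read_vcf: %d heterozygous genotypes set missing under "
                "collapse_homozygous", int(het.sum()))
        alleles = collapsed
        sample_ids = np.asarray(samples, dtype=object)

    return HaplotypeMatrix(alleles, chrom, pos, np.zeros(len(pos)), sample_ids)


def write_vcf(matrix: HaplotypeMatrix, path: str,
              ref: str = "A", alt: str = "T") -> None:
    """Write a phased VCF v4.2. Haplotype pairs of one individual become one
    phased diploid sample; an individual with a single haplotype is written
    haploid. Positions are 1-based inclusive."""
    inds = matrix.individuals()
    cols = {ind: list(np.flatnonzero(matrix.sample_ids == ind)) for ind in inds}
    for ind, c in cols.items():
        if len(c) > 2:
            raise ValueError(f"individual {ind} has {len(c)} haplotypes")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=colonpop\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description='
                 '"Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        for c in matrix.chromosomes():
            m = matrix.chrom == c
            fh.write(f"##contig=<ID={c},length={int(matrix.pos_bp[m].max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in inds) + "\n")

        def code(a: int) -> str:
            return "." if a < 0 else str(int(a))

        for s in range(matrix.n_sites):
            row = matrix.alleles[s]
            gts = []
            for ind in inds:
                c = cols[ind]
                if len(c) == 1:
                    gts.append(code(row[c[0]]))
                else:
                    gts.append(code(row[c[0]]) + "|" + code(row[c[1]]))
            fh.write(f"{matrix.chrom[s]}\t{matrix.pos_bp[s]}\t.\t{ref}\t{alt}"
                     f"\t.\tPASS\tAA={ref}\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Polarization and frequencies


def polarize(matrix: HaplotypeMatrix,
             ancestral: Sequence[str]) -> HaplotypeMatrix:
    """Orient alleles so 0 = ancestral, using a per-site ancestral call in
    ``{"ref", "alt", "unknown"}``. Sites with ancestral = alt are flipped;
    unknown sites are dropped (count logged)."""
    ancestral = np.asarray(ancestral, dtype=object)
    if len(ancestral) != matrix.n_sites:
        raise ValueError("ancestral call list length mismatch")
    bad = ~np.isin(ancestral, ("ref", "alt", "unknown"))
    if bad.any():
        raise ValueError(f"bad ancestral codes: {set(ancestral[bad])}")
    alleles = matrix.alleles.copy()
    flip = ancestral == "alt"
    sub = alleles[flip]
    sub[sub >= 0] = 1 - sub[sub >= 0]
    alleles[flip] = sub
    keep = ancestral != "unknown"
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("polarize: dropped %d sites with unknown ancestral state",
                    n_drop)
    return HaplotypeMatrix(alleles[keep], matrix.chrom[keep],
                           matrix.pos_bp[keep], matrix.pos_cM[keep],
                           matrix.sample_ids)


def group_frequencies(matrix: HaplotypeMatrix,
                      assignment: GroupAssignment,
                      level: str = "group") -> GroupFrequencies:
    """Derived-allele frequency and non-missing allele count per group per
    site (complete case within group; no imputation)."""
    groups = assignment.groups(level)
    S = matrix.n_sites
    p = np.full((S, len(groups)), np.nan)
    n = np.zeros((S, len(groups)), dtype=np.int64)
    for j, g in enumerate(groups):
        cols = matrix.haplotypes_of(assignment.members(g, level))
        if len(cols) == 0:
            logger.warning("group %r has no haplotypes in the matrix", g)
            continue
        sub = matrix.alleles[:, cols]
        nonmiss = (sub >= 0).sum(axis=1)
        der = (sub == 1).sum(axis=1)
        n[:, j] = nonmiss
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, j] = np.where(nonmiss > 0, der / np.maximum(nonmiss, 1), np.nan)
    return GroupFrequencies(groups, p, n, matrix.chrom, matrix.pos_bp,
                            matrix.pos_cM)


def frequencies_from_arrays(pools: dict, chrom: np.ndarray,
                            pos_bp: np.ndarray,
                            pos_cM: np.ndarray | None = None) -> GroupFrequencies:
    """Build :class:`GroupFrequencies` straight from per-group haplotype
    arrays (site × haplotype, entries {0, 1, missing}) — the fast path for
    simulation replicates that never materialize a full matrix."""
    groups = list(pools)
    S = len(pos_bp)
    p = np.full((S, len(groups)), np.nan)
    n = np.zeros((S, len(groups)), dtype=np.int64)
    for j, g in enumerate(groups):
        arr = np.asarray(pools[g])
        nonmiss = (arr >= 0).sum(axis=1)
        n[:, j] = nonmiss
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, j] = np.where(nonmiss > 0,
                               (arr == 1).sum(axis=1) / np.maximum(nonmiss, 1),
                               np.nan)
    return GroupFrequencies(groups, p, n, np.asarray(chrom, dtype=object),
                            np.asarray(pos_bp), pos_cM)


def make_blocks(chrom: np.ndarray, pos_bp: np.ndarray,
                block_size_bp: int = 5_000_000) -> list[tuple[int, int]]:
    """Contiguous site-index blocks of at most *block_size_bp*, never spanning
    chromosomes; returns 0-based half-open (start, stop) site ranges."""
    if block_size_bp <= 0:
        raise ValueError("block_size_bp must be > 0")
    chrom = np.asarray(chrom, dtype=object)
    pos_bp = np.asarray(pos_bp)
    blocks: list[tuple[int, int]] = []
    start = 0
    for c in dict.fromkeys(chrom):
        m = np.flatnonzero(chrom == c)
        first, last = m[0], m[-1] + 1
        bin_id = (pos_bp[first:last] - pos_bp[first]) // block_size_bp
        edges = np.flatnonzero(np.diff(bin_id)) + 1
        bounds = np.concatenate(([0], edges, [last - first]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            blocks.append((first + int(a), first + int(b)))
        start = last
    return blocks


def make_blocks_count(n_sites: int, n_blocks: int) -> list[tuple[int, int]]:
    """Equal-count contiguous blocks (for simulated independent sites)."""
    edges = np.linspace(0, n_sites, n_blocks + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]


# ---------------------------------------------------------------------------
# Genetic map


def interpolate_cM(map_table: pd.DataFrame, chrom: np.ndarray,
                   pos_bp: np.ndarray) -> np.ndarray:
    """Linear interpolation of genetic position between map anchors;
    extrapolation beyond the anchors continues the terminal map slope."""
    chrom = np.asarray(chrom, dtype=object)
    pos_bp = np.asarray(pos_bp, dtype=float)
    out = np.empty(len(pos_bp))
    for c in dict.fromkeys(chrom):
        anchors = map_table[map_table["chrom"].astype(str) == str(c)]
        if anchors.empty:
            raise KeyError(f"no map anchors for chromosome {c}")
        anchors = anchors.sort_values("pos_bp")
        xp = anchors["pos_bp"].to_numpy(dtype=float)
        fp = anchors["cM"].to_numpy(dtype=float)
        m = chrom == c
        x = pos_bp[m]
        y = np.interp(x, xp, fp)
        if len(xp) >= 2:
            lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            left = x < xp[0]
            right = x > xp[-1]
            y[left] = fp[0] + (x[left] - xp[0]) * lo_slope
            y[right] = fp[-1] + (x[right] - xp[-1]) * hi_slope
        out[m] = y
    return out


# ---------------------------------------------------------------------------
# Table readers / writers (all TSV, 1-based inclusive coordinates)


def read_group_table(path: str) -> GroupAssignment:
    return GroupAssignment(pd.read_csv(path, sep="\t", dtype=str))


def read_site_categories(path: str, chrom: np.ndarray,
                         pos_bp: np.ndarray) -> SiteAnnotation:
    """Read a per-site category TSV (chrom, pos, category[, score]) aligned to
    the matrix sites; sites absent from the table get category 'other'."""
    t = pd.read_csv(path, sep="\t")
    key = {(str(c), int(p)): i for i, (c, p) in
           enumerate(zip(t["chrom"], t["pos"]))}
    cat = np.full(len(pos_bp), "other", dtype=object)
    score = np.full(len(pos_bp), np.nan)
    has_score = "score" in t.columns
    cats = t["category"].to_numpy(dtype=object)
    scores = t["score"].to_numpy(dtype=float) if has_score else None
    for i, (c, p) in enumerate(zip(chrom, pos_bp)):
        j = key.get((str(c), int(p)))
        if j is not None:
            cat[i] = cats[j]
            if has_score:
                score[i] = scores[j]
    return SiteAnnotation(cat, score if has_score else None)


def read_genetic_map(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos_bp", "cM"}
    if not need <= set(t.columns):
        raise FormatError(f"genetic map needs columns {sorted(need)}")
    return t


def read_tracts(path: str) -> AncestryTracts:
    return AncestryTracts(pd.read_csv(path, sep="\t"))


def read_env_table(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    if "deme" not in t.columns:
        raise FormatError("environment table needs a 'deme' column")
    return t
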
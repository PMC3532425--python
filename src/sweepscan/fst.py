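"""Weir-Cockerham F_ST at three levels of a hierarchical panel.

The estimator is the Weir & Cockerham (1984) theta, computed from the
variance components a (among groups), b (among individuals within
groups) and c (within individuals), using per-group sample sizes,
allele frequencies and observed heterozygote frequencies.  Scans run at
four level tags mirroring a regions-within-world design:

* ``global-regions``     — one group per geographic region,
* ``global-populations`` — one group per population,
* ``inter-regional:R``   — region R versus the pooled remainder (two groups),
* ``intra-regional:R``   — populations within region R only.

Significance is empirical: a focal score is ranked inside a background
distribution built from putatively neutral SNPs, within bins of equal
numbers of SNPs grouped by minor allele frequency, which corrects for
the strong dependence of F_ST on heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix, PopulationStructure, ScoreTrack

__all__ = [
    "AlleleCounts",
    "wc_theta",
    "group_counts",
    "fst_scan",
    "maf_binned_empirical_p",
]


@dataclass
class AlleleCounts:
    """Per-group diploid sample sizes, coded-allele counts and het counts."""

    sizes: np.ndarray  # diploids genotyped, per group
    allele_counts: np.ndarray  # copies of the coded allele, per group
    het_counts: np.ndarray  # observed heterozygotes, per group

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.float64)
        self.allele_counts = np.asarray(self.allele_counts, dtype=np.float64)
        self.het_counts = np.asarray(self.het_counts, dtype=np.float64)
        if not (self.sizes.shape == self.allele_counts.shape == self.het_counts.shape):
            raise ValueError("group arrays must have identical shape")
        if np.any(self.allele_counts > 2 * self.sizes) or np.any(self.allele_counts < 0):
            raise ValueError("allele count outside [0, 2*size]")
        if np.any(self.het_counts > self.sizes) or np.any(self.het_counts < 0):
            raise ValueError("het count outside [0, size]")


def _theta_components(n, p, h):
    """WC84 variance components for arrays shaped (r, ...) over r groups."""
    r = n.shape[0]
    n_bar = n.mean(axis=0)
    n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum(axis=0) / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=0) / (r * n_bar)
    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (pq - (r - 1) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
    c = h_bar / 2.0
    return a, b, c


def wc_theta(counts: AlleleCounts) -> float:
    """Weir & Cockerham (1984) theta-hat for one SNP over r >= 2 groups.

    Returns NaN when the SNP is monomorphic across all groups combined
    (the estimator is then undefined and the SNP is excluded from
    empirical null distributions).  Negative estimates are possible and
    kept.
    """
    n = counts.sizes
    if n.ndim != 1 or n.size < 2:
        raise ValueError("need >= 2 groups")
    if np.any(n < 1):
        raise ValueError("every group needs >= 1 genotyped diploid")
    p = counts.allele_counts / (2.0 * n)
    h = counts.het_counts / n
    total = counts.allele_counts.sum()
    if total == 0 or total == 2 * n.sum():
        return float("nan")
    a, b, c = _theta_components(n, p, h)
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return float(a / denom)


def group_counts(gm: GenotypeMatrix, groups: list[list[str]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group (sizes, allele counts, het counts), shape (r, M).

    Missing genotypes are excluded per SNP (complete-case per site).
    """
    index = {s: i for i, s in enumerate(gm.samples)}
    sizes, acounts, hcounts = [], [], []
    for members in groups:
        rows = np.array([index[s] for s in members], dtype=np.intp)
        codes = gm.codes[rows]
        called = codes != MISSING
        sizes.append(called.sum(axis=0))
        acounts.append(np.where(called, codes, 0).sum(axis=0))
        hcounts.append((codes == 1).sum(axis=0))
    return (
        np.array(sizes, dtype=np.float64),
        np.array(acounts, dtype=np.float64),
        np.array(hcounts, dtype=np.float64),
    )


def _theta_vector(n, ac, hc) -> np.ndarray:
    """Vectorized theta over M SNPs; NaN where undefined."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ac / (2.0 * n)
        h = hc / np.where(n > 0, n, np.nan)
        a, b, c = _theta_components(n, p, h)
        theta = a / (a + b + c)
    total = ac.sum(axis=0)
    mono = (total == 0) | (total == 2 * n.sum(axis=0))
    theta = np.where(mono, np.nan, theta)
    empty_group = (n == 0).any(axis=0)
    return np.where(empty_group, np.nan, theta)


def fst_scan(
    gm: GenotypeMatrix,
    structure: PopulationStructure,
    level: str,
    min_maf: float = 1e-3,
) -> ScoreTrack:
    """One Weir-Cockerham theta per SNP passing the MAF filter.

    ``level`` is one of ``global-regions``, ``global-populations``,
    ``inter-regional:<region>``, ``intra-regional:<region>``.  The MAF
    filter is applied to the pooled sample of the groups being
    contrasted.
    """
    structure.check_samples(gm.samples)
    in_panel = set(gm.samples)

    def members_of_pops(pops: list[str]) -> list[list[str]]:
        return [[s for s in structure.samples_of_population(p) if s in in_panel] for p in pops]

    if level == "global-regions":
        groups = [
            [s for s in structure.samples_of_region(r) if s in in_panel]
            for r in structure.regions
        ]
    elif level == "global-populations":
        groups = members_of_pops(structure.populations)
    elif level.startswith("inter-regional:"):
        region = level.split(":", 1)[1]
        if region not in structure.regions:
            raise ValueError(f"unknown region {region!r}")
        inside = [s for s in structure.samples_of_region(region) if s in in_panel]
        outside = [s for s in in_panel if structure.region_of_sample(s) != region]
        groups = [inside, sorted(outside)]
    elif level.startswith("intra-regional:"):
        region = level.split(":", 1)[1]
        pops = structure.populations_of_region(region)
        if len(pops) < 2:
            import warnings

            warnings.warn(f"region {region!r} has a single population; empty track")
            return ScoreTrack(
                "fst", level, gm.variants[0].chrom if gm.variants else "unknown",
                np.array([], dtype=np.int64), np.array([]), ids=[], maf=np.array([]),
            )
        groups = members_of_pops(pops)
    else:
        raise ValueError(f"unknown level {level!r}")
    groups = [g for g in groups if g]

    n, ac, hc = group_counts(gm, groups)
    # pooled MAF at this grouping
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = ac.sum(axis=0) / (2.0 * n.sum(axis=0))
    maf = np.minimum(pooled, 1.0 - pooled)
    keep = np.where(np.nan_to_num(maf) >= min_maf)[0]

    theta = _theta_vector(n[:, keep], ac[:, keep], hc[:, keep])
    chrom = gm.variants[0].chrom if gm.variants else "unknown"
    return ScoreTrack(
        test="fst",
        level=level,
        chrom=chrom,
        pos=gm.positions()[keep],
        score=theta,
        ids=[gm.variants[i].id for i in keep],
        maf=maf[keep],
    )


def maf_binned_empirical_p(
    track: ScoreTrack, background: ScoreTrack, bin_size: int = 10_000
) -> ScoreTrack:
    """Empirical p-values ranked within MAF-matched background bins.

    Background SNPs with defined scores are sorted by MAF and cut into
    consecutive bins of ``bin_size`` (the last bin may be short).  Each
    focal SNP is assigned to the bin whose MAF range contains its MAF and
    ranked with the add-one rule, ties counted inclusively:
    ``p = (1 + #{bin scores >= observed}) / (bin count + 1)``.
    """
    if track.maf is None or background.maf is None:
        raise ValueError("both tracks need MAF annotations")
    ok = np.isfinite(background.score) & np.isfinite(background.maf)
    bg_maf = background.maf[ok]
    bg_score = background.score[ok]
    if bg_maf.size == 0:
        raise ValueError("empty background")
    order = np.argsort(bg_maf, kind="stable")
    bg_maf, bg_score = bg_maf[order], bg_score[order]
    edges = list(range(0, bg_maf.size, bin_size)) + [bg_maf.size]
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo:
            bins.append((bg_maf[lo], bg_maf[hi - 1], np.sort(bg_score[lo:hi])))
    if not bins:
        raise ValueError("background too small to form a bin")

    uppers = np.array([b[1] for b in bins])
    p = np.full(len(track), np.nan)
    for i in range(len(track)):
        if not np.isfinite(track.score[i]):
            continue
        k = int(np.searchsorted(uppers, track.maf[i], side="left"))
        if k >= len(bins):
            k = len(bins) - 1
        scores = bins[k][2]
        n_ge = scores.size - np.searchsorted(scores, track.score[i], side="left")
        p[i] = (1.0 + n_ge) / (scores.size + 1.0)
    return ScoreTrack(
        test=track.test, level=track.level, chrom=track.chrom, pos=track.pos,
        score=track.score, ids=track.ids, p=p, maf=track.maf,
    )
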
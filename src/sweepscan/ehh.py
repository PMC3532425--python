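"""Extended haplotype homozygosity statistics: EHH, iHH, iHS, XP-EHH.

EHH for a core SNP and allele class is the probability that two
haplotypes drawn at random among the carriers of that allele are
identical at every SNP between the core and a given flanking SNP
(inclusive interval).  It equals 1 at the core and is non-increasing
with distance, since adding SNPs can only refine the partition of the
carrier set into identity classes.

iHH integrates EHH against genetic distance (cM) outward from the core,
stopping at the first SNP where EHH falls below a cutoff (default 0.05);
the boundary trapezoid down to that SNP is included, with no
interpolation to the exact cutoff crossing.  An integration span that
contains a physical gap larger than 200 kb between successive SNPs
invalidates the statistic ("gap"), and a span that reaches the
chromosome end before the cutoff is crossed invalidates it ("boundary")
— both are reported as NA rather than numbers.

iHS is ln(iHH_ancestral / iHH_derived), standardized to zero mean and
unit variance within 5% bins of derived allele frequency.  Extreme
negative values mark unusually long haplotypes around the derived
allele; extreme positive values, around the ancestral allele.

XP-EHH contrasts a test against a reference population:
ln(iHH_test / iHH_ref) over a single shared span delimited by the EHH
of the pooled sample, then normalized to zero mean and unit variance
across the chromosome-wide track.  Sweeps near fixation in the test
population drive it strongly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GeneticMap, HaplotypePanel, ScoreTrack

__all__ = [
    "EhhCurve",
    "IhhValue",
    "IhsRecord",
    "XpehhRecord",
    "ehh_curve",
    "ihh",
    "ihs_scan",
    "ihs_track",
    "xpehh_scan",
    "xpehh_track",
]


@dataclass
class EhhCurve:
    """EHH values outward from a core SNP in one direction.

    ``indices[0]`` is the core itself; ``ehh[0]`` is 1 for the
    ancestral/derived allele classes and the core-site homozygosity for
    the pooled class ``"all"``.
    """

    core: int
    allele: str  # 'ancestral' | 'derived' | 'all'
    direction: str  # 'left' | 'right'
    indices: np.ndarray
    ehh: np.ndarray
    n_carriers: int
    exhausted: bool  # ran out of SNPs before dropping below the stop threshold


@dataclass
class IhhValue:
    value: float
    valid: bool
    reason: str | None = None  # 'gap' | 'boundary' | 'allele-count' | 'span'


@dataclass
class IhsRecord:
    index: int
    pos: int
    daf: float
    ihh_ancestral: float
    ihh_derived: float
    raw: float
    standardized: float
    valid: bool
    reason: str | None = None


@dataclass
class XpehhRecord:
    index: int
    pos: int
    ihh_test: float
    ihh_ref: float
    raw: float
    normalized: float
    valid: bool
    reason: str | None = None


def _prefix_pair_fractions(C: np.ndarray) -> np.ndarray:
    """Identity-pair fraction for every prefix of the columns of ``C``.

    Returns f with f[t] = P(two random rows identical over columns
    0..t) — computed in O(n log n * L) by sorting rows lexicographically
    once and merging adjacent identity classes in decreasing order of
    the first-difference depth between neighbouring sorted rows.
    """
    n, L = C.shape
    pair_denom = n * (n - 1) / 2.0
    Cc = np.ascontiguousarray(C)
    view = Cc.view(np.dtype((np.void, L)))[:, 0]
    order = np.argsort(view, kind="stable")
    A = Cc[order]
    neq = A[1:] != A[:-1]
    any_diff = neq.any(axis=1)
    depth = np.where(any_diff, neq.argmax(axis=1), L)  # first differing column

    cut_order = np.argsort(-depth, kind="stable")
    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    p_cum = np.zeros(cut_order.size + 1, dtype=np.float64)
    running = 0.0
    for t, i in enumerate(cut_order):
        ra, rb = find(int(i)), find(int(i) + 1)
        running += size[ra] * size[rb]
        parent[rb] = ra
        size[ra] += size[rb]
        p_cum[t + 1] = running
    thresholds = depth[cut_order]  # descending
    # prefix 0..t identical requires depth >= t + 1
    wanted = np.arange(1, L + 1)
    counts = np.searchsorted(-thresholds, -wanted, side="right")
    return p_cum[counts] / pair_denom


def _ehh_walk(haps, rows, core, order, init_labels, stop_below):
    """Walk SNPs in ``order`` refining identity classes among ``rows``.

    Returns (indices walked, EHH at each, exhausted flag).  Walking
    stops once EHH < stop_below (that SNP included).  The initial class
    labels (all-zero for a single allele class, core alleles for the
    pooled class) act as a zeroth column of the identity prefix.
    """
    order = np.asarray(list(order), dtype=np.intp)
    n = rows.size
    if order.size == 0:
        return order, np.array([]), True
    sub = np.ascontiguousarray(haps[rows])
    init_col = np.asarray(init_labels, dtype=np.uint8).reshape(-1, 1)

    chunk = 256 if stop_below is not None else order.size
    while True:
        m = min(chunk, order.size)
        C = np.concatenate([init_col, sub[:, order[:m]]], axis=1)
        f = _prefix_pair_fractions(C)
        vals = f[1:]  # f[0] is the core-only value
        if stop_below is not None:
            below = np.nonzero(vals < stop_below)[0]
            if below.size:
                stop = int(below[0])
                return order[: stop + 1], vals[: stop + 1], False
        if m == order.size:
            return order, vals, True
        chunk *= 4


def _carrier_rows(panel: HaplotypePanel, core: int, allele: str) -> np.ndarray:
    col = panel.haplotypes[:, core]
    if allele == "derived":
        return np.nonzero(col == 1)[0]
    if allele == "ancestral":
        return np.nonzero(col == 0)[0]
    if allele == "all":
        return np.arange(panel.n_haplotypes)
    raise ValueError(f"unknown allele class {allele!r}")


def ehh_curve(
    panel: HaplotypePanel,
    core: int,
    allele: str = "derived",
    direction: str = "right",
    stop_below: float | None = None,
) -> EhhCurve:
    """EHH curve from ``core`` moving left or right along the panel."""
    rows = _carrier_rows(panel, core, allele)
    if rows.size < 2:
        raise ValueError(f"fewer than 2 carriers of the {allele} allele at SNP {core}")
    if direction == "right":
        order = range(core + 1, panel.n_variants)
    elif direction == "left":
        order = range(core - 1, -1, -1)
    else:
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")

    if allele == "all":
        init = panel.haplotypes[rows, core].astype(np.int64)
        n = rows.size
        counts = np.bincount(init)
        e0 = float((counts * (counts - 1)).sum() / (n * (n - 1)))
    else:
        init = np.zeros(rows.size, dtype=np.int64)
        e0 = 1.0
    idx, vals, exhausted = _ehh_walk(
        panel.haplotypes, rows, core, order, init, stop_below
    )
    if stop_below is not None and e0 < stop_below:
        idx, vals, exhausted = np.array([], dtype=int), np.array([]), False
    return EhhCurve(
        core=core,
        allele=allele,
        direction=direction,
        indices=np.concatenate([[core], idx]).astype(int),
        ehh=np.concatenate([[e0], vals]),
        n_carriers=rows.size,
        exhausted=exhausted,
    )


def ihh(
    curve: EhhCurve,
    gmap: GeneticMap,
    panel: HaplotypePanel,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
) -> IhhValue:
    """Trapezoidal integral of an EHH curve against genetic distance (cM).

    Integration proceeds outward and stops at the first SNP with
    EHH < cutoff, including the trapezoid down to that SNP's actual EHH
    value.  Validity follows the NA rules described in the module
    docstring.
    """
    pos = panel.positions()[curve.indices].astype(np.float64)
    cm = np.atleast_1d(gmap.interpolate(pos))
    ehh_vals = curve.ehh
    if ehh_vals[0] < cutoff:
        return IhhValue(0.0, False, "span")

    total = 0.0
    for k in range(1, ehh_vals.size):
        if abs(pos[k] - pos[k - 1]) > max_gap_bp:
            return IhhValue(float("nan"), False, "gap")
        total += 0.5 * (ehh_vals[k] + ehh_vals[k - 1]) * abs(cm[k] - cm[k - 1])
        if ehh_vals[k] < cutoff:
            return IhhValue(total, True, None)
    # never dropped below the cutoff: chromosome end reached first
    return IhhValue(float("nan"), False, "boundary")


def _side_ihh(panel, gmap, core, allele, direction, cutoff, max_gap_bp):
    curve = ehh_curve(panel, core, allele, direction, stop_below=cutoff)
    return ihh(curve, gmap, panel, cutoff=cutoff, max_gap_bp=max_gap_bp)


def _bin_standardize(raw, bin_key, bin_width, min_bin):
    """Zero-mean/unit-variance transform within bins of ``bin_key``.

    Bins with fewer than ``min_bin`` members are merged with the nearest
    non-empty neighbouring bin (lower index on ties) before
    standardizing.  Variance uses the 1/n convention so each bin is
    exactly unit variance afterwards.
    """
    raw = np.asarray(raw, dtype=np.float64)
    k = np.floor(bin_key / bin_width).astype(int)
    k = np.minimum(k, int(np.ceil(1.0 / bin_width)) - 1)
    # merge under-filled bins
    labels = {b: b for b in np.unique(k)}

    def counts():
        eff = np.array([labels[b] for b in k])
        u, c = np.unique(eff, return_counts=True)
        return dict(zip(u, c)), eff

    cmap, eff = counts()
    while len(cmap) > 1 and min(cmap.values()) < min_bin:
        small = min((b for b, c in cmap.items() if c < min_bin), key=lambda b: (cmap[b], b))
        others = sorted(b for b in cmap if b != small)
        target = min(others, key=lambda b: (abs(b - small), b))
        for b in labels:
            if labels[b] == small:
                labels[b] = target
        cmap, eff = counts()

    z = np.empty_like(raw)
    for b in np.unique(eff):
        m = eff == b
        mu = raw[m].mean()
        sd = raw[m].std(ddof=0)
        z[m] = 0.0 if sd == 0 else (raw[m] - mu) / sd
    return z


def ihs_scan(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    min_maf: float = 0.01,
    bin_width: float = 0.05,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
    min_bin: int = 20,
) -> list[IhsRecord]:
    """iHS at every core SNP of a polarized panel.

    Cores failing the MAF filter are skipped entirely; cores where any
    of the four directional integrals is invalid yield a record with the
    validity flag and reason but no standardized score.
    """
    daf = panel.derived_frequency()
    positions = panel.positions()
    records: list[IhsRecord] = []
    for core in range(panel.n_variants):
        d = float(daf[core])
        maf = min(d, 1.0 - d)
        if maf < min_maf:
            continue
        n_der = int(round(d * panel.n_haplotypes))
        n_anc = panel.n_haplotypes - n_der
        if n_der < 2 or n_anc < 2:
            records.append(
                IhsRecord(core, int(positions[core]), d, np.nan, np.nan, np.nan, np.nan,
                          False, "allele-count")
            )
            continue
        parts = {}
        bad = None
        for allele in ("ancestral", "derived"):
            tot = 0.0
            for direction in ("left", "right"):
                r = _side_ihh(panel, gmap, core, allele, direction, cutoff, max_gap_bp)
                if not r.valid:
                    bad = r.reason
                    break
                tot += r.value
            if bad:
                break
            parts[allele] = tot
        if bad:
            records.append(
                IhsRecord(core, int(positions[core]), d, np.nan, np.nan, np.nan, np.nan,
                          False, bad)
            )
            continue
        ihh_a, ihh_d = parts["ancestral"], parts["derived"]
        if ihh_a <= 0 or ihh_d <= 0:
            records.append(
                IhsRecord(core, int(positions[core]), d, ihh_a, ihh_d, np.nan, np.nan,
                          False, "zero-ihh")
            )
            continue
        raw = float(np.log(ihh_a / ihh_d))
        records.append(IhsRecord(core, int(positions[core]), d, ihh_a, ihh_d, raw, np.nan, True))

    valid = [r for r in records if r.valid]
    if not valid:
        import warnings

        warnings.warn("no valid iHS scores")
        return records
    z = _bin_standardize(
        np.array([r.raw for r in valid]),
        np.array([r.daf for r in valid]),
        bin_width,
        min_bin,
    )
    for r, zi in zip(valid, z):
        r.standardized = float(zi)
    return records


def ihs_track(records: list[IhsRecord], chrom: str, level: str = "region") -> ScoreTrack:
    pos = np.array([r.pos for r in records], dtype=np.int64)
    score = np.array([r.standardized for r in records])
    maf = np.array([min(r.daf, 1 - r.daf) for r in records])
    return ScoreTrack("ihs", level, chrom, pos, score, maf=maf)


def xpehh_scan(
    test: HaplotypePanel,
    ref: HaplotypePanel,
    gmap: GeneticMap,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
    min_maf: float = 0.0,
) -> list[XpehhRecord]:
    """XP-EHH at every shared core SNP.

    The integration span on each side is delimited where the EHH of the
    pooled (test + reference) sample drops below ``cutoff``; both
    populations are then integrated over exactly that span, and
    raw = ln(iHH_test / iHH_ref).  Raw scores are normalized to zero
    mean and unit variance across the valid records of the track.
    """
    if [v.id for v in test.variants] != [v.id for v in ref.variants]:
        raise ValueError("test and reference panels must share the same variant set")
    pooled_h = np.vstack([test.haplotypes, ref.haplotypes])
    positions = test.positions()
    cm = np.atleast_1d(gmap.interpolate(positions.astype(np.float64)))
    n_pool = pooled_h.shape[0]
    all_rows = np.arange(n_pool)

    records: list[XpehhRecord] = []
    for core in range(test.n_variants):
        if min_maf > 0:
            p = float(pooled_h[:, core].mean())
            if min(p, 1 - p) < min_maf:
                continue
        # pooled homozygosity at the core delimits whether a span exists at all
        counts = np.bincount(pooled_h[:, core].astype(np.int64), minlength=2)
        e0 = float((counts * (counts - 1)).sum() / (n_pool * (n_pool - 1)))
        if e0 < cutoff:
            records.append(XpehhRecord(core, int(positions[core]), np.nan, np.nan,
                                       np.nan, np.nan, False, "span"))
            continue
        spans = {}
        fail = None
        for direction, order in (
            ("left", range(core - 1, -1, -1)),
            ("right", range(core + 1, test.n_variants)),
        ):
            idx, vals, exhausted = _ehh_walk(
                pooled_h, all_rows, core, order, pooled_h[all_rows, core].astype(np.int64),
                cutoff,
            )
            if exhausted:
                fail = "boundary"
                break
            span = np.concatenate([[core], idx]).astype(int)
            if np.any(np.abs(np.diff(positions[span].astype(np.int64))) > max_gap_bp):
                fail = "gap"
                break
            spans[direction] = span
        if fail:
            records.append(XpehhRecord(core, int(positions[core]), np.nan, np.nan,
                                       np.nan, np.nan, False, fail))
            continue

        ihh_t = ihh_r = 0.0
        for direction, span in spans.items():
            for which, pan in (("t", test), ("r", ref)):
                rows = np.arange(pan.n_haplotypes)
                init = pan.haplotypes[rows, core].astype(np.int64)
                _, vals, _ = _ehh_walk(pan.haplotypes, rows, core, span[1:], init, None)
                n = rows.size
                c0 = np.bincount(init, minlength=2)
                e0p = float((c0 * (c0 - 1)).sum() / (n * (n - 1)))
                ev = np.concatenate([[e0p], vals])
                d = np.abs(np.diff(cm[span]))
                val = float((0.5 * (ev[1:] + ev[:-1]) * d).sum())
                if which == "t":
                    ihh_t += val
                else:
                    ihh_r += val
        if ihh_t <= 0 or ihh_r <= 0:
            records.append(XpehhRecord(core, int(positions[core]), ihh_t, ihh_r,
                                       np.nan, np.nan, False, "zero-ihh"))
            continue
        raw = float(np.log(ihh_t / ihh_r))
        records.append(XpehhRecord(core, int(positions[core]), ihh_t, ihh_r, raw, np.nan, True))

    valid = [r for r in records if r.valid]
    if valid:
        raws = np.array([r.raw for r in valid])
        mu, sd = raws.mean(), raws.std(ddof=0)
        for r in valid:
            r.normalized = 0.0 if sd == 0 else float((r.raw - mu) / sd)
    return records


def xpehh_track(records: list[XpehhRecord], chrom: str, level: str = "region") -> ScoreTrack:
    pos = np.array([r.pos for r in records], dtype=np.int64)
    score = np.array([r.normalized for r in records])
    return ScoreTrack("xpehh", level, chrom, pos, score)
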
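"""Gene-scale haplotype analysis: EM frequency estimation, weighted
global frequencies, diversity, ancestral-haplotype identification,
pairwise LD and LD-block delineation.

Haplotype frequencies from unphased diploid genotypes are maximum
likelihood by expectation-maximization over phase configurations, run
from several random starting points and keeping the best final
log-likelihood.  At gene scale (<= 12 SNPs) the phase space is
enumerable and EM is exact in the likelihood; phased input bypasses
estimation entirely (direct gamete counting).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix, HaplotypePanel, PopulationStructure

__all__ = [
    "HaplotypeTable",
    "EmResult",
    "em_haplotype_frequencies",
    "count_gametes",
    "regional_haplotype_table",
    "global_frequencies",
    "haplotype_diversity",
    "identify_ancestral_haplotype",
    "LdResult",
    "ld_pairwise",
    "dprime_matrix",
    "ld_blocks",
]

MAX_EM_SNPS = 12


# ------------------------------------------------------------------ EM


@dataclass
class EmResult:
    frequencies: dict[str, float]  # haplotype 0/1-string -> frequency
    loglik: float
    n_individuals: int
    n_iterations: int


def _compatible_pairs(g: np.ndarray) -> list[tuple[int, int, int]]:
    """(hap1 bits, hap2 bits, ordering multiplicity) for one genotype row."""
    het = np.nonzero(g == 1)[0]
    mis = np.nonzero(g == MISSING)[0]
    base = 0
    for j in np.nonzero(g == 2)[0]:
        base |= 1 << int(j)
    pairs: dict[tuple[int, int], int] = {}
    for het_bits in itertools.product((0, 1), repeat=len(het)):
        for mis1 in itertools.product((0, 1), repeat=len(mis)):
            for mis2 in itertools.product((0, 1), repeat=len(mis)):
                h1, h2 = base, base
                for j, b in zip(het, het_bits):
                    if b:
                        h1 |= 1 << int(j)
                    else:
                        h2 |= 1 << int(j)
                for j, b in zip(mis, mis1):
                    if b:
                        h1 |= 1 << int(j)
                for j, b in zip(mis, mis2):
                    if b:
                        h2 |= 1 << int(j)
                key = (h1, h2) if h1 <= h2 else (h2, h1)
                pairs[key] = pairs.get(key, 0) + 1
    # collapse ordering multiplicity: unordered pair with h1 != h2 counted once,
    # weighted 2 in the likelihood
    return [(a, b, 1 if a == b else 1) for (a, b), _ in pairs.items()]


def _bits_to_string(bits: int, m: int) -> str:
    return "".join("1" if bits >> j & 1 else "0" for j in range(m))


def em_haplotype_frequencies(
    gm: GenotypeMatrix,
    max_missing: int = 2,
    max_iter: int = 500,
    tol: float = 1e-9,
    restarts: int = 10,
    seed: int = 0,
) -> EmResult:
    """ML haplotype frequencies by multi-restart EM over phase configurations.

    Individuals with more than ``max_missing`` missing genotypes are
    excluded.  The log-likelihood is asserted non-decreasing at every
    iteration; the best of ``restarts`` runs is returned.
    """
    m = gm.n_variants
    if m > MAX_EM_SNPS:
        raise ValueError(f"EM supports <= {MAX_EM_SNPS} SNPs, got {m}")
    rows = [i for i in range(gm.n_samples) if (gm.codes[i] == MISSING).sum() <= max_missing]
    if not rows:
        raise ValueError("no individuals pass the missingness filter")

    pair_lists = [_compatible_pairs(gm.codes[i]) for i in rows]
    hap_ids = sorted({h for pl in pair_lists for a, b, _ in pl for h in (a, b)})
    index = {h: k for k, h in enumerate(hap_ids)}
    K = len(hap_ids)
    # per individual: arrays of (idx1, idx2, weight) with weight 2 for het pairs
    enc = [
        (
            np.array([index[a] for a, b, _ in pl]),
            np.array([index[b] for a, b, _ in pl]),
            np.array([1.0 if a == b else 2.0 for a, b, _ in pl]),
        )
        for pl in pair_lists
    ]

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, int] | None = None
    for r in range(max(restarts, 1)):
        p = rng.dirichlet(np.ones(K)) if r > 0 else np.full(K, 1.0 / K)
        last_ll = -np.inf
        for it in range(1, max_iter + 1):
            counts = np.zeros(K)
            ll = 0.0
            for i1, i2, w in enc:
                lik = w * p[i1] * p[i2]
                tot = lik.sum()
                ll += np.log(max(tot, 1e-300))
                lik /= max(tot, 1e-300)
                np.add.at(counts, i1, lik)
                np.add.at(counts, i2, lik)
            assert ll >= last_ll - 1e-9, "EM log-likelihood decreased"
            p_new = counts / (2.0 * len(enc))
            if ll - last_ll < tol and it > 1:
                last_ll = ll
                break
            last_ll = ll
            p = p_new
        if best is None or last_ll > best[0]:
            best = (last_ll, p, it)

    ll, p, iters = best
    freqs = {
        _bits_to_string(h, m): float(p[index[h]]) for h in hap_ids if p[index[h]] > 1e-12
    }
    return EmResult(freqs, float(ll), len(rows), iters)


def count_gametes(panel: HaplotypePanel, rows: np.ndarray | None = None) -> dict[str, float]:
    """Direct haplotype frequencies from phased data."""
    h = panel.haplotypes if rows is None else panel.haplotypes[rows]
    strings = ["".join(map(str, row)) for row in h]
    out: dict[str, float] = {}
    for s in strings:
        out[s] = out.get(s, 0.0) + 1.0
    return {k: v / len(strings) for k, v in out.items()}


# ------------------------------------------------------------- tables


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-region and weighted global frequencies.

    Labels H1, H2, ... follow descending global frequency (ties broken
    lexicographically on the haplotype string).  ``labeled`` restricts
    to haplotypes above the reporting floor in at least one region; the
    full estimate set stays in ``haplotypes``/``frequencies``.
    """

    snp_ids: list[str]
    haplotypes: list[str]
    regional: dict[str, np.ndarray]  # region -> frequency per haplotype
    weights: dict[str, float]  # region -> gamete count used
    global_frequency: np.ndarray
    labels: dict[str, str]  # haplotype string -> H-label (floor-passing only)
    floor: float = 0.01

    def label_of(self, hap: str) -> str | None:
        return self.labels.get(hap)

    def haplotype_of_label(self, label: str) -> str | None:
        for h, l in self.labels.items():
            if l == label:
                return h
        return None


def global_frequencies(
    regional: dict[str, np.ndarray], weights: dict[str, float]
) -> np.ndarray:
    """Weighted mean of regional frequencies (weights ~ sample counts)."""
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("weights sum to zero")
    out = None
    for region, f in regional.items():
        term = weights[region] / total * np.asarray(f, dtype=np.float64)
        out = term if out is None else out + term
    return out


def regional_haplotype_table(
    gm: GenotypeMatrix,
    structure: PopulationStructure,
    max_missing: int = 2,
    restarts: int = 10,
    seed: int = 0,
    floor: float = 0.01,
) -> HaplotypeTable:
    """EM per region, then weighted global frequencies and H-labels."""
    regional_raw: dict[str, dict[str, float]] = {}
    weights: dict[str, float] = {}
    for region in structure.regions:
        members = [s for s in structure.samples_of_region(region) if s in gm.samples]
        if not members:
            continue
        sub = gm.take_samples(members)
        res = em_haplotype_frequencies(sub, max_missing=max_missing, restarts=restarts, seed=seed)
        regional_raw[region] = res.frequencies
        weights[region] = 2.0 * res.n_individuals

    universe = sorted({h for f in regional_raw.values() for h in f})
    regional = {
        region: np.array([f.get(h, 0.0) for h in universe])
        for region, f in regional_raw.items()
    }
    gfreq = global_frequencies(regional, weights)
    passing = [
        i for i, h in enumerate(universe)
        if any(regional[r][i] >= floor for r in regional)
    ]
    order = sorted(passing, key=lambda i: (-gfreq[i], universe[i]))
    labels = {universe[i]: f"H{rank + 1}" for rank, i in enumerate(order)}
    return HaplotypeTable(
        snp_ids=[v.id for v in gm.variants],
        haplotypes=universe,
        regional=regional,
        weights=weights,
        global_frequency=gfreq,
        labels=labels,
        floor=floor,
    )


def haplotype_diversity(frequencies: np.ndarray, n: int) -> tuple[float, float]:
    """Unbiased haplotype diversity H and its standard error (Nei 1987).

    H = n/(n-1) (1 - sum p_i^2); the SE is the square root of
    V(H) = 2/(n(n-1)) {2(n-2) [sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2}.
    ``n`` is the number of gametes.
    """
    if n < 2:
        raise ValueError("need at least 2 gametes")
    p = np.asarray(frequencies, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    H = n / (n - 1.0) * (1.0 - s2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return H, float(np.sqrt(max(var, 0.0)))


def identify_ancestral_haplotype(table: HaplotypeTable, ancestral: str | None = None) -> str | None:
    """Label of the haplotype carrying the ancestral allele at every SNP.

    With derived-coded haplotypes the ancestral string is all zeros
    (the default).  Returns None when it is not among the observed
    haplotypes.
    """
    if ancestral is None:
        ancestral = "0" * len(table.snp_ids)
    if len(ancestral) != len(table.snp_ids) or set(ancestral) - {"0", "1"}:
        raise ValueError("ancestral string must be 0/1 over the table's SNP set")
    if ancestral not in table.haplotypes:
        return None
    return table.labels.get(ancestral)


# ------------------------------------------------------------------- LD


@dataclass
class LdResult:
    dprime: float
    rsq: float
    defined: bool = True
    reason: str | None = None


def _ld_from_hap_freqs(p_ab: float, p_a: float, p_b: float) -> LdResult:
    qa, qb = 1.0 - p_a, 1.0 - p_b
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LdResult(np.nan, np.nan, False, "monomorphic")
    D = p_ab - p_a * p_b
    if D >= 0:
        dmax = min(p_a * qb, qa * p_b)
    else:
        dmax = min(p_a * p_b, qa * qb)
    dprime = 0.0 if dmax == 0 else D / dmax
    rsq = D * D / (p_a * qa * p_b * qb)
    return LdResult(float(dprime), float(rsq))


def ld_pairwise(data, i: int, j: int, samples: list[str] | None = None) -> LdResult:
    """Lewontin's D' and r^2 for one SNP pair.

    Phased input gives haplotype counts directly; unphased genotypes go
    through a two-locus EM first.  A monomorphic SNP in the evaluated
    sample yields an undefined (flagged) result, never a silent zero.
    """
    if isinstance(data, HaplotypePanel):
        panel = data if samples is None else data.take_samples(samples)
        a = panel.haplotypes[:, i].astype(float)
        b = panel.haplotypes[:, j].astype(float)
        return _ld_from_hap_freqs(float((a * b).mean()), float(a.mean()), float(b.mean()))
    if isinstance(data, GenotypeMatrix):
        sub = data if samples is None else data.take_samples(samples)
        pair = sub.take_variants([min(i, j), max(i, j)])
        complete = ~np.any(pair.codes == MISSING, axis=1)
        pair = GenotypeMatrix(
            [s for s, ok in zip(pair.samples, complete) if ok],
            pair.variants,
            pair.codes[complete],
        )
        if pair.n_samples == 0:
            return LdResult(np.nan, np.nan, False, "no-complete-genotypes")
        freqs = em_haplotype_frequencies(pair, max_missing=0, restarts=4, seed=0).frequencies
        p11 = freqs.get("11", 0.0)
        p_a = freqs.get("10", 0.0) + p11
        p_b = freqs.get("01", 0.0) + p11
        return _ld_from_hap_freqs(p11, p_a, p_b)
    raise TypeError(f"cannot compute LD from {type(data).__name__}")


def dprime_matrix(data, indices: np.ndarray | None = None, samples: list[str] | None = None) -> np.ndarray:
    """|D'| for all pairs (NaN where undefined)."""
    if indices is None:
        n = data.n_variants
        indices = np.arange(n)
    m = len(indices)
    out = np.full((m, m), np.nan)
    np.fill_diagonal(out, 1.0)
    for a in range(m):
        for b in range(a + 1, m):
            r = ld_pairwise(data, int(indices[a]), int(indices[b]), samples)
            if r.defined:
                out[a, b] = out[b, a] = abs(r.dprime)
    return out


def ld_blocks(
    dprime: np.ndarray,
    positions: np.ndarray,
    d_min: float = 0.8,
    f_min: float = 0.9,
) -> list[tuple[int, int]]:
    """Greedy chaining of strong-LD runs into maximal blocks.

    Starting at each unassigned SNP, the block grows rightward while the
    fraction of strong pairs (|D'| >= d_min) among informative pairs
    inside the block stays >= f_min.  Blocks need >= 2 SNPs.  Returns
    (start bp, end bp) intervals.
    """
    m = dprime.shape[0]
    positions = np.asarray(positions)
    blocks: list[tuple[int, int]] = []
    i = 0
    while i < m - 1:
        end = i
        strong = informative = 0
        for j in range(i + 1, m):
            col = dprime[i : j, j]
            inf = np.isfinite(col)
            informative += int(inf.sum())
            strong += int((col[inf] >= d_min).sum())
            if informative == 0 or strong / informative < f_min:
                break
            end = j
        if end > i:
            blocks.append((int(positions[i]), int(positions[end])))
            i = end + 1
        else:
            i += 1
    return blocks
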
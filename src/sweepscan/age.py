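"""Allele-age estimation from the decay of a shared ancestral haplotype.

All carriers of a focal allele are assumed to descend from a single
common ancestor who introduced it n generations ago.  Over n meioses
the ancestral haplotype around the focal site is eroded by
recombination; the length of the segment still shared by present-day
carriers is therefore informative about n.  For each carrier haplotype
and each side of the focal site, the observation is the first marker
(scanning outward) discordant with the shared ancestral haplotype.

With c_j the recombination fraction between the focal site and marker j
(ordered outward), the ancestral segment survives past marker j with
probability (1 - c_j)^n.  A haplotype whose segment ended between
markers j-1 and j still matches the ancestral haplotype at marker
m >= j by state with probability f_m (the population frequency of the
ancestral-consensus allele), giving a geometric identity-by-state tail.
Retained ancestral markers mutate with probability 1 - (1 - mu)^n.
The per-side outcome probabilities are

  P(first discordance at k) = A_k (1-u)^(k-1) u
      + sum_{j<=k} (A_{j-1} - A_j) (1-u)^(j-1) (prod_{m=j}^{k-1} f_m) (1 - f_k)
  P(no discordance)         = A_K (1-u)^K
      + sum_{j<=K} (A_{j-1} - A_j) (1-u)^(j-1) prod_{m=j}^{K} f_m

with A_j = (1 - c_j)^n, A_0 = 1 and u = 1 - (1 - mu)^n; they sum to one
exactly for any mu and f.  Sides and haplotypes are treated as
independent; n is estimated by maximizing the summed log-likelihood on
an integer grid, with a 95% profile-likelihood interval
{n : loglik(n) >= max - 1.92} and years = n * generation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GeneticMap, HaplotypePanel, PopulationStructure

__all__ = [
    "AgeEstimate",
    "SideData",
    "CarrierHaplotypeSet",
    "haldane_fraction",
    "modal_carrier_haplotype",
    "build_carrier_set",
    "detect_breakpoints",
    "side_outcome_probs",
    "estiage_loglik",
    "mle_age",
    "sides_from_concordance",
]

DEFAULT_MU = 1e-6
DEFAULT_GENERATION_TIME = 25.0


def haldane_fraction(cm) -> np.ndarray:
    """Genetic distance (cM) -> recombination fraction, Haldane map function."""
    d = np.abs(np.asarray(cm, dtype=np.float64)) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


@dataclass
class AgeEstimate:
    generations: int
    ci_generations: tuple[int, int]
    generation_time: float = DEFAULT_GENERATION_TIME
    at_boundary: bool = False

    @property
    def years(self) -> float:
        return self.generations * self.generation_time

    @property
    def ci_years(self) -> tuple[float, float]:
        lo, hi = self.ci_generations
        return (lo * self.generation_time, hi * self.generation_time)


@dataclass
class SideData:
    """One side of the focal site: marker geometry plus observed breaks.

    ``rec_fraction`` and ``match_freq`` are ordered outward from the
    focal site; ``breaks[i]`` is the 1-based index of the first
    discordant marker for haplotype i, or 0 when the haplotype is
    concordant out to the window edge.
    """

    rec_fraction: np.ndarray
    match_freq: np.ndarray
    breaks: np.ndarray

    def __post_init__(self) -> None:
        self.rec_fraction = np.asarray(self.rec_fraction, dtype=np.float64)
        self.match_freq = np.asarray(self.match_freq, dtype=np.float64)
        self.breaks = np.asarray(self.breaks, dtype=np.int64)
        if np.any(np.diff(self.rec_fraction) < 0):
            raise ValueError("recombination fractions must be non-decreasing outward")
        if self.rec_fraction.shape != self.match_freq.shape:
            raise ValueError("rec_fraction and match_freq length mismatch")
        if np.any((self.breaks < 0) | (self.breaks > self.rec_fraction.size)):
            raise ValueError("break index outside marker range")


@dataclass
class CarrierHaplotypeSet:
    """Modal carrier haplotypes around a focal site, ready for dating.

    ``haplotypes`` holds one modal haplotype per population over the
    window markers (columns ordered by position); ``focal_index`` is the
    focal SNP's column.  ``allele1_freq`` is the full-sample frequency
    of allele 1 at each marker and ``cm`` the genetic position.
    """

    haplotypes: np.ndarray
    focal_index: int
    cm: np.ndarray
    allele1_freq: np.ndarray
    populations: list[str]
    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        if not np.all(self.haplotypes[:, self.focal_index] == self.haplotypes[0, self.focal_index]):
            raise ValueError("all haplotypes must carry the focal allele at the focal site")


def modal_carrier_haplotype(
    panel: HaplotypePanel,
    structure: PopulationStructure,
    population: str,
    focal_index: int,
    focal_allele: int = 1,
    window_bp: float = 6e6,
) -> np.ndarray | None:
    """Per-marker majority allele among a population's carrier haplotypes.

    Ties break toward the across-population carrier consensus, then
    toward the ancestral (0) allele.  Returns None when the population
    has no carrier.
    """
    positions = panel.positions()
    center = positions[focal_index]
    cols = np.nonzero(np.abs(positions - center) <= window_bp / 2)[0]

    pop_rows = panel.haplotype_rows_of_samples(structure.samples_of_population(population))
    carriers = pop_rows[panel.haplotypes[pop_rows, focal_index] == focal_allele]
    if carriers.size == 0:
        return None
    all_carriers = np.nonzero(panel.haplotypes[:, focal_index] == focal_allele)[0]
    sub = panel.haplotypes[np.ix_(carriers, cols)]
    ones = sub.sum(axis=0)
    modal = (2 * ones > carriers.size).astype(np.uint8)
    tied = 2 * ones == carriers.size
    if tied.any():
        global_ones = panel.haplotypes[np.ix_(all_carriers, cols)].sum(axis=0)
        global_modal = (2 * global_ones > all_carriers.size).astype(np.uint8)
        modal[tied] = global_modal[tied]  # remaining global ties fall to 0 (ancestral)
    return modal


def build_carrier_set(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    structure: PopulationStructure,
    populations: list[str],
    focal_index: int,
    focal_allele: int = 1,
    window_bp: float = 6e6,
    mu: float = DEFAULT_MU,
) -> CarrierHaplotypeSet:
    """One modal carrier haplotype per population over the focal window."""
    import warnings

    positions = panel.positions()
    center = positions[focal_index]
    cols = np.nonzero(np.abs(positions - center) <= window_bp / 2)[0]
    focal_col = int(np.searchsorted(cols, focal_index))

    rows = []
    kept: list[str] = []
    for pop in populations:
        modal = modal_carrier_haplotype(panel, structure, pop, focal_index, focal_allele, window_bp)
        if modal is None:
            warnings.warn(f"population {pop!r} has no carrier of the focal allele; omitted")
            continue
        modal[focal_col] = focal_allele  # the focal site itself defines carriership
        rows.append(modal)
        kept.append(pop)
    if not rows:
        raise ValueError("no population carries the focal allele")
    cm = np.atleast_1d(gmap.interpolate(positions[cols].astype(np.float64)))
    freq = panel.haplotypes[:, cols].mean(axis=0)
    return CarrierHaplotypeSet(
        np.array(rows, dtype=np.uint8), focal_col, cm, freq, kept, mu
    )


def detect_breakpoints(cset: CarrierHaplotypeSet) -> tuple[SideData, SideData]:
    """First discordant marker per haplotype on each side of the focal site.

    The shared ancestral haplotype is the across-haplotype consensus
    (majority per marker, ties to the higher-frequency allele then 0);
    identity-by-state match frequencies use the full-sample frequency of
    the consensus allele.
    """
    H = cset.haplotypes
    n_hap = H.shape[0]
    ones = H.sum(axis=0)
    consensus = (2 * ones > n_hap).astype(np.uint8)
    tied = 2 * ones == n_hap
    consensus[tied] = (cset.allele1_freq[tied] > 0.5).astype(np.uint8)

    match = cset.allele1_freq.copy()
    match = np.where(consensus == 1, match, 1.0 - match)
    focal_cm = cset.cm[cset.focal_index]

    sides = []
    for which in ("left", "right"):
        if which == "left":
            order = np.arange(cset.focal_index - 1, -1, -1)
        else:
            order = np.arange(cset.focal_index + 1, H.shape[1])
        c = haldane_fraction(np.abs(cset.cm[order] - focal_cm))
        f = match[order]
        conc = (H[:, order] == consensus[order]).astype(np.uint8)
        breaks = np.zeros(n_hap, dtype=np.int64)
        for i in range(n_hap):
            disc = np.nonzero(conc[i] == 0)[0]
            breaks[i] = disc[0] + 1 if disc.size else 0
        sides.append(SideData(c, f, breaks))
    return sides[0], sides[1]


def _outcome_prob_matrix(c, f, mu, ns) -> np.ndarray:
    """Outcome probabilities for every age in ``ns``: shape (len(ns), K+1).

    Uses the recurrence G_k = sum_{j<=k} dA_j (1-u)^(j-1) prod_{m=j}^{k-1} f_m,
    G_{k+1} = G_k f_k + dA_{k+1} (1-u)^k, so each side costs O(K) per age.
    """
    c = np.asarray(c, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    ns = np.asarray(ns)
    K = c.size
    u = 1.0 - (1.0 - mu) ** ns[:, None]  # (N, 1)
    A = (1.0 - c)[None, :] ** ns[:, None]  # (N, K): A_1..A_K
    A_full = np.concatenate([np.ones((ns.size, 1)), A], axis=1)  # A_0..A_K
    dA = A_full[:, :-1] - A_full[:, 1:]  # (N, K)
    keep = (1.0 - u) ** np.arange(0, K + 1)[None, :]  # (N, K+1)

    probs = np.zeros((ns.size, K + 1))
    G = np.zeros(ns.size)
    for k in range(1, K + 1):
        G = (G * f[k - 2] if k > 1 else G) + dA[:, k - 1] * keep[:, k - 1]
        probs[:, k - 1] = A[:, k - 1] * keep[:, k - 1] * u[:, 0] + (1.0 - f[k - 1]) * G
    probs[:, K] = A[:, K - 1] * keep[:, K] + G * f[K - 1] if K > 0 else 1.0
    return probs


def side_outcome_probs(
    rec_fraction: np.ndarray,
    match_freq: np.ndarray,
    n: int,
    mu: float = DEFAULT_MU,
) -> np.ndarray:
    """Probability of each per-side outcome at age ``n``.

    Returns length K+1: entries 0..K-1 are P(first discordance at marker
    k+1), entry K is P(concordant to the window edge).  Sums to 1 for
    any mutation rate and match frequencies.
    """
    return _outcome_prob_matrix(rec_fraction, match_freq, mu, np.array([n]))[0]


def estiage_loglik(sides: list[SideData], n: int, mu: float = DEFAULT_MU) -> float:
    """Log-likelihood of the observed breakpoints at age ``n`` generations."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    total = 0.0
    for side in sides:
        probs = side_outcome_probs(side.rec_fraction, side.match_freq, n, mu)
        idx = np.where(side.breaks == 0, probs.size - 1, side.breaks - 1)
        total += float(np.log(np.maximum(probs[idx], 1e-300)).sum())
    return total


def mle_age(
    sides: list[SideData],
    n_max: int = 5000,
    mu: float = DEFAULT_MU,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> AgeEstimate:
    """Integer-grid maximum-likelihood age with a profile-likelihood CI."""
    import warnings

    ns = np.arange(1, n_max + 1)
    ll = np.zeros(ns.size)
    for side in sides:
        probs = _outcome_prob_matrix(side.rec_fraction, side.match_freq, mu, ns)
        idx = np.where(side.breaks == 0, probs.shape[1] - 1, side.breaks - 1)
        ll += np.log(np.maximum(probs[:, idx], 1e-300)).sum(axis=1)
    best = int(np.argmax(ll))
    inside = np.nonzero(ll >= ll[best] - 1.92)[0]
    lo, hi = int(ns[inside[0]]), int(ns[inside[-1]])
    boundary = best in (0, len(ns) - 1)
    if boundary:
        warnings.warn(f"age maximum at grid boundary (n = {ns[best]})")
    return AgeEstimate(int(ns[best]), (lo, hi), generation_time, boundary)


def sides_from_concordance(
    conc_left: np.ndarray,
    conc_right: np.ndarray,
    marker_cm: np.ndarray,
    match_freq: np.ndarray,
) -> list[SideData]:
    """Build SideData from 0/1 ancestral-concordance matrices (simulation aid)."""
    c = haldane_fraction(marker_cm)
    out = []
    for conc in (conc_left, conc_right):
        n_hap = conc.shape[0]
        breaks = np.zeros(n_hap, dtype=np.int64)
        for i in range(n_hap):
            disc = np.nonzero(conc[i] == 0)[0]
            breaks[i] = disc[0] + 1 if disc.size else 0
        out.append(SideData(c, match_freq, breaks))
    return out
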
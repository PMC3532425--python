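"""Cross-population composite likelihood ratio (XP-CLR) sweep scan.

The test contrasts allele frequencies in a test population against a
reference population over a genetic-distance window.  Under the null
model the test-population frequency p2 drifts around the reference
frequency p1 as a Gaussian with variance omega * p1 * (1 - p1); mass
falling outside [0, 1] is collapsed onto the boundaries (loss or
fixation).  Under the sweep alternative, a linked neutral lineage
escapes the sweep with probability

    c(s, d) = 1 - exp(-r_d * (2/s) * ln(max(2*N*s, 2)))

where r_d is the recombination fraction at genetic distance d from the
selected site (Haldane) and (2/s) ln(2Ns) approximates the sweep
duration in generations.  Lineages that fail to escape are dragged to
the swept allele, so the post-sweep frequency is a two-point mixture:
with probability p1 the sweeping haplotype carried the coded allele and
the frequency is shifted to c*p1 + (1-c); otherwise it is shifted to
c*p1.  Weak selection or large distance make c -> 1 and the sweep model
collapses onto the null.

The observed test-population allele count is binomial around p2, and
the marginal likelihood integrates the drift density by fixed-order
Gauss-Legendre quadrature (order 64) so scores are reproducible.  The
window score is twice the maximized composite log-likelihood ratio over
a logarithmic grid of selection coefficients, floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GeneticMap, GenotypeMatrix, MISSING, ScoreTrack

__all__ = [
    "DriftParam",
    "XpclrGrid",
    "estimate_omega",
    "build_grid",
    "single_snp_loglik",
    "xpclr_score",
    "xpclr_scan",
    "DEFAULT_S_GRID",
]

_GL_ORDER = 64
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(_GL_ORDER)
# map from [-1, 1] to (0, 1)
_U = 0.5 * (_GL_NODES + 1.0)
_W = 0.5 * _GL_WEIGHTS

DEFAULT_S_GRID = np.logspace(-4, -1, 20)


@dataclass
class DriftParam:
    """Variance-scaling drift coefficient between test and reference."""

    omega: float

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be positive")


@dataclass
class XpclrGrid:
    """Regularly spaced grid points with their SNP windows."""

    positions: np.ndarray  # grid point bp
    windows: list[np.ndarray]  # SNP indices per grid point (may be empty)
    spacing: int
    window_cm: float


def estimate_omega(
    p_test: np.ndarray,
    p_ref: np.ndarray,
    min_snps: int = 1000,
    floor: float = 1e-6,
    robust: bool = False,
) -> DriftParam:
    """Method-of-moments drift coefficient from background frequency pairs.

    omega-hat = mean over SNPs of (p_test - p_ref)^2 / (p_ref (1 - p_ref)),
    restricted to SNPs segregating in the reference.  With
    ``robust=True`` the mean is replaced by the median rescaled by the
    chi-square(1) median (0.4549), which is insensitive to swept regions
    and to the heavy tails of real drift.
    """
    p_test = np.asarray(p_test, dtype=np.float64)
    p_ref = np.asarray(p_ref, dtype=np.float64)
    ok = np.isfinite(p_test) & np.isfinite(p_ref) & (p_ref > 0) & (p_ref < 1)
    if ok.sum() < min_snps:
        raise ValueError(f"need >= {min_snps} informative background SNPs, got {int(ok.sum())}")
    r = (p_test[ok] - p_ref[ok]) ** 2 / (p_ref[ok] * (1 - p_ref[ok]))
    if robust:
        w = float(np.median(r)) / 0.45494  # chi2(1) median
    else:
        w = float(r.mean())
    if w < floor:
        import warnings

        warnings.warn(f"omega estimate {w:.3g} below floor; clamped to {floor}")
        w = floor
    return DriftParam(float(w))


def build_grid(
    interval: tuple[int, int],
    gmap: GeneticMap,
    gm: GenotypeMatrix,
    spacing: int = 4000,
    window_cm: float = 0.1,
    max_snps: int = 200,
    min_maf: float = 1e-3,
    seed: int = 0,
    maf: np.ndarray | None = None,
) -> XpclrGrid:
    """Grid points every ``spacing`` bp with SNPs within +-window_cm/2.

    The MAF filter uses ``maf`` when given (e.g. pooled test+reference
    frequencies), else the panel's own frequencies.  Windows exceeding
    ``max_snps`` are downsampled uniformly without replacement
    (deterministic under ``seed``).  Empty windows stay empty and score
    as missing.
    """
    start, end = interval
    rng = np.random.default_rng(seed)
    grid_pos = np.arange(start, end + 1, spacing, dtype=np.int64)
    if maf is None:
        maf = gm.minor_allele_frequency()
    usable = np.where(np.nan_to_num(maf) >= min_maf)[0]
    snp_pos = gm.positions()[usable].astype(np.float64)
    snp_cm = np.atleast_1d(gmap.interpolate(snp_pos))
    grid_cm = np.atleast_1d(gmap.interpolate(grid_pos.astype(np.float64)))
    half = window_cm / 2.0
    windows: list[np.ndarray] = []
    for gc in grid_cm:
        lo = np.searchsorted(snp_cm, gc - half, side="left")
        hi = np.searchsorted(snp_cm, gc + half, side="right")
        w = usable[lo:hi]
        if w.size > max_snps:
            w = np.sort(rng.choice(w, size=max_snps, replace=False))
        windows.append(w)
    return XpclrGrid(grid_pos, windows, spacing, window_cm)


def _escape_prob(s: float, r_d: np.ndarray, n_effective: float) -> np.ndarray:
    """Probability that a lineage at recombination fraction r_d escapes."""
    if s <= 0:
        return np.ones_like(r_d)
    duration = (2.0 / s) * np.log(max(2.0 * n_effective * s, 2.0))
    return 1.0 - np.exp(-r_d * duration)


def _haldane(cm: np.ndarray) -> np.ndarray:
    """cM distance -> recombination fraction via Haldane's map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.abs(cm) / 100.0))


def _mixture_loglik(k, n, centers, weights, var):
    """log E[Binom(k | n, p2)] with p2 ~ mixture of truncated Gaussians.

    ``centers``/``weights``: mixture components (arrays broadcastable to
    a common shape (..., n_comp)); boundary mass is collapsed to exact
    loss/fixation.  Quadrature over the open interval uses the density
    renormalized implicitly by accumulating interior + boundary masses.
    """
    sd = np.sqrt(var)[..., None]
    centers = np.asarray(centers)
    lo = stats.norm.cdf((0.0 - centers) / sd)
    hi = stats.norm.sf((1.0 - centers) / sd)
    # interior quadrature nodes: shape (..., n_comp, order)
    z = (_U[None, :] - centers[..., None]) / sd[..., None]
    dens = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sd[..., None])
    binom = stats.binom.pmf(k[..., None, None], n[..., None, None], _U[None, :])
    interior = (dens * binom * _W[None, :]).sum(axis=-1)
    at0 = np.where(k[..., None] == 0, 1.0, 0.0)
    at1 = np.where(k[..., None] == n[..., None], 1.0, 0.0)
    lik = (weights * (interior + lo * at0 + hi * at1)).sum(axis=-1)
    return np.log(np.maximum(lik, 1e-300))


def single_snp_loglik(
    k: int,
    n: int,
    p_ref: float,
    omega: float,
    s: float,
    distance_cm: float,
    n_effective: float = 1e4,
) -> tuple[float, float]:
    """(null, sweep) log-likelihood of observing k of n test alleles.

    ``p_ref`` must be strictly inside (0, 1); SNPs fixed in the
    reference carry no information and are skipped upstream.
    """
    if not 0.0 < p_ref < 1.0:
        raise ValueError("p_ref must be in (0, 1)")
    karr = np.array([k], dtype=np.float64)
    narr = np.array([n], dtype=np.float64)
    var = np.array([omega * p_ref * (1.0 - p_ref)])
    null = _mixture_loglik(
        karr, narr, np.array([[p_ref]]), np.array([[1.0]]), var
    )[0]
    c = float(_escape_prob(s, np.atleast_1d(_haldane(np.array([distance_cm]))), n_effective)[0])
    m_hitch = c * p_ref + (1.0 - c)  # coded allele rode the sweeping haplotype
    m_escape = c * p_ref
    sweep = _mixture_loglik(
        karr, narr,
        np.array([[m_hitch, m_escape]]),
        np.array([[p_ref, 1.0 - p_ref]]),
        var,
    )[0]
    return float(null), float(sweep)


def _window_logliks(k, n, p_ref, dist_cm, omega, s_grid, n_effective):
    """Null vector and sweep matrix (len(s_grid), n_snps) of log-likelihoods."""
    var = omega * p_ref * (1.0 - p_ref)
    null = _mixture_loglik(k, n, p_ref[:, None], np.ones((k.size, 1)), var)
    r_d = _haldane(dist_cm)
    sweep = np.empty((len(s_grid), k.size))
    for i, s in enumerate(s_grid):
        c = _escape_prob(float(s), r_d, n_effective)
        centers = np.stack([c * p_ref + (1.0 - c), c * p_ref], axis=-1)
        weights = np.stack([p_ref, 1.0 - p_ref], axis=-1)
        sweep[i] = _mixture_loglik(k, n, centers, weights, var)
    return null, sweep


def xpclr_score(
    k: np.ndarray,
    n: np.ndarray,
    p_ref: np.ndarray,
    dist_cm: np.ndarray,
    omega: float,
    s_grid: np.ndarray = DEFAULT_S_GRID,
    n_effective: float = 1e4,
) -> float:
    """2 * max_s [sum sweep loglik - sum null loglik], floored at 0."""
    ok = (p_ref > 0) & (p_ref < 1) & (n > 0)
    if not ok.any():
        return float("nan")
    null, sweep = _window_logliks(
        k[ok].astype(float), n[ok].astype(float), p_ref[ok], dist_cm[ok],
        omega, s_grid, n_effective,
    )
    lr = 2.0 * (sweep.sum(axis=1).max() - null.sum())
    return float(max(lr, 0.0))


def xpclr_scan(
    gm_test: GenotypeMatrix,
    gm_ref: GenotypeMatrix,
    gmap: GeneticMap,
    interval: tuple[int, int] | None = None,
    omega: float | None = None,
    spacing: int = 4000,
    window_cm: float = 0.1,
    max_snps: int = 200,
    min_maf: float = 1e-3,
    s_grid: np.ndarray = DEFAULT_S_GRID,
    n_effective: float = 1e4,
    seed: int = 0,
    level: str = "region",
    min_informative: int = 2,
) -> ScoreTrack:
    """XP-CLR scores on a physical grid across ``interval``.

    ``omega`` defaults to the method-of-moments estimate from all
    MAF-passing SNPs of the scanned panel.  Windows that are empty, or
    hold fewer than ``min_informative`` SNPs segregating in the
    reference, score NaN (a composite likelihood over very few SNPs is
    dominated by single-SNP drift outliers).
    """
    if [v.id for v in gm_test.variants] != [v.id for v in gm_ref.variants]:
        raise ValueError("test and reference panels must share the same variant set")
    pos = gm_test.positions()
    if interval is None:
        interval = (int(pos[0]), int(pos[-1]))

    called_t = gm_test.codes != MISSING
    n_t = called_t.sum(axis=0).astype(float)
    k_t = np.where(called_t, gm_test.codes, 0).sum(axis=0).astype(float)
    p_r = gm_ref.allele_frequency()

    # MAF filter on the pooled sample of both panels
    called_r = gm_ref.codes != MISSING
    n_r = called_r.sum(axis=0).astype(float)
    k_r = np.where(called_r, gm_ref.codes, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (k_t + k_r) / (2.0 * (n_t + n_r))
    pooled_maf = np.minimum(pooled, 1.0 - pooled)
    grid = build_grid(
        interval, gmap, gm_test, spacing, window_cm, max_snps, min_maf, seed, maf=pooled_maf
    )

    if omega is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            p_t = np.where(n_t > 0, k_t / (2 * n_t), np.nan)
        usable = np.concatenate(grid.windows) if grid.windows else np.array([], dtype=int)
        usable = np.unique(usable)
        omega = estimate_omega(
            p_t[usable], p_r[usable], min_snps=min(200, max(usable.size, 1)), robust=True
        ).omega

    snp_cm = np.atleast_1d(gmap.interpolate(pos.astype(np.float64)))
    grid_cm = np.atleast_1d(gmap.interpolate(grid.positions.astype(np.float64)))
    scores = np.full(grid.positions.size, np.nan)
    informative = (p_r > 0) & (p_r < 1)
    for g, window in enumerate(grid.windows):
        if window.size == 0 or informative[window].sum() < min_informative:
            continue
        scores[g] = xpclr_score(
            k_t[window], 2 * n_t[window], p_r[window],
            np.abs(snp_cm[window] - grid_cm[g]),
            omega, s_grid, n_effective,
        )
    chrom = gm_test.variants[0].chrom if gm_test.variants else "unknown"
    return ScoreTrack("xpclr", level, chrom, grid.positions, scores)
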
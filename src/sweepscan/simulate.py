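"""Synthetic structured panels: neutral background, regional hard sweep,
and a small 7-SNP gene fixture.

The neutral generator emulates a hierarchical sampling design of the
HGDP-CEPH kind — diploid samples nested in populations nested in
geographic regions — with a coalescent (msprime) under a star-like
demography: populations within a region split from a regional ancestor,
regional ancestors split from a common root, optionally with symmetric
migration among present-day demes.  Ancestral alleles are the
simulation's true ancestral states, so polarization is exact (a
configurable fraction can be masked "unknown" to exercise the removal
path).

The sweep generator overlays a hard selective sweep on one region by
forward-in-time Wright-Fisher resampling with selection at a single
site, conditioned on the derived allele reaching a target present-day
frequency.  Whole haplotypes are copied (with Poisson crossovers on the
genetic map), so hitchhiking of linked variation emerges mechanically.
Haplotypes outside the target region are untouched.

The gene fixture draws diploids from seven predefined haplotypes over
seven SNPs at configurable per-region frequencies.  One haplotype (the
"H1 analogue") uniquely carries the derived allele at two designated
SNPs, which are therefore in complete LD (D' = r^2 = 1) by
construction; the all-ancestral haplotype is the "H6 analogue".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    PopulationStructure,
    Variant,
)

__all__ = [
    "PanelConfig",
    "SweepConfig",
    "NeutralPanel",
    "SweepResult",
    "simulate_neutral_panel",
    "impose_sweep",
    "make_vkorc1_fixture",
    "simulate_carrier_haplotypes",
    "hgdp_like_config",
    "VKORC1_HAPLOTYPES",
    "VKORC1_REGIONAL_FREQUENCIES",
    "VKORC1_LD_PAIR",
]


@dataclass
class PanelConfig:
    """Study design of a synthetic panel.

    ``regions`` maps region name -> list of (population name, diploid
    sample size).  Split times are in generations before present;
    ``migration_rate`` is the per-generation migration probability
    between every pair of present-day demes.
    """

    regions: list[tuple[str, list[tuple[str, int]]]]
    sequence_length: float = 3e6
    mutation_rate: float = 6e-9
    recombination_rate: float = 2e-7
    effective_size: float = 4000.0
    region_split_time: float = 500.0
    population_split_time: float = 250.0
    migration_rate: float = 0.0
    ancestral_unknown_fraction: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("need at least one region")
        for _, pops in self.regions:
            for _, size in pops:
                if size < 1:
                    raise ValueError("population sizes must be >= 1")
        for rate in (self.mutation_rate, self.recombination_rate, self.migration_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")

    def structure(self) -> PopulationStructure:
        s2p: dict[str, str] = {}
        p2r: dict[str, str] = {}
        for region, pops in self.regions:
            for pop, size in pops:
                p2r[pop] = region
                for i in range(size):
                    s2p[f"{pop}_{i}"] = pop
        return PopulationStructure(s2p, p2r, [r for r, _ in self.regions])


@dataclass
class SweepConfig:
    """A hard sweep in one region.

    ``age`` is the number of generations since the sweep started (the
    forward simulation always runs for exactly this many generations,
    so recombination has a realistic amount of time to erode the swept
    haplotype).  The derived allele must cross ``target_frequency``
    within that window — overshooting it by more than
    ``frequency_tolerance`` at the crossing restarts the attempt — and
    is then held at the crossing frequency (recombination continues,
    the allele count is clamped) for the remaining generations.
    """

    region: str
    position: float
    s: float = 0.15
    target_frequency: float = 0.9
    dominance: float = 0.5
    age: int = 180
    forward_population: int = 3000  # diploids in the forward Wright-Fisher deme
    initial_copies: int = 15  # identical copies of the founder haplotype at onset
    frequency_tolerance: float = 0.03
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError("selection coefficient must be > 0")
        if not 0 < self.target_frequency <= 1:
            raise ValueError("target frequency must be in (0, 1]")


@dataclass
class NeutralPanel:
    panel: HaplotypePanel
    gmap: GeneticMap
    structure: PopulationStructure
    ancestral: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.panel, self.gmap, self.structure, self.ancestral))


@dataclass
class SweepResult:
    panel: HaplotypePanel
    site_index: int
    realized_frequency: float
    attempts: int
    generations: int


def simulate_neutral_panel(config: PanelConfig) -> NeutralPanel:
    """Coalescent-generated phased panel under the configured demography.

    Deterministic for a given config (same seed -> bit-identical
    output).  Raises if the simulation yields no variants.
    """
    import msprime

    rng = np.random.default_rng(config.seed)
    seed_anc, seed_mut = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))

    demography = msprime.Demography()
    leaf_names: list[str] = []
    for region, pops in config.regions:
        for pop, _ in pops:
            demography.add_population(name=pop, initial_size=config.effective_size)
            leaf_names.append(pop)
    multi_region = len(config.regions) > 1
    for region, pops in config.regions:
        demography.add_population(name=f"{region}__anc", initial_size=config.effective_size)
        demography.add_population_split(
            time=config.population_split_time,
            derived=[p for p, _ in pops],
            ancestral=f"{region}__anc",
        )
    if multi_region:
        demography.add_population(name="__root", initial_size=config.effective_size)
        demography.add_population_split(
            time=config.region_split_time,
            derived=[f"{r}__anc" for r, _ in config.regions],
            ancestral="__root",
        )
    if config.migration_rate > 0 and len(leaf_names) > 1:
        demography.set_symmetric_migration_rate(leaf_names, config.migration_rate)
    demography.sort_events()

    samples = [
        msprime.SampleSet(size, population=pop, ploidy=2)
        for _, pops in config.regions
        for pop, size in pops
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=config.sequence_length,
        recombination_rate=config.recombination_rate,
        random_seed=seed_anc,
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mutation_rate, model=msprime.BinaryMutationModel(), random_seed=seed_mut
    )
    if ts.num_sites == 0:
        raise ValueError(
            "simulation produced no variants; increase sequence_length or mutation_rate"
        )

    structure = config.structure()
    sample_names = list(structure.sample_to_population)
    geno = ts.genotype_matrix().T.astype(np.uint8)  # (2N, M)
    keep = [j for j, site in enumerate(ts.sites()) if len({m.derived_state for m in site.mutations} | {site.ancestral_state}) == 2]
    positions = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
    geno = geno[:, keep]
    positions = positions[keep]

    variants = [
        Variant(f"snp{j}", "chrS", int(positions[i]), ("A", "G"), "A")
        for i, j in enumerate(keep)
    ]
    ancestral = {v.id: "A" for v in variants}
    if config.ancestral_unknown_fraction > 0:
        n_mask = int(round(config.ancestral_unknown_fraction * len(variants)))
        masked = rng.choice(len(variants), size=n_mask, replace=False)
        for i in masked:
            ancestral[variants[i].id] = "unknown"

    sample_of_hap = [s for s in sample_names for _ in range(2)]
    panel = HaplotypePanel(geno, sample_of_hap, variants)
    gmap = GeneticMap.uniform(config.sequence_length, config.recombination_rate * 1e8)
    return NeutralPanel(
        panel, gmap, structure, ancestral,
        metadata={"seed": config.seed, "n_sites_raw": ts.num_sites},
    )


def _make_gamete(h1, h2, cm_morgans, total_morgans, rng, k=None, first=None):
    if k is None:
        k = rng.poisson(total_morgans)
    if first is None:
        first = int(rng.integers(2))
    if k == 0:
        return (h1 if first == 0 else h2).copy()
    xs = np.sort(rng.uniform(cm_morgans[0], cm_morgans[-1], size=k))
    cuts = np.searchsorted(cm_morgans, xs, side="right")
    gamete = np.empty_like(h1)
    src = (h1, h2)
    which = first
    prev = 0
    for c in np.concatenate([cuts, [h1.size]]):
        gamete[prev:c] = src[which][prev:c]
        which ^= 1
        prev = c
    return gamete


def _gamete_batch(pop, parent_idx, cm_m, total_m, rng):
    """One gamete per entry of ``parent_idx`` (diploid parent indices)."""
    B = parent_idx.size
    ks = rng.poisson(total_m, size=B)
    firsts = rng.integers(0, 2, size=B)
    out = np.empty((B, pop.shape[1]), dtype=pop.dtype)
    simple = ks == 0
    out[simple] = pop[2 * parent_idx[simple] + firsts[simple]]
    for i in np.nonzero(~simple)[0]:
        p = int(parent_idx[i])
        out[i] = _make_gamete(pop[2 * p], pop[2 * p + 1], cm_m, total_m, rng,
                              k=int(ks[i]), first=int(firsts[i]))
    return out


def impose_sweep(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    structure: PopulationStructure,
    sweep: SweepConfig,
    seed: int = 1,
) -> SweepResult:
    """Overlay a hard sweep on the target region of a neutral panel.

    The variant nearest ``sweep.position`` becomes the selected site.
    Within the region its derived allele is re-seeded on a single
    haplotype (a new mutation on an existing background) and the region
    is resampled forward in time under genic selection with free
    recombination per the genetic map, until the derived frequency
    crosses the target.  Attempts in which the allele is lost, the
    duration is exhausted, or the crossing overshoots the tolerance are
    restarted with a fresh seed.
    """
    if sweep.region not in structure.regions:
        raise ValueError(f"unknown region {sweep.region!r}")
    positions = panel.positions()
    if not positions[0] <= sweep.position <= positions[-1]:
        raise ValueError("selected-site position outside the simulated sequence")
    site = int(np.argmin(np.abs(positions - sweep.position)))

    rows = panel.haplotype_rows_of_samples(structure.samples_of_region(sweep.region))
    n_hap = rows.size
    n_dip = n_hap // 2
    cm_m = np.atleast_1d(gmap.interpolate(positions.astype(np.float64))) / 100.0
    total_m = float(cm_m[-1] - cm_m[0])
    h, s_coef = sweep.dominance, sweep.s

    master = np.random.default_rng(seed)
    base = panel.haplotypes[rows].copy()
    n_fwd = max(sweep.forward_population, (n_hap + 1) // 2)
    n_fwd_hap = 2 * n_fwd
    for attempt in range(1, sweep.max_attempts + 1):
        rng = np.random.default_rng(master.integers(1, 2**31 - 1))
        # expand the sampled region haplotypes into the forward deme and
        # seed the derived allele as a single new mutation
        hap0 = base.copy()
        hap0[:, site] = 0
        pop = hap0[rng.integers(0, n_hap, size=n_fwd_hap)]
        founders = rng.choice(n_fwd_hap, size=max(sweep.initial_copies, 1), replace=False)
        pop[founders] = pop[founders[0]]  # single origin: identical copies
        pop[founders, site] = 1
        crossed = False
        failed = False
        for _gen in range(1, sweep.age + 1):
            if not crossed:
                g = pop[0::2, site].astype(np.int64) + pop[1::2, site]
                w = 1.0 + np.where(g == 2, s_coef, 0.0) + np.where(g == 1, h * s_coef, 0.0)
                w /= w.sum()
                parents = rng.choice(n_fwd, size=n_fwd_hap, p=w)
                pop = _gamete_batch(pop, parents, cm_m, total_m, rng)
                freq = pop[:, site].mean()
                if freq == 0.0:
                    failed = True
                    break
                if freq >= sweep.target_frequency:
                    if freq > sweep.target_frequency + sweep.frequency_tolerance:
                        failed = True
                        break
                    crossed = True
                    k_derived = int(pop[:, site].sum())
            else:
                # frequency clamp: neutral resampling with the derived
                # allele count held fixed, recombination continuing
                need_d, need_a = k_derived, n_fwd_hap - k_derived
                got_d: list[np.ndarray] = []
                got_a: list[np.ndarray] = []
                have_d = have_a = 0
                while have_d < need_d or have_a < need_a:
                    batch = _gamete_batch(
                        pop, rng.integers(0, n_fwd, size=n_fwd_hap), cm_m, total_m, rng
                    )
                    der = batch[:, site] == 1
                    if have_d < need_d:
                        take = batch[der][: need_d - have_d]
                        got_d.append(take)
                        have_d += take.shape[0]
                    if have_a < need_a:
                        take = batch[~der][: need_a - have_a]
                        got_a.append(take)
                        have_a += take.shape[0]
                pop = np.concatenate(got_d + got_a, axis=0)
                rng.shuffle(pop, axis=0)
        if crossed and not failed:
            # draw the region sample back out, conditioned on the sample
            # frequency staying inside the tolerance band
            for _try in range(50):
                pick = rng.choice(n_fwd_hap, size=n_hap, replace=False)
                f_sample = pop[pick, site].mean()
                if abs(f_sample - sweep.target_frequency) <= sweep.frequency_tolerance:
                    break
            else:
                continue
            haps = panel.haplotypes.copy()
            haps[rows] = pop[pick]
            out = HaplotypePanel(haps, list(panel.sample_of_haplotype), list(panel.variants))
            return SweepResult(out, site, float(f_sample), attempt, sweep.age)
    raise RuntimeError(
        f"sweep conditioning failed after {sweep.max_attempts} attempts "
        f"(s={s_coef}, target={sweep.target_frequency})"
    )


# ------------------------------------------------------------------ fixture

# Seven haplotypes over seven SNPs (1 = derived).  The H1 analogue
# uniquely carries the derived allele at SNPs 0 and 2 (the designated
# complete-LD pair); the H6 analogue is all-ancestral.
VKORC1_HAPLOTYPES: dict[str, str] = {
    "H1": "1011000",
    "H2": "0000001",
    "H3": "0001000",
    "H4": "0001100",
    "H5": "0100000",
    "H6": "0000000",
    "H7": "0000010",
}

VKORC1_LD_PAIR: tuple[int, int] = (0, 2)

# per-region haplotype frequencies (each row sums to 1)
VKORC1_REGIONAL_FREQUENCIES: dict[str, dict[str, float]] = {
    "Africa": {"H1": 0.044, "H2": 0.40, "H3": 0.25, "H4": 0.12, "H5": 0.07, "H6": 0.11, "H7": 0.006},
    "MiddleEast": {"H1": 0.51, "H2": 0.20, "H3": 0.15, "H4": 0.08, "H5": 0.04, "H6": 0.015, "H7": 0.005},
    "Europe": {"H1": 0.51, "H2": 0.22, "H3": 0.14, "H4": 0.08, "H5": 0.03, "H6": 0.01, "H7": 0.01},
    "CentralSouthAsia": {"H1": 0.31, "H2": 0.30, "H3": 0.20, "H4": 0.12, "H5": 0.05, "H6": 0.015, "H7": 0.005},
    "EastAsia": {"H1": 0.896, "H2": 0.06, "H3": 0.034, "H4": 0.01, "H5": 0.0, "H6": 0.0, "H7": 0.0},
    "Oceania": {"H1": 0.28, "H2": 0.40, "H3": 0.20, "H4": 0.10, "H5": 0.02, "H6": 0.0, "H7": 0.0},
    "America": {"H1": 0.41, "H2": 0.30, "H3": 0.19, "H4": 0.08, "H5": 0.02, "H6": 0.0, "H7": 0.0},
}

_H952_REGION_SIZES = {
    "Africa": (105, 7),
    "MiddleEast": (163, 4),
    "Europe": (158, 8),
    "CentralSouthAsia": (202, 9),
    "EastAsia": (232, 17),
    "Oceania": (28, 2),
    "America": (64, 5),
}


def hgdp_like_config(scale: float = 1.0, seed: int = 1, **overrides) -> PanelConfig:
    """A 7-region / 52-population design with H952-like region sizes.

    ``scale`` shrinks sample sizes proportionally (minimum 1 diploid per
    population) for desk-scale runs.
    """
    regions = []
    for region, (total, n_pops) in _H952_REGION_SIZES.items():
        total = max(int(round(total * scale)), n_pops)
        base, extra = divmod(total, n_pops)
        pops = [
            (f"{region}_pop{i}", base + (1 if i < extra else 0)) for i in range(n_pops)
        ]
        regions.append((region, pops))
    return PanelConfig(regions=regions, seed=seed, **overrides)


def make_vkorc1_fixture(
    regional_frequencies: dict[str, dict[str, float]] | None = None,
    population_sizes: dict[str, list[tuple[str, int]]] | None = None,
    seed: int = 1,
):
    """Sample a 7-SNP diploid panel from predefined haplotype frequencies.

    Returns ``(genotypes, structure, truth, ancestral)`` where ``truth``
    records the generating per-region haplotype frequencies.
    """
    freqs = regional_frequencies or VKORC1_REGIONAL_FREQUENCIES
    labels = sorted(VKORC1_HAPLOTYPES)
    hap_vec = {k: np.array([int(c) for c in v], dtype=np.uint8) for k, v in VKORC1_HAPLOTYPES.items()}
    for region, f in freqs.items():
        total = sum(f.get(k, 0.0) for k in labels)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region {region!r} frequencies sum to {total}, not 1")
        if any(not 0 <= f.get(k, 0.0) <= 1 for k in labels):
            raise ValueError(f"region {region!r} has frequencies outside [0, 1]")

    if population_sizes is None:
        population_sizes = {}
        for region in freqs:
            total, n_pops = _H952_REGION_SIZES.get(region, (40, 2))
            base, extra = divmod(total, n_pops)
            population_sizes[region] = [
                (f"{region}_pop{i}", base + (1 if i < extra else 0)) for i in range(n_pops)
            ]

    rng = np.random.default_rng(seed)
    pos0 = 31_096_368  # promoter-analogue coordinate; spacing within a ~4 kb gene
    offsets = [0, 497, 1173, 1542, 2255, 3462, 4131]
    variants = [
        Variant(f"vk_snp{i + 1}", "chr16", pos0 + off, ("A", "G"), "A")
        for i, off in enumerate(offsets)
    ]

    samples: list[str] = []
    codes_rows: list[np.ndarray] = []
    s2p: dict[str, str] = {}
    p2r: dict[str, str] = {}
    for region, pops in population_sizes.items():
        p = np.array([freqs[region].get(k, 0.0) for k in labels])
        for pop, size in pops:
            p2r[pop] = region
            draws = rng.choice(len(labels), size=2 * size, p=p)
            for i in range(size):
                name = f"{pop}_{i}"
                samples.append(name)
                s2p[name] = pop
                h1 = hap_vec[labels[draws[2 * i]]]
                h2 = hap_vec[labels[draws[2 * i + 1]]]
                codes_rows.append((h1 + h2).astype(np.int8))
    gm = GenotypeMatrix(samples, variants, np.array(codes_rows, dtype=np.int8))
    structure = PopulationStructure(s2p, p2r, list(population_sizes))
    ancestral = {v.id: "A" for v in variants}
    truth = {region: dict(f) for region, f in freqs.items()}
    return gm, structure, truth, ancestral


# ------------------------------------------------------- carrier genealogies


def simulate_carrier_haplotypes(
    n_generations: int,
    n_haplotypes: int,
    marker_cm: np.ndarray,
    match_freq: np.ndarray,
    mu: float = 1e-6,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Carrier haplotypes descending from a common ancestor n generations ago.

    ``marker_cm``: genetic distances of markers outward on each side
    (same symmetric layout used for both sides).  Each descendant
    lineage accumulates crossovers as a Poisson process of rate
    ``n_generations`` per Morgan, so the retained ancestral segment ends
    at an Exp(n/100 per cM) distance; beyond it, marker alleles match
    the ancestral haplotype with probability ``match_freq``; retained
    markers mutate with probability 1-(1-mu)^n.

    Returns (left, right) 0/1 concordance matrices of shape
    (n_haplotypes, n_markers): 1 = carries the ancestral-haplotype
    allele at that marker.
    """
    rng = np.random.default_rng(seed)
    marker_cm = np.asarray(marker_cm, dtype=np.float64)
    out = []
    mut_p = 1.0 - (1.0 - mu) ** n_generations
    for _side in ("left", "right"):
        conc = np.ones((n_haplotypes, marker_cm.size), dtype=np.uint8)
        breaks = rng.exponential(scale=100.0 / n_generations, size=n_haplotypes)
        for i in range(n_haplotypes):
            drawn = marker_cm > breaks[i]
            conc[i, drawn] = rng.random(drawn.sum()) < match_freq[drawn]
            kept = ~drawn
            flips = rng.random(kept.sum()) < mut_p
            conc[i, kept] = np.where(flips, 0, 1)
        out.append(conc)
    return out[0], out[1]
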
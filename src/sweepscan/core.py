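"""Core domain types shared by every analysis stage.

Coordinate conventions: physical positions are 1-based inclusive (VCF
convention) throughout the library; only the BED writer converts to
0-based half-open intervals.  Genotype codes count copies of the
alternate allele — or of the derived allele once :func:`polarize` has
been applied.  Missing genotypes are stored as ``-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "Variant",
    "GenotypeMatrix",
    "HaplotypePanel",
    "GeneticMap",
    "PopulationStructure",
    "ScoreTrack",
    "PolarizationReport",
    "polarize",
]


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with optional ancestral-allele polarity.

    ``ancestral`` is one of the two alleles, or ``"unknown"`` when the
    outgroup consensus could not assign it (such variants are dropped
    from ancestral-dependent analyses by :func:`polarize`).
    """

    id: str
    chrom: str
    pos: int
    alleles: tuple[str, str]
    ancestral: str = "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1, got {self.pos}")
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError(f"{self.id}: need two distinct alleles, got {self.alleles}")
        if self.ancestral != "unknown" and self.ancestral not in self.alleles:
            raise ValueError(
                f"{self.id}: ancestral allele {self.ancestral!r} not among {self.alleles}"
            )

    @property
    def derived(self) -> str | None:
        """The non-ancestral allele, or None when polarity is unknown."""
        if self.ancestral == "unknown":
            return None
        return self.alleles[1] if self.ancestral == self.alleles[0] else self.alleles[0]


def _check_sorted(variants: Sequence[Variant]) -> None:
    last: tuple[str, int] | None = None
    seen: set[str] = set()
    for v in variants:
        if v.id in seen:
            raise ValueError(f"duplicated variant id {v.id!r}")
        seen.add(v.id)
        key = (v.chrom, v.pos)
        if last is not None and last[0] == v.chrom and v.pos <= last[1]:
            raise ValueError(
                f"variants not strictly increasing within chromosome at {v.id} ({v.chrom}:{v.pos})"
            )
        last = key


@dataclass
class GenotypeMatrix:
    """N samples x M variants of diploid allele counts in {0,1,2,-1}."""

    samples: list[str]
    variants: list[Variant]
    codes: np.ndarray  # shape (N, M), int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = len(self.samples), len(self.variants)
        if self.codes.shape != (n, m):
            raise ValueError(f"codes shape {self.codes.shape} != ({n}, {m})")
        if len(set(self.samples)) != n:
            raise ValueError("duplicated sample ids")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype codes outside {{0,1,2,{MISSING}}}")
        _check_sorted(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def allele_frequency(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Complete-case frequency of the coded allele, per variant.

        Monomorphic-by-missingness columns (no genotyped sample) yield NaN.
        """
        codes = self.codes if rows is None else self.codes[rows]
        called = codes != MISSING
        n_alleles = 2 * called.sum(axis=0)
        counts = np.where(called, codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, counts / np.maximum(n_alleles, 1), np.nan)

    def minor_allele_frequency(self, rows: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_frequency(rows)
        return np.minimum(p, 1.0 - p)

    def take_variants(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            codes=self.codes[:, idx],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = np.array([pos[s] for s in names], dtype=np.intp)
        return GenotypeMatrix(samples=list(names), variants=list(self.variants), codes=self.codes[rows])


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes: 2N rows x M variants, 1 = coded allele.

    After :func:`polarize` the coded allele is the derived allele, which
    is what every EHH-family statistic assumes.
    """

    haplotypes: np.ndarray  # (2N, M) uint8
    sample_of_haplotype: list[str]  # length 2N, two consecutive rows per sample
    variants: list[Variant]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        n_hap, m = self.haplotypes.shape
        if len(self.sample_of_haplotype) != n_hap:
            raise ValueError("sample_of_haplotype length mismatch")
        if n_hap % 2:
            raise ValueError("expected an even number of haplotype rows (two per sample)")
        counts: dict[str, int] = {}
        for s in self.sample_of_haplotype:
            counts[s] = counts.get(s, 0) + 1
        if any(c != 2 for c in counts.values()):
            raise ValueError("every sample must contribute exactly two haplotypes")
        if m != len(self.variants):
            raise ValueError("variant count mismatch")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        _check_sorted(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def samples(self) -> list[str]:
        return self.sample_of_haplotype[::2]

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def derived_frequency(self, rows: np.ndarray | None = None) -> np.ndarray:
        h = self.haplotypes if rows is None else self.haplotypes[rows]
        return h.mean(axis=0)

    def haplotype_rows_of_samples(self, names: Iterable[str]) -> np.ndarray:
        wanted = set(names)
        return np.array(
            [i for i, s in enumerate(self.sample_of_haplotype) if s in wanted], dtype=np.intp
        )

    def take_samples(self, names: Sequence[str]) -> "HaplotypePanel":
        rows = self.haplotype_rows_of_samples(names)
        return HaplotypePanel(
            haplotypes=self.haplotypes[rows],
            sample_of_haplotype=[self.sample_of_haplotype[i] for i in rows],
            variants=list(self.variants),
        )

    def take_variants(self, idx: np.ndarray | list[int]) -> "HaplotypePanel":
        idx = np.asarray(idx, dtype=np.intp)
        return HaplotypePanel(
            haplotypes=self.haplotypes[:, idx],
            sample_of_haplotype=list(self.sample_of_haplotype),
            variants=[self.variants[i] for i in idx],
        )

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse the two haplotypes of each sample into diploid codes."""
        h = self.haplotypes.astype(np.int8)
        codes = h[0::2] + h[1::2]
        return GenotypeMatrix(samples=self.samples, variants=list(self.variants), codes=codes)


@dataclass
class GeneticMap:
    """Monotone physical (bp) <-> genetic (cM) map, linearly interpolated.

    Queries beyond either end are extrapolated at the terminal interval
    rate so that statistics integrating genetic distance stay computable
    at chromosome ends.
    """

    positions: np.ndarray  # bp, strictly increasing
    cumulative: np.ndarray  # cM, non-decreasing
    rate: np.ndarray | None = None  # cM/Mb for the interval starting at each position

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.cumulative = np.asarray(self.cumulative, dtype=np.float64)
        if self.positions.ndim != 1 or self.positions.shape != self.cumulative.shape:
            raise ValueError("positions and cumulative must be 1-D arrays of equal length")
        if self.positions.size == 0:
            raise ValueError("empty genetic map")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative) < 0):
            raise ValueError("cumulative cM must be non-decreasing")
        if self.rate is None:
            # cM per Mb over each interval; last point repeats the final interval rate
            if self.positions.size == 1:
                self.rate = np.zeros(1)
            else:
                r = np.diff(self.cumulative) / np.diff(self.positions) * 1e6
                self.rate = np.append(r, r[-1])
        else:
            self.rate = np.asarray(self.rate, dtype=np.float64)
            if np.any(self.rate < 0):
                raise ValueError("negative recombination rate")

    @classmethod
    def uniform(cls, length_bp: float, rate_cm_per_mb: float) -> "GeneticMap":
        pos = np.array([1.0, float(length_bp)])
        return cls(pos, (pos - 1.0) * rate_cm_per_mb * 1e-6)

    def interpolate(self, pos) -> np.ndarray | float:
        """Genetic position in cM at physical position(s) ``pos``."""
        q = np.asarray(pos, dtype=np.float64)
        out = np.interp(q, self.positions, self.cumulative)
        if self.positions.size >= 2:
            left = q < self.positions[0]
            right = q > self.positions[-1]
            if np.any(left):
                r0 = (self.cumulative[1] - self.cumulative[0]) / (
                    self.positions[1] - self.positions[0]
                )
                out = np.where(left, self.cumulative[0] + (q - self.positions[0]) * r0, out)
            if np.any(right):
                r1 = (self.cumulative[-1] - self.cumulative[-2]) / (
                    self.positions[-1] - self.positions[-2]
                )
                out = np.where(right, self.cumulative[-1] + (q - self.positions[-1]) * r1, out)
        if np.isscalar(pos):
            return float(out)
        return out


@dataclass
class PopulationStructure:
    """Three-level sample -> population -> region assignment."""

    sample_to_population: dict[str, str]
    population_to_region: dict[str, str]
    regions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = {
            p for p in self.sample_to_population.values() if p not in self.population_to_region
        }
        if missing:
            raise ValueError(f"populations without a region: {sorted(missing)}")
        if not self.regions:
            seen: list[str] = []
            for r in self.population_to_region.values():
                if r not in seen:
                    seen.append(r)
            self.regions = seen
        else:
            unknown = set(self.population_to_region.values()) - set(self.regions)
            if unknown:
                raise ValueError(f"regions not in configured region list: {sorted(unknown)}")

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_population)

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.sample_to_population.values():
            if p not in seen:
                seen.append(p)
        return seen

    def region_of_sample(self, sample: str) -> str:
        return self.population_to_region[self.sample_to_population[sample]]

    def samples_of_population(self, population: str) -> list[str]:
        return [s for s, p in self.sample_to_population.items() if p == population]

    def samples_of_region(self, region: str) -> list[str]:
        return [s for s in self.sample_to_population if self.region_of_sample(s) == region]

    def populations_of_region(self, region: str) -> list[str]:
        return [p for p in self.populations if self.population_to_region[p] == region]

    def check_samples(self, samples: Iterable[str]) -> None:
        absent = [s for s in samples if s not in self.sample_to_population]
        if absent:
            raise ValueError(f"samples missing from population table: {absent}")


@dataclass
class ScoreTrack:
    """Per-locus statistic values (and optional empirical p-values)."""

    test: str
    level: str
    chrom: str
    pos: np.ndarray
    score: np.ndarray  # NaN marks undefined / invalid scores
    ids: list[str] | None = None
    p: np.ndarray | None = None
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.score = np.asarray(self.score, dtype=np.float64)
        if self.pos.shape != self.score.shape:
            raise ValueError("pos and score length mismatch")
        if np.any(np.diff(self.pos) < 0):
            raise ValueError("track positions must be sorted")
        if self.p is not None:
            self.p = np.asarray(self.p, dtype=np.float64)
            ok = np.isnan(self.p) | ((self.p > 0) & (self.p <= 1))
            if not ok.all():
                raise ValueError("p-values must lie in (0, 1]")
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=np.float64)

    def __len__(self) -> int:
        return self.pos.size

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.score)

    def to_dataframe(self):
        import pandas as pd

        d = {"chrom": self.chrom, "pos": self.pos, "score": self.score}
        if self.ids is not None:
            d["id"] = self.ids
        if self.maf is not None:
            d["maf"] = self.maf
        if self.p is not None:
            d["p"] = self.p
        df = pd.DataFrame(d)
        df["test"] = self.test
        df["level"] = self.level
        return df


@dataclass
class PolarizationReport:
    """Variants excluded from the polarized set, with the reason."""

    removed: list[tuple[str, str]] = field(default_factory=list)  # (variant id, reason)
    n_flipped: int = 0

    @property
    def removed_ids(self) -> list[str]:
        return [i for i, _ in self.removed]


def polarize(data, ancestral: Mapping[str, str]):
    """Recode so that counts refer to the derived allele.

    Variants whose ancestral state is unknown, or whose tabulated
    ancestral base is not one of the two observed alleles, are removed
    from the returned object and listed in the report.  The input is not
    modified, so the unpolarized copy stays available for analyses that
    only need allele frequencies.

    Returns ``(polarized, report)`` where ``polarized`` has the same
    type as ``data`` (GenotypeMatrix or HaplotypePanel).
    """
    if isinstance(data, GenotypeMatrix):
        matrix, flip_hi = True, 2
    elif isinstance(data, HaplotypePanel):
        matrix, flip_hi = False, 1
    else:
        raise TypeError(f"cannot polarize {type(data).__name__}")

    report = PolarizationReport()
    keep: list[int] = []
    new_variants: list[Variant] = []
    flip: list[bool] = []
    for j, v in enumerate(data.variants):
        anc = ancestral.get(v.id, v.ancestral)
        if anc == "unknown" or anc is None:
            report.removed.append((v.id, "unknown"))
            continue
        if anc not in v.alleles:
            report.removed.append((v.id, "ancestral-not-observed"))
            continue
        keep.append(j)
        flip.append(anc == v.alleles[1])
        new_variants.append(replace(v, ancestral=anc))

    flip_arr = np.array(flip, dtype=bool)
    report.n_flipped = int(flip_arr.sum())
    if matrix:
        codes = data.codes[:, keep].copy()
        miss = codes == MISSING
        codes[:, flip_arr] = flip_hi - codes[:, flip_arr]
        codes[miss] = MISSING
        return GenotypeMatrix(list(data.samples), new_variants, codes), report
    haps = data.haplotypes[:, keep].copy()
    haps[:, flip_arr] = 1 - haps[:, flip_arr]
    return (
        HaplotypePanel(haps, list(data.sample_of_haplotype), new_variants),
        report,
    )
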
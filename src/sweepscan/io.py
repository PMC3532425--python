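"""Readers and writers for the tabular and VCF formats the toolkit touches.

All tabular formats are plain tab-separated text with a header row.
VCF parsing goes through cyvcf2; writing uses a minimal VCFv4.2 emitter
sufficient for biallelic SNPs with optional phased genotypes.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    PopulationStructure,
    ScoreTrack,
    Variant,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_haplotypes",
    "write_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "read_population_table",
    "write_population_table",
    "read_ancestral_table",
    "write_ancestral_table",
    "read_scores",
    "write_scores",
]

_GT_HEADER = ["id", "chrom", "pos", "ref", "alt", "ancestral"]


def _is_vcf(path) -> bool:
    name = str(path)
    return name.endswith(".vcf") or name.endswith(".vcf.gz")


# ---------------------------------------------------------------- genotypes


def _variants_from_vcf(path, require_phased: bool):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants: list[Variant] = []
    codes_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    n_rejected = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_rejected += 1
            continue
        anc = "unknown"
        aa = rec.INFO.get("AA")
        if aa:
            anc = str(aa).upper()
        try:
            v = Variant(rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS,
                        (rec.REF, rec.ALT[0]), anc if anc in (rec.REF, rec.ALT[0]) else "unknown")
        except ValueError as exc:
            raise ValueError(f"malformed VCF record at {rec.CHROM}:{rec.POS}: {exc}") from exc
        variants.append(v)
        gts = rec.gt_types  # 0=hom ref, 1=het, 2=hom alt, 3=unknown (gts012)
        row = np.where(gts == 3, MISSING, gts).astype(np.int8)
        codes_rows.append(row)
        if require_phased:
            g = np.asarray(rec.genotypes, dtype=object)
            phased = np.array([bool(x[-1]) for x in g])
            alleles = np.array([[x[0], x[1]] for x in g], dtype=np.int16)
            if np.any(alleles < 0):
                raise ValueError(
                    f"missing genotype at {rec.CHROM}:{rec.POS}: phased panels must be complete"
                )
            het = alleles[:, 0] != alleles[:, 1]
            if np.any(het & ~phased):
                raise ValueError(
                    f"unphased heterozygote at {rec.CHROM}:{rec.POS}: cannot build haplotypes"
                )
            hap_rows.append(alleles.reshape(-1).astype(np.uint8))
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} non-biallelic-SNP VCF records", stacklevel=3)
    return samples, variants, codes_rows, hap_rows


def read_genotypes(path) -> GenotypeMatrix:
    """Read diploid genotypes from VCF or the TSV genotype dialect.

    The TSV dialect has one row per variant with columns
    id/chrom/pos/ref/alt/ancestral followed by one column per sample
    holding 0/1/2/NA alternate-allele counts.
    """
    if _is_vcf(path):
        samples, variants, codes_rows, _ = _variants_from_vcf(path, require_phased=False)
        codes = (
            np.array(codes_rows, dtype=np.int8).T
            if codes_rows
            else np.zeros((len(samples), 0), dtype=np.int8)
        )
        return GenotypeMatrix(samples, variants, codes)

    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:6]) != _GT_HEADER:
        raise ValueError(f"genotype TSV must start with columns {_GT_HEADER}, got {list(df.columns[:6])}")
    samples = list(df.columns[6:])
    variants = []
    for i, row in df.iterrows():
        try:
            variants.append(
                Variant(row["id"], row["chrom"], int(row["pos"]), (row["ref"], row["alt"]),
                        row["ancestral"] if isinstance(row["ancestral"], str) else "unknown")
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed genotype record at line {i + 2}: {exc}") from exc
    body = df[samples].to_numpy(dtype=object)
    codes = np.full(body.shape, MISSING, dtype=np.int8)
    for val, code in (("0", 0), ("1", 1), ("2", 2)):
        codes[body == val] = code
    bad = ~np.isin(body, ("0", "1", "2", "NA", "nan")) & ~pd.isna(body)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"malformed genotype code {body[i, j]!r} at line {i + 2} (sample {samples[j]})"
        )
    return GenotypeMatrix(samples, variants, codes.T)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the TSV genotype dialect (round-trips with read_genotypes)."""
    rows = []
    for j, v in enumerate(gm.variants):
        col = gm.codes[:, j]
        rows.append(
            [v.id, v.chrom, v.pos, v.alleles[0], v.alleles[1], v.ancestral]
            + ["NA" if c == MISSING else str(int(c)) for c in col]
        )
    pd.DataFrame(rows, columns=_GT_HEADER + list(gm.samples)).to_csv(path, sep="\t", index=False)


def read_haplotypes(path) -> HaplotypePanel:
    """Read a phased panel from a VCF (all heterozygotes must be phased)."""
    if not _is_vcf(path):
        raise ValueError("phased panels are read from VCF")
    samples, variants, _, hap_rows = _variants_from_vcf(path, require_phased=True)
    if hap_rows:
        haps = np.array(hap_rows, dtype=np.uint8).T
    else:
        haps = np.zeros((2 * len(samples), 0), dtype=np.uint8)
    sample_of_hap = [s for s in samples for _ in range(2)]
    return HaplotypePanel(haps, sample_of_hap, variants)


def write_vcf(data, path, phased: bool | None = None) -> None:
    """Write a GenotypeMatrix or HaplotypePanel as an uncompressed VCF."""
    if isinstance(data, HaplotypePanel):
        samples = data.samples
        phased = True
    else:
        samples = data.samples
        phased = False
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({v.chrom for v in data.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, v in enumerate(data.variants):
            info = f"AA={v.ancestral}" if v.ancestral != "unknown" else "."
            if phased:
                col = data.haplotypes[:, j]
                gts = [f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(samples))]
            else:
                col = data.codes[:, j]
                lut = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [lut[int(c)] for c in col]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.alleles[0]}\t{v.alleles[1]}\t.\t.\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------- genetic map


def read_genetic_map(path) -> GeneticMap:
    """Read a HapMap-style genetic map TSV.

    Expected columns (header required): position, rate_cM_Mb, cM; an
    optional leading chrom column is accepted.
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) >= 4 and not cols[0].startswith("pos"):
        df = df.iloc[:, 1:4]
    else:
        df = df.iloc[:, 0:3]
    pos = df.iloc[:, 0].to_numpy(dtype=np.float64)
    rate = df.iloc[:, 1].to_numpy(dtype=np.float64)
    cm = df.iloc[:, 2].to_numpy(dtype=np.float64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("genetic map positions must be strictly increasing")
    return GeneticMap(pos, cm, rate)


def write_genetic_map(gmap: GeneticMap, path, chrom: str = "chr1") -> None:
    pd.DataFrame(
        {
            "chrom": chrom,
            "position": gmap.positions.astype(np.int64),
            "rate_cM_Mb": gmap.rate,
            "cM": gmap.cumulative,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- tables


def read_population_table(path, regions: list[str] | None = None) -> PopulationStructure:
    """Read the sample/population/region TSV into a PopulationStructure.

    ``regions`` optionally fixes the allowed region list; labels outside
    it are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample", "population", "region"}
    if not need.issubset(df.columns):
        raise ValueError(f"population table must have columns {sorted(need)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample rows: {dups}")
    s2p = dict(zip(df["sample"], df["population"]))
    p2r: dict[str, str] = {}
    for p, r in zip(df["population"], df["region"]):
        if p in p2r and p2r[p] != r:
            raise ValueError(f"population {p!r} assigned to two regions")
        p2r[p] = r
    return PopulationStructure(s2p, p2r, regions or [])


def write_population_table(structure: PopulationStructure, path) -> None:
    rows = [
        (s, p, structure.population_to_region[p])
        for s, p in structure.sample_to_population.items()
    ]
    pd.DataFrame(rows, columns=["sample", "population", "region"]).to_csv(
        path, sep="\t", index=False
    )


def read_ancestral_table(path) -> dict[str, str]:
    """snp_id -> ancestral base ("unknown" rows allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "ancestral_base"}.issubset(df.columns):
        raise ValueError("ancestral table must have columns snp_id, ancestral_base")
    if df["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id rows in ancestral table")
    return dict(zip(df["snp_id"], df["ancestral_base"]))


def write_ancestral_table(table: dict[str, str], path) -> None:
    pd.DataFrame(sorted(table.items()), columns=["snp_id", "ancestral_base"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- score tracks


def write_scores(track: ScoreTrack, path, format: str = "tsv") -> None:
    """Write a ScoreTrack as TSV, or BED (0-based half-open intervals)."""
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            {
                "chrom": track.chrom,
                "pos": track.pos,
                "id": track.ids if track.ids is not None else ["."] * len(track),
                "score": track.score,
                "maf": track.maf if track.maf is not None else np.nan,
                "p": track.p if track.p is not None else np.nan,
                "test": track.test,
                "level": track.level,
            }
        )
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "bed":
        with open(path, "w") as fh:
            for i in range(len(track)):
                name = track.ids[i] if track.ids is not None else "."
                fh.write(
                    f"{track.chrom}\t{track.pos[i] - 1}\t{track.pos[i]}\t{name}\t{track.score[i]:.6g}\n"
                )
    else:
        raise ValueError(f"unknown score format {format!r}")


def read_scores(path) -> ScoreTrack:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    p = df["p"].to_numpy() if df["p"].notna().any() else None
    maf = df["maf"].to_numpy() if df["maf"].notna().any() else None
    return ScoreTrack(
        test=str(df["test"].iloc[0]) if len(df) else "unknown",
        level=str(df["level"].iloc[0]) if len(df) else "unknown",
        chrom=str(df["chrom"].iloc[0]) if len(df) else "unknown",
        pos=df["pos"].to_numpy(dtype=np.int64),
        score=df["score"].to_numpy(dtype=np.float64),
        ids=[str(x) for x in df["id"]] if len(df) else [],
        p=p,
        maf=maf,
    )
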
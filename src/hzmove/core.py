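"""Shared data containers and file formats.

The substrate of every analysis is a biallelic genotype matrix (individuals x
loci, dosages 0/1/2 of the counted allele, -1 for missing) with a population
assignment per individual, plus a population table carrying coordinates and a
three-way group label (speciesA = southern parental, hybrid = hybrid zone,
speciesB = northern parental).  Genotypes round-trip through plain 0/1/2 TSV
and minimal biallelic VCF; phased haplotypes are retained when available
because the two-locus disequilibrium statistics are gametic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("speciesA", "hybrid", "speciesB")

MISSING = -1


class ConfigurationError(ValueError):
    """Invalid analysis or generator configuration."""


class ValidationError(ValueError):
    """Input data violates a documented precondition."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci dosage matrix.

    Parameters
    ----------
    genotypes
        int array of shape (n_individuals, n_loci); values in {0, 1, 2} or
        ``MISSING`` (-1).  Dosage counts the "B" (speciesB-associated) allele
        wherever the generator or caller fixes an orientation.
    individuals, loci
        Identifier lists matching the two axes.
    pops
        Population id per individual (length n_individuals).
    haplotypes
        Optional phased array (n_individuals, 2, n_loci) with values {0, 1};
        when present, ``haplotypes.sum(axis=1)`` must equal ``genotypes``
        at non-missing entries.
    """

    genotypes: np.ndarray
    individuals: list[str]
    loci: list[str]
    pops: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pops = np.asarray(self.pops, dtype=object)
        n, m = self.genotypes.shape
        if len(self.individuals) != n:
            raise ValidationError("individual ids do not match genotype rows")
        if len(self.loci) != m:
            raise ValidationError("locus ids do not match genotype columns")
        if self.pops.shape[0] != n:
            raise ValidationError("population assignment length mismatch")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValidationError("genotype dosages must be 0/1/2 or -1")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (n, 2, m):
                raise ValidationError("haplotype array shape mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def pop_mask(self, pop_ids) -> np.ndarray:
        return np.isin(self.pops, list(pop_ids))

    def subset(self, individual_mask=None, locus_ids=None) -> "GenotypeMatrix":
        gm = self
        if individual_mask is not None:
            idx = np.asarray(individual_mask)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
            gm = GenotypeMatrix(
                gm.genotypes[idx],
                [gm.individuals[i] for i in idx],
                gm.loci,
                gm.pops[idx],
                None if gm.haplotypes is None else gm.haplotypes[idx],
            )
        if locus_ids is not None:
            pos = [gm.loci.index(l) for l in locus_ids]
            gm = GenotypeMatrix(
                gm.genotypes[:, pos],
                gm.individuals,
                [gm.loci[i] for i in pos],
                gm.pops,
                None if gm.haplotypes is None else gm.haplotypes[:, :, pos],
            )
        return gm

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        """Write loci-as-rows 0/1/2 TSV with 'NA' for missing."""
        df = pd.DataFrame(
            self.genotypes.T.astype(object), index=self.loci, columns=self.individuals
        )
        df = df.mask(df == MISSING, "NA")
        df.index.name = "locus"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, pops: dict[str, str] | pd.Series) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        geno = df.to_numpy(dtype=float).T
        geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
        individuals = list(df.columns)
        pop_arr = np.array([pops[i] for i in individuals], dtype=object)
        return cls(geno, individuals, list(df.index.astype(str)), pop_arr)

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal biallelic VCF (GT only; '|' separators if phased)."""
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.individuals),
        ]
        phased = self.haplotypes is not None
        sep = "|" if phased else "/"
        for j, locus in enumerate(self.loci):
            calls = []
            for i in range(self.n_individuals):
                g = self.genotypes[i, j]
                if g == MISSING:
                    calls.append(f".{sep}.")
                elif phased:
                    a, b = self.haplotypes[i, :, j]
                    calls.append(f"{a}|{b}")
                else:
                    calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(g)])
            lines.append(f"1\t{j + 1}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_vcf(cls, path: str | Path, pops: dict[str, str] | pd.Series) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        individuals = list(vcf.samples)
        loci: list[str] = []
        rows = []
        haps = []
        phased_all = True
        for var in vcf:
            loci.append(var.ID or f"{var.CHROM}:{var.POS}")
            gts = np.array(var.genotypes, dtype=object)  # (n, 3): a, b, phased
            a = np.array([g[0] for g in gts])
            b = np.array([g[1] for g in gts])
            phased_all &= all(bool(g[2]) for g in gts)
            dose = np.where((a < 0) | (b < 0), MISSING, a + b)
            rows.append(dose)
            haps.append(np.stack([np.maximum(a, 0), np.maximum(b, 0)], axis=0))
        geno = np.array(rows, dtype=np.int8).T
        hap_arr = None
        if phased_all and not (geno == MISSING).any():
            hap_arr = np.stack(haps, axis=-1).transpose(1, 0, 2).astype(np.int8)
        pop_arr = np.array([pops[i] for i in individuals], dtype=object)
        return cls(geno, individuals, loci, pop_arr, hap_arr)


# --------------------------------------------------------------- populations
POP_COLUMNS = ["pop_id", "lat", "lon", "group"]


def validate_populations(pops: pd.DataFrame) -> pd.DataFrame:
    """Check a population table (pop_id, lat, lon, group[, distance_km])."""
    missing = [c for c in POP_COLUMNS if c not in pops.columns]
    if missing:
        raise ValidationError(f"population table missing columns: {missing}")
    if pops["pop_id"].duplicated().any():
        raise ValidationError("duplicate pop_id")
    if (pops["lat"].abs() > 90).any() or (pops["lon"].abs() > 180).any():
        raise ValidationError("coordinates outside valid lat/lon ranges")
    bad = set(pops["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels: {sorted(bad)}")
    return pops


def read_populations(path: str | Path) -> pd.DataFrame:
    return validate_populations(pd.read_csv(path))


def write_populations(pops: pd.DataFrame, path: str | Path) -> None:
    pops.to_csv(path, index=False)


TRAIT_COLUMNS = ["pop_id", "trait", "mean", "sd", "n"]


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trait table missing columns: {missing}")
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=False)
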
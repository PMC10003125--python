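"""Core genotype containers: SNP panel metadata and the individuals x SNPs dosage matrix.

Genotypes are stored as counts of the *effect allele* (the allele declared a
priori to promote the phenotype), coded 0/1/2, with ``MISSING`` (-1) marking a
failed or absent genotype call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpInfo:
    """Metadata for one biallelic SNP on the candidate panel."""

    snp_id: str
    chrom: str
    pos: int  # 1-based, VCF convention; build label is opaque metadata
    effect_allele: str
    other_allele: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be 1-based positive")


@dataclass(frozen=True)
class PanelMetadata:
    """Ordered collection of SNPs genotyped on the panel."""

    snps: tuple[SnpInfo, ...]

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in panel")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def __len__(self) -> int:
        return len(self.snps)

    def __getitem__(self, snp_id: str) -> SnpInfo:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chrom": [s.chrom for s in self.snps],
                "pos": [s.pos for s in self.snps],
                "effect_allele": [s.effect_allele for s in self.snps],
                "other_allele": [s.other_allele for s in self.snps],
            }
        )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele counts.

    ``codes`` is an int8 array with values in {0, 1, 2, MISSING}. Rows follow
    ``sample_ids``; columns follow ``panel.snp_ids``.
    """

    codes: np.ndarray
    sample_ids: list[str]
    panel: PanelMetadata
    population: np.ndarray = field(default=None)  # per-individual population label codes

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x SNPs)")
        n, m = self.codes.shape
        if n != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if m != len(self.panel):
            raise ValueError("column count does not match panel")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"invalid genotype codes at {np.argwhere(bad)[:5].tolist()}")
        if self.population is None:
            self.population = np.zeros(n, dtype=np.int64)
        else:
            self.population = np.asarray(self.population, dtype=np.int64)
            if self.population.shape != (n,):
                raise ValueError("population labels must be one per individual")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return self.panel.snp_ids

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_ids.index(snp_id)
        return self.codes[:, j]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        sub_panel = PanelMetadata(tuple(self.panel.snps[i] for i in idx))
        return GenotypeMatrix(
            self.codes[:, idx].copy(), list(self.sample_ids), sub_panel, self.population.copy()
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = [sid for sid, keep in zip(self.sample_ids, mask) if keep]
        return GenotypeMatrix(self.codes[mask].copy(), ids, self.panel, self.population[mask].copy())

    def complete_cases(self) -> np.ndarray:
        """Boolean mask of individuals with no missing genotype on the panel."""
        return ~(self.codes == MISSING).any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=self.snp_ids, index=self.sample_ids)
        return df.replace(MISSING, pd.NA)
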
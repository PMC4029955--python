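"""Core data containers for the selection-scan pipeline.

Variants are kept 1-based (VCF convention); windows, BED intervals and
aggregation regions are 0-based half-open.  Allele coding throughout is
0 = ancestral, 1 = derived; where the ancestral state is unknown the REF
allele is stored in the ``ancestral`` slot and the variant is flagged
``ancestral_known = False`` so that polarity-dependent statistics (iHS)
can exclude it while polarity-free ones (PBS, XP-EHH) keep it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = [
    "chrom",
    "pos_bp",
    "snp_id",
    "ancestral",
    "derived",
    "gmap_cM",
    "ancestral_known",
]

#: dosage sentinel for a missing diploid genotype
MISSING = -1

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_snps",
    "stat",
    "bin",
    "percentile",
    "top1",
    "top5",
    "excluded_by_outgroup",
]


def validate_variants(variants: pd.DataFrame, require_gmap: bool = False) -> pd.DataFrame:
    """Check the invariants of a variant table and return it unchanged.

    Positions must be strictly increasing and genetic positions
    non-decreasing within each chromosome; ancestral and derived alleles
    must differ at every site.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table lacks columns: {missing}")
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
        g = sub["gmap_cM"].to_numpy(dtype=float)
        if require_gmap and np.any(np.isnan(g)):
            raise ValueError(f"genetic positions missing on {chrom}")
        if not np.all(np.isnan(g)) and np.any(np.diff(g[~np.isnan(g)]) < 0):
            raise ValueError(f"genetic positions decrease on {chrom}")
    same = variants["ancestral"] == variants["derived"]
    if same.any():
        bad = variants.loc[same, "snp_id"].iloc[0]
        raise ValueError(f"ancestral equals derived allele at {bad}")
    return variants


@dataclass
class GenotypeMatrix:
    """Diploid derived-allele dosages with explicit missingness.

    ``dosage`` has shape (n_variants, n_samples) with values in
    {0, 1, 2, MISSING}.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        validate_variants(self.variants)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.variants.iloc[index].reset_index(drop=True),
            list(self.samples),
            self.dosage[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.variants.copy(),
            [self.samples[i] for i in index],
            self.dosage[:, index],
        )

    def allele_freq(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        """Derived-allele frequency per variant, ignoring missing calls."""
        d = self.dosage if sample_index is None else self.dosage[:, sample_index]
        obs = d != MISSING
        n_chrom = 2 * obs.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(d == MISSING, 0, d).sum(axis=1) / np.where(
                n_chrom > 0, n_chrom, np.nan
            )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (0 ancestral, 1 derived), no missing data.

    ``alleles`` has shape (n_variants, n_haplotypes); haplotype ids are
    ``<sample>|0`` and ``<sample>|1`` in sample order.
    """

    variants: pd.DataFrame
    haplotype_ids: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if len(self.haplotype_ids) % 2 != 0:
            raise ValueError("haplotype count must be even (diploid panel)")
        if self.alleles.shape != (len(self.variants), len(self.haplotype_ids)):
            raise ValueError("allele matrix shape mismatch")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be 0/1")
        validate_variants(self.variants)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def sample_ids(self) -> list[str]:
        return [h.rsplit("|", 1)[0] for h in self.haplotype_ids[::2]]

    def haplotype_index_for_samples(self, samples: list[str]) -> np.ndarray:
        """Column indices of both haplotypes of each named sample."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = []
        for s in samples:
            if s not in pos:
                raise KeyError(f"sample {s!r} not in panel")
            idx.extend((2 * pos[s], 2 * pos[s] + 1))
        return np.asarray(idx, dtype=int)

    def take_variants(self, index: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            self.variants.iloc[index].reset_index(drop=True),
            list(self.haplotype_ids),
            self.alleles[index],
        )

    def take_haplotypes(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        return HaplotypePanel(
            self.variants.copy(),
            [self.haplotype_ids[i] for i in index],
            self.alleles[:, index],
        )

    def to_genotypes(self) -> GenotypeMatrix:
        dosage = (self.alleles[:, 0::2] + self.alleles[:, 1::2]).astype(np.int8)
        return GenotypeMatrix(self.variants.copy(), self.sample_ids, dosage)

    def derived_freq(self, hap_index: np.ndarray | None = None) -> np.ndarray:
        a = self.alleles if hap_index is None else self.alleles[:, hap_index]
        return a.mean(axis=1)


def make_sample_info(
    sample_ids: list[str],
    populations: list[str],
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Build a sample→population(/group) label table."""
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": populations,
            "group": groups if groups is not None else populations,
        }
    )


def population_index(labels: pd.DataFrame, samples: list[str], population: str) -> np.ndarray:
    """Indices into ``samples`` of members of ``population`` (by population
    label, falling back to group label)."""
    members = set(labels.loc[labels["population"] == population, "sample_id"])
    if not members:
        members = set(labels.loc[labels["group"] == population, "sample_id"])
    if not members:
        raise KeyError(f"unknown population label {population!r}")
    return np.asarray([i for i, s in enumerate(samples) if s in members], dtype=int)


def empty_window_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "n_snps": pd.Series(dtype=np.int64),
            "stat": pd.Series(dtype=float),
            "bin": pd.Series(dtype=np.int64),
            "percentile": pd.Series(dtype=float),
            "top1": pd.Series(dtype=bool),
            "top5": pd.Series(dtype=bool),
            "excluded_by_outgroup": pd.Series(dtype=bool),
        }
    )
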
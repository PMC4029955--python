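"""Readers and writers for the pipeline's file formats.

VCF parsing goes through cyvcf2; everything else is plain TSV/BED.  The
phased-VCF reader enforces the contracts the scans rely on: biallelic
sites, phased genotypes, no missing alleles, and an ancestral-allele
annotation (INFO/AA or a side table) that decides polarity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    WINDOW_COLUMNS,
    GenotypeMatrix,
    HaplotypePanel,
    empty_window_table,
    validate_variants,
)


def read_phased_vcf(path, ancestral: dict[str, str] | None = None) -> HaplotypePanel:
    """Read a phased, biallelic VCF into a haplotype panel.

    Alleles are recoded so 1 = derived.  The ancestral allele is taken from
    INFO/AA, overridden by the optional ``ancestral`` side table
    (snp_id → allele).  Sites whose annotated ancestral allele matches
    neither REF nor ALT (or is absent) keep REF-coding and are flagged
    ``ancestral_known = False``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    haps = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic site at {rec.CHROM}:{rec.POS} ({rec.ID}); "
                "split or filter before loading"
            )
        gt = np.asarray(rec.genotypes, dtype=object)
        phased = np.asarray([g[-1] for g in rec.genotypes], dtype=bool)
        if not phased.all():
            bad = samples[int(np.flatnonzero(~phased)[0])]
            raise ValueError(
                f"unphased genotype for sample {bad} at {rec.CHROM}:{rec.POS}"
            )
        alleles = np.asarray([g[:2] for g in rec.genotypes], dtype=np.int64).reshape(-1)
        if (alleles < 0).any():
            raise ValueError(f"missing allele at {rec.CHROM}:{rec.POS}")
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        aa = None
        if ancestral is not None and snp_id in ancestral:
            aa = ancestral[snp_id]
        else:
            info_aa = rec.INFO.get("AA")
            if info_aa is not None:
                aa = str(info_aa).upper()
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if aa == ref:
            anc, der, known, flip = ref, alt, True, False
        elif aa == alt:
            anc, der, known, flip = alt, ref, True, True
        else:
            anc, der, known, flip = ref, alt, False, False
        if flip:
            alleles = 1 - alleles
        rows.append(
            {
                "chrom": str(rec.CHROM),
                "pos_bp": int(rec.POS),
                "snp_id": snp_id,
                "ancestral": anc,
                "derived": der,
                "gmap_cM": np.nan,
                "ancestral_known": known,
            }
        )
        haps.append(alleles.astype(np.uint8))
    variants = pd.DataFrame(rows)
    hap_ids = [f"{s}|{k}" for s in samples for k in (0, 1)]
    alleles = (
        np.vstack(haps) if haps else np.empty((0, len(hap_ids)), dtype=np.uint8)
    )
    return HaplotypePanel(validate_variants(variants), hap_ids, alleles)


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel as an uncompressed phased VCF with INFO/AA.

    REF/ALT are written so REF is the ancestral allele where known; the
    0/1 coding round-trips exactly through :func:`read_phased_vcf`.
    """
    samples = panel.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.variants["chrom"].unique():
            sub = panel.variants[panel.variants["chrom"] == chrom]
            fh.write(
                f"##contig=<ID={chrom},length={int(sub['pos_bp'].max()) + 1}>\n"
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        A = panel.alleles
        for i, v in panel.variants.iterrows():
            info = f"AA={v.ancestral}" if v.ancestral_known else "."
            gts = "\t".join(
                f"{A[i, 2 * j]}|{A[i, 2 * j + 1]}" for j in range(len(samples))
            )
            fh.write(
                f"{v.chrom}\t{v.pos_bp}\t{v.snp_id}\t{v.ancestral}\t{v.derived}"
                f"\t.\t.\t{info}\tGT\t{gts}\n"
            )


def read_labels(path, samples: list[str] | None = None) -> pd.DataFrame:
    """Read a sample→population(/group) TSV.

    Columns: sample_id, population[, group].  Errors on duplicate ids and,
    when ``samples`` is given, on any sample lacking a label.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "group" not in df.columns:
        df["group"] = df["population"]
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ids in labels: {sorted(set(dup))}")
    if samples is not None:
        unlabeled = sorted(set(samples) - set(df["sample_id"]))
        if unlabeled:
            raise ValueError(f"samples missing a label: {unlabeled}")
    return df[["sample_id", "population", "group"]]


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """Read gene annotation BED (chrom, start, end, gene_id[, score, strand]);
    coordinates stay 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError("BED needs at least 4 columns (chrom start end name)")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(np.int64),
            "end": df[2].astype(np.int64),
            "gene_id": df[3].astype(str),
            "strand": df[5].astype(str) if df.shape[1] > 5 else "+",
        }
    )
    if (out["start"] >= out["end"]).any():
        bad = out.loc[out["start"] >= out["end"], "gene_id"].iloc[0]
        raise ValueError(f"BED record with start >= end: {bad}")
    if out["gene_id"].duplicated().any():
        bad = sorted(set(out["gene_id"][out["gene_id"].duplicated()]))
        raise ValueError(f"duplicate gene ids in BED: {bad}")
    return out


def write_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene_id"]].assign(
        score=0, strand=genes.get("strand", "+")
    ).to_csv(path, sep="\t", index=False, header=False)


def read_go_map(path) -> dict[str, list[str]]:
    """Read a gene→GO-terms TSV (gene_id, term per line) into a multimap."""
    out: dict[str, list[str]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return out
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(gene, [])
        if term not in out[gene]:
            out[gene].append(term)
    return out


def write_go_map(go_map: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm\n")
        for gene, terms in go_map.items():
            for term in terms:
                fh.write(f"{gene}\t{term}\n")


def write_window_table(table: pd.DataFrame, path) -> None:
    """Write a window table TSV with fixed column order."""
    out = table.copy()
    for col in WINDOW_COLUMNS:
        if col not in out.columns:
            out[col] = (
                False if col in ("top1", "top5", "excluded_by_outgroup") else np.nan
            )
    out[WINDOW_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_window_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        return empty_window_table()
    for col in ("top1", "top5", "excluded_by_outgroup"):
        df[col] = df[col].astype(bool)
    return df


def write_scores(track: pd.DataFrame, path) -> None:
    """Write a per-SNP score track TSV (chrom, pos_bp, snp_id, score columns)."""
    track.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
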
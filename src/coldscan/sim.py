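"""Synthetic phased panels with known truth.

The generator emulates the data regimes a SNP-array selection scan
operates on: several populations diverged by pure drift from a common
ancestor (Balding–Nichols model), phased haplotypes on a uniform
recombination map, hard sweeps injected at a chosen derived-allele
frequency, planted duplicate / parent-offspring pairs, and two-way
admixed mosaic individuals with recorded tract boundaries.

Background linkage disequilibrium is optional: by default each site is
drawn independently given the population frequency (fast, sufficient for
allele-frequency statistics); with ``copying_smoothing`` every haplotype
is re-drawn as a Li–Stephens-style mosaic of a small founder set, which
gives the non-trivial haplotype-homozygosity decay the EHH-based scans
need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, HaplotypePanel, make_sample_info, population_index
from .genmap import GeneticMap


@dataclass
class SweepSpec:
    """A hard sweep: carriers of the derived core allele share one
    haplotype over ±core_len_cM around the core."""

    pop: str
    pos_bp: int
    target_freq: float
    core_len_cM: float = 0.5
    epsilon: float = 0.002  # per-SNP copy error within the swept tract


@dataclass
class RelativeSpec:
    duplicates: int = 0
    parent_offspring: int = 0
    pop: str | None = None  # default: first population


@dataclass
class AdmixtureSpec:
    sources: tuple[str, str] = ("POP1", "POP2")
    proportion: float = 0.5  # fraction of ancestry from sources[0]
    generations: float = 5.0
    n_samples: int = 10
    label: str = "ADMIX"


@dataclass
class AnnotationConfig:
    n_genes: int = 100
    n_terms: int = 20
    term_cluster_size: int = 1  # adjacent genes sharing each term


@dataclass
class SimConfig:
    n_pops: int = 3
    samples_per_pop: int = 20
    n_snps: int = 5_000
    chrom_length_bp: int = 10_000_000
    chrom: str = "1"
    recomb_rate_cM_per_Mb: float = 1.0
    drift_F: tuple[float, ...] | None = None  # default 0.05 per pop
    ancestral_beta: tuple[float, float] = (1.0, 1.0)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    copying_smoothing: bool = True
    n_founders: int = 20
    bg_switch_per_cM: float = 5.0  # founder-mosaic switch rate
    bg_error: float = 0.002  # per-site flip rate after smoothing
    sweeps: list[SweepSpec] = field(default_factory=list)
    relatives: RelativeSpec = field(default_factory=RelativeSpec)
    admixture: AdmixtureSpec | None = None
    annotations: AnnotationConfig = field(default_factory=AnnotationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift_F is None:
            self.drift_F = tuple([0.05] * self.n_pops)
        if len(self.drift_F) != self.n_pops:
            raise ValueError("drift_F needs one value per population")
        for F in self.drift_F:
            if not 0 <= F < 1:
                raise ValueError("drift F must lie in [0, 1)")


@dataclass
class SimTruth:
    sweep_cores: list[dict] = field(default_factory=list)
    related_pairs: list[dict] = field(default_factory=list)
    admixture_tracts: dict[str, list[tuple[int, int, str]]] = field(
        default_factory=dict
    )


def _balding_nichols(rng, p: np.ndarray, F: float) -> np.ndarray:
    """Population allele frequencies drifted from ancestral ``p``."""
    if F == 0:
        return p.copy()
    scale = (1 - F) / F
    return rng.beta(p * scale, (1 - p) * scale)


def _mosaic_of_founders(rng, founders: np.ndarray, switch_prob: np.ndarray) -> np.ndarray:
    """One haplotype copied from ``founders`` with interval switch probs."""
    n_snps, n_f = founders.shape
    switches = rng.random(n_snps - 1) < switch_prob
    seg = np.concatenate([[0], np.cumsum(switches)])
    seg_founder = rng.integers(0, n_f, size=seg[-1] + 1)
    return founders[np.arange(n_snps), seg_founder[seg]]


def _draw_pop_haplotypes(rng, freq: np.ndarray, n_haps: int, cfg: SimConfig,
                         gmap_cM: np.ndarray) -> np.ndarray:
    n_snps = len(freq)
    if not cfg.copying_smoothing:
        return (rng.random((n_snps, n_haps)) < freq[:, None]).astype(np.uint8)
    founders = (rng.random((n_snps, cfg.n_founders)) < freq[:, None]).astype(np.uint8)
    switch_prob = 1.0 - np.exp(-cfg.bg_switch_per_cM * np.diff(gmap_cM))
    haps = np.empty((n_snps, n_haps), dtype=np.uint8)
    for h in range(n_haps):
        haps[:, h] = _mosaic_of_founders(rng, founders, switch_prob)
    if cfg.bg_error > 0:
        flips = rng.random((n_snps, n_haps)) < cfg.bg_error
        haps ^= flips.astype(np.uint8)
    return haps


def simulate_panel(
    cfg: SimConfig,
) -> tuple[HaplotypePanel, GenotypeMatrix, pd.DataFrame, SimTruth, GeneticMap]:
    """Generate a phased panel, its genotype view, labels, truth and map."""
    rng = np.random.default_rng(cfg.seed)
    pos = np.sort(
        rng.choice(np.arange(1, cfg.chrom_length_bp), size=cfg.n_snps, replace=False)
    )
    gmap_cM = pos * cfg.recomb_rate_cM_per_Mb / 1e6
    lo, hi = cfg.ancestral_freq_range
    p = lo + (hi - lo) * rng.beta(*cfg.ancestral_beta, size=cfg.n_snps)

    pops = [f"POP{i + 1}" for i in range(cfg.n_pops)]
    sample_ids, pop_labels, blocks = [], [], []
    for pop, F in zip(pops, cfg.drift_F):
        freq = _balding_nichols(rng, p, F)
        haps = _draw_pop_haplotypes(rng, freq, 2 * cfg.samples_per_pop, cfg, gmap_cM)
        blocks.append(haps)
        ids = [f"{pop}_S{j:03d}" for j in range(cfg.samples_per_pop)]
        sample_ids.extend(ids)
        pop_labels.extend([pop] * cfg.samples_per_pop)

    variants = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos_bp": pos.astype(np.int64),
            "snp_id": [f"snp{i:06d}" for i in range(cfg.n_snps)],
            "ancestral": "A",
            "derived": "G",
            "gmap_cM": gmap_cM,
            "ancestral_known": True,
        }
    )
    hap_ids = [f"{s}|{k}" for s in sample_ids for k in (0, 1)]
    panel = HaplotypePanel(variants, hap_ids, np.hstack(blocks))
    labels = make_sample_info(sample_ids, pop_labels)
    truth = SimTruth()

    for sw in cfg.sweeps:
        panel = inject_sweep(
            panel, labels, sw.pop, sw.pos_bp, sw.target_freq,
            sw.core_len_cM, epsilon=sw.epsilon, rng=rng, truth=truth,
        )
    if cfg.relatives.duplicates or cfg.relatives.parent_offspring:
        panel = plant_relatives(panel, labels, cfg.relatives, rng=rng, truth=truth)
    if cfg.admixture is not None:
        panel, labels = make_admixed(
            panel, labels, cfg.admixture, rng=rng, truth=truth
        )

    gmap = GeneticMap(
        pd.DataFrame(
            {
                "chrom": [cfg.chrom, cfg.chrom],
                "pos_bp": [0, cfg.chrom_length_bp],
                "rate_cM_per_Mb": [cfg.recomb_rate_cM_per_Mb] * 2,
                "cM": [0.0, cfg.chrom_length_bp * cfg.recomb_rate_cM_per_Mb / 1e6],
            }
        )
    )
    return panel, panel.to_genotypes(), labels, truth, gmap


def inject_sweep(
    panel: HaplotypePanel,
    labels: pd.DataFrame,
    pop: str,
    core_pos: int,
    target_freq: float,
    core_len_cM: float,
    epsilon: float = 0.002,
    rng=None,
    truth: SimTruth | None = None,
) -> HaplotypePanel:
    """Plant a hard sweep in ``pop`` around the variant nearest ``core_pos``.

    A fraction ``target_freq`` of the population's haplotypes get the
    derived core allele and are overwritten, over ±core_len_cM, by copies
    of one randomly chosen carrier haplotype with per-SNP copy-error rate
    ``epsilon``; all other haplotypes are untouched.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0 < target_freq <= 1:
        raise ValueError("target frequency must lie in (0, 1]")
    sample_idx = population_index(labels, panel.sample_ids, pop)
    hap_idx = panel.haplotype_index_for_samples(
        [panel.sample_ids[i] for i in sample_idx]
    )
    # nearest variant whose current derived frequency does not already
    # exceed the target (the sweep can only raise frequency)
    pos_all = panel.variants["pos_bp"].to_numpy()
    order = np.argsort(np.abs(pos_all - core_pos), kind="stable")
    n_pop = len(hap_idx)
    core = -1
    for cand in order:
        if panel.alleles[cand, hap_idx].sum() <= round(target_freq * n_pop):
            core = int(cand)
            break
    if core < 0:
        raise ValueError("target frequency below current derived frequency")
    chrom = panel.variants.loc[core, "chrom"]
    g = panel.variants["gmap_cM"].to_numpy()
    in_region = (
        (panel.variants["chrom"] == chrom)
        & (np.abs(g - g[core]) <= core_len_cM)
    ).to_numpy()
    region = np.flatnonzero(in_region)

    alleles = panel.alleles.copy()
    n = len(hap_idx)
    k = int(round(target_freq * n))
    current = alleles[core, hap_idx] == 1
    if current.sum() > k:
        raise ValueError("target frequency below current derived frequency")
    carriers = list(np.flatnonzero(current))
    others = [i for i in rng.permutation(n) if not current[i]]
    carriers = np.asarray(carriers + others[: k - len(carriers)], dtype=int)
    carrier_haps = hap_idx[carriers]
    template_hap = hap_idx[carriers[rng.integers(len(carriers))]]
    template = alleles[region, template_hap]

    for h in carrier_haps:
        copy = template.copy()
        if epsilon > 0:
            copy ^= (rng.random(len(region)) < epsilon).astype(np.uint8)
        alleles[region, h] = copy
    alleles[core, carrier_haps] = 1
    non_carriers = np.setdiff1d(hap_idx, carrier_haps)
    alleles[core, non_carriers] = 0

    if truth is not None:
        truth.sweep_cores.append(
            {
                "pop": pop,
                "snp_index": core,
                "chrom": str(chrom),
                "pos_bp": int(panel.variants.loc[core, "pos_bp"]),
                "target_freq": target_freq,
            }
        )
    return HaplotypePanel(panel.variants.copy(), list(panel.haplotype_ids), alleles)


def _recombined_gamete(rng, hapA: np.ndarray, hapB: np.ndarray, gmap_cM: np.ndarray) -> np.ndarray:
    """Meiotic product of two parental haplotypes (Haldane crossovers)."""
    switch_prob = 1.0 - np.exp(-np.diff(gmap_cM) / 100.0)
    switches = rng.random(len(gmap_cM) - 1) < switch_prob
    phase = np.concatenate([[rng.integers(2)], np.zeros(len(switches), dtype=int)])
    phase = (phase[0] + np.concatenate([[0], np.cumsum(switches)])) % 2
    return np.where(phase == 0, hapA, hapB).astype(np.uint8)


def plant_relatives(
    panel: HaplotypePanel,
    labels: pd.DataFrame,
    spec: RelativeSpec,
    rng=None,
    truth: SimTruth | None = None,
) -> HaplotypePanel:
    """Overwrite samples to create duplicate and parent-offspring pairs.

    A duplicate is an exact copy of both haplotypes; a parent-offspring
    child receives one recombined gamete from each parent.
    """
    rng = np.random.default_rng() if rng is None else rng
    pop = spec.pop or labels["population"].iloc[0]
    sample_idx = population_index(labels, panel.sample_ids, pop)
    needed = 2 * spec.duplicates + 3 * spec.parent_offspring
    if needed > len(sample_idx):
        raise ValueError(
            f"need {needed} samples in {pop} for the requested relatives, "
            f"have {len(sample_idx)}"
        )
    pool = list(rng.permutation(sample_idx))
    alleles = panel.alleles.copy()
    gmap = panel.variants["gmap_cM"].to_numpy()
    sample_ids = panel.sample_ids

    for _ in range(spec.duplicates):
        src, dst = pool.pop(), pool.pop()
        alleles[:, 2 * dst] = alleles[:, 2 * src]
        alleles[:, 2 * dst + 1] = alleles[:, 2 * src + 1]
        if truth is not None:
            truth.related_pairs.append(
                {
                    "sample1": sample_ids[src],
                    "sample2": sample_ids[dst],
                    "relation": "duplicate",
                    "expected_pihat": 1.0,
                }
            )
    for _ in range(spec.parent_offspring):
        pa, pb, child = pool.pop(), pool.pop(), pool.pop()
        alleles[:, 2 * child] = _recombined_gamete(
            rng, alleles[:, 2 * pa], alleles[:, 2 * pa + 1], gmap
        )
        alleles[:, 2 * child + 1] = _recombined_gamete(
            rng, alleles[:, 2 * pb], alleles[:, 2 * pb + 1], gmap
        )
        if truth is not None:
            for parent in (pa, pb):
                truth.related_pairs.append(
                    {
                        "sample1": sample_ids[parent],
                        "sample2": sample_ids[child],
                        "relation": "parent_offspring",
                        "expected_pihat": 0.5,
                    }
                )
    return HaplotypePanel(panel.variants.copy(), list(panel.haplotype_ids), alleles)


def make_admixed(
    panel: HaplotypePanel,
    labels: pd.DataFrame,
    spec: AdmixtureSpec,
    rng=None,
    truth: SimTruth | None = None,
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Append two-way admixed mosaic samples to the panel.

    Tract lengths are exponential with mean 100/g cM (g generations since
    admixture); each tract copies one randomly chosen haplotype from a
    source population picked with the stated proportion.  Truth tracts
    tile each admixed haplotype exactly, recorded in bp.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0 < spec.proportion < 1:
        raise ValueError("admixture proportion must lie in (0, 1)")
    src_haps = {
        pop: panel.haplotype_index_for_samples(
            [panel.sample_ids[i] for i in population_index(labels, panel.sample_ids, pop)]
        )
        for pop in spec.sources
    }
    gmap = panel.variants["gmap_cM"].to_numpy()
    pos = panel.variants["pos_bp"].to_numpy()
    total_cM = gmap[-1] - gmap[0]
    mean_tract = 100.0 / spec.generations

    new_cols, new_ids, new_samples = [], [], []
    for s in range(spec.n_samples):
        sid = f"{spec.label}_S{s:03d}"
        new_samples.append(sid)
        for k in (0, 1):
            hap = np.empty(panel.n_variants, dtype=np.uint8)
            tracts = []
            start_cM = 0.0
            while start_cM < total_cM:
                length = rng.exponential(mean_tract)
                end_cM = min(start_cM + length, total_cM)
                donor = spec.sources[0 if rng.random() < spec.proportion else 1]
                donor_hap = int(rng.choice(src_haps[donor]))
                lo = np.searchsorted(gmap - gmap[0], start_cM, side="left")
                hi = np.searchsorted(gmap - gmap[0], end_cM, side="left")
                if end_cM >= total_cM:
                    hi = panel.n_variants
                hap[lo:hi] = panel.alleles[lo:hi, donor_hap]
                start_bp = 0 if lo == 0 else int(pos[lo])
                end_bp = int(pos[-1]) + 1 if hi >= panel.n_variants else int(pos[hi])
                if hi > lo:
                    tracts.append((start_bp, end_bp, donor))
                start_cM = end_cM
            # merge zero-SNP tracts happened above by the hi>lo guard
            new_cols.append(hap)
            new_ids.append(f"{sid}|{k}")
            if truth is not None:
                truth.admixture_tracts[f"{sid}|{k}"] = tracts

    alleles = np.hstack([panel.alleles, np.column_stack(new_cols)])
    out_panel = HaplotypePanel(
        panel.variants.copy(), list(panel.haplotype_ids) + new_ids, alleles
    )
    out_labels = pd.concat(
        [
            labels,
            make_sample_info(
                new_samples, [spec.label] * len(new_samples)
            ),
        ],
        ignore_index=True,
    )
    return out_panel, out_labels


def emit_annotations(
    cfg: SimConfig, rng=None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Synthetic gene annotation tiling the chromosome, plus a GO map.

    Genes tile the chromosome end to end; each GO term is assigned to a
    run of ``term_cluster_size`` adjacent genes, which exercises the
    positional-clustering correction of the window-count enrichment.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    ann = cfg.annotations
    step = cfg.chrom_length_bp // max(ann.n_genes, 1)
    genes = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": np.arange(ann.n_genes, dtype=np.int64) * step,
            "end": np.arange(ann.n_genes, dtype=np.int64) * step + max(step * 4 // 5, 1),
            "gene_id": [f"GENE{i:04d}" for i in range(ann.n_genes)],
            "strand": "+",
        }
    )
    go_map: dict[str, list[str]] = {}
    for t in range(ann.n_terms):
        start = int(rng.integers(0, max(ann.n_genes - ann.term_cluster_size + 1, 1)))
        term = f"GO:{t:07d}"
        for g in range(start, min(start + ann.term_cluster_size, ann.n_genes)):
            go_map.setdefault(f"GENE{g:04d}", []).append(term)
    return genes, go_map
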
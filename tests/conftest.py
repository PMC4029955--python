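import numpy as np
import pandas as pd
import pytest

from coldscan.core import GenotypeMatrix, HaplotypePanel, make_sample_info


def variant_frame(n: int, chrom: str = "1", spacing_bp: int = 1000,
                  rate_cM_per_Mb: float = 1.0) -> pd.DataFrame:
    pos = (np.arange(n) + 1) * spacing_bp
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": pos.astype(np.int64),
            "snp_id": [f"s{i}" for i in range(n)],
            "ancestral": "A",
            "derived": "G",
            "gmap_cM": pos * rate_cM_per_Mb / 1e6,
            "ancestral_known": True,
        }
    )


def panel_from_alleles(alleles: np.ndarray, **kw) -> HaplotypePanel:
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_var, n_hap = alleles.shape
    ids = [f"S{i}|{k}" for i in range(n_hap // 2) for k in (0, 1)]
    return HaplotypePanel(variant_frame(n_var, **kw), ids, alleles)


def gm_from_dosage(dosage: np.ndarray, pops: list[str], **kw) -> tuple:
    dosage = np.asarray(dosage, dtype=np.int8)
    n_var, n_samp = dosage.shape
    samples = [f"S{i}" for i in range(n_samp)]
    gm = GenotypeMatrix(variant_frame(n_var, **kw), samples, dosage)
    return gm, make_sample_info(samples, pops)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_521)
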